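import numpy as np
import pytest

import pbpkfit as pf


@pytest.fixture(scope="session")
def human():
    return pf.default_human()


@pytest.fixture(scope="session")
def neutral_compound():
    """Low-clearance neutral reference compound."""
    return pf.CompoundProfile(
        name="neutral-ref",
        logp=1.0,
        ionization=pf.IonizationSpec("neutral"),
        fup=0.5,
        bp_ratio=1.0,
        cl_hepatic=2.0,
        cl_renal=1.0,
        ka=1.0,
    )


@pytest.fixture(scope="session")
def strong_base_compound():
    return pf.CompoundProfile(
        name="base-ref",
        logp=2.0,
        ionization=pf.IonizationSpec("monoprotic_base_strong", pka_base=9.4),
        fup=0.3,
        bp_ratio=1.2,
        cl_hepatic=20.0,
        cl_renal=5.0,
        ka=1.0,
    )


@pytest.fixture
def uniform_kp():
    return pf.PartitionSet(kp={t: 1.0 for t in pf.TISSUES}, method="kp_optimized")


def one_compartment_subject(human, flow_scale=1000.0):
    """Degenerate physiology: flows fast enough that the whole body mixes
    as one compartment."""
    from dataclasses import replace

    from pbpkfit.physiology import TissueEntry

    tissues = {
        n: TissueEntry(e.volume, e.blood_flow * flow_scale, e.composition)
        for n, e in human.tissues.items()
    }
    return replace(
        human, tissues=tissues, cardiac_output=human.cardiac_output * flow_scale
    )


@pytest.fixture(scope="session")
def fast_flow_subject(human):
    return one_compartment_subject(human)


def exp_series(c0=12.5, lam=0.25, t_end=60.0, n=2000, dose=100.0, dataset_id="exp"):
    """Exact mono-exponential profile C = c0·exp(−lam·t) on a dense grid."""
    t = np.linspace(0.0, t_end, n)
    return pf.ConcentrationSeries(
        dataset_id=dataset_id, times=t, conc=c0 * np.exp(-lam * t), dose=dose
    )
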