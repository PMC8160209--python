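"""Synthetic compound libraries and noisy plasma-concentration studies.

Real fitting studies of this kind rest on literature concentration-time
profiles that cannot be redistributed; this module generates studies with
the same statistical structure so that every downstream stage (NCA, fitting,
accuracy reporting) is exercisable end to end.  A library of compounds
spanning acid / strong-base / weak-base / neutral / zwitterion ionization
classes is drawn, each with a hidden truth record (true effective Kp or
logP, ka, B:P); profiles are forward-simulated from the truth and corrupted
with multiplicative log-normal residual error (default CV 15%, the standard
proportional-error PK residual model).  Fitting code receives only the
public compound profiles and datasets — the truth record lives in a
separate structure it never reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .nca import ConcentrationSeries
from .partition import IonizationSpec, PartitionSet, build_partition_set
from .pbpk import CompoundProfile, DoseEvent, analytic_vdss, simulate, venous_plasma_series
from .physiology import SubjectPhysiology, default_human, validate_compound

#: Default ionization-class proportions for a "structurally diverse" library.
DEFAULT_CLASS_MIX = {
    "monoprotic_base_strong": 0.30,
    "monoprotic_acid": 0.25,
    "monoprotic_base_weak": 0.15,
    "neutral": 0.15,
    "zwitterion": 0.15,
}

#: pKa sampling ranges per ionization class (pH units).
PKA_RANGES = {
    "monoprotic_acid": (3.0, 6.0),
    "monoprotic_base_strong": (7.5, 10.5),
    "monoprotic_base_weak": (4.0, 7.0),
}

#: Rich sampling designs: times in h.
IV_DESIGN_TIMES = np.geomspace(0.083, 48.0, 12)
ORAL_DESIGN_TIMES = np.geomspace(0.25, 48.0, 12)
DEFAULT_DOSE_UG = 1.0e4


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class CompoundTruth:
    """Hidden data-generating parameters for one synthetic compound."""

    mode: str  # "kp" (global effective Kp) or "logp" (mechanistic)
    kp_scalar: Optional[float]
    logp: float
    ka: float
    bp_ratio: float
    f_oral: float


@dataclass(frozen=True)
class ArmDesign:
    route: str
    dose: float  # µg
    times: np.ndarray  # h


@dataclass
class StudyBundle:
    """A full synthetic study: public inputs plus the sealed truth records."""

    compounds: list[CompoundProfile]
    datasets: list[ConcentrationSeries]
    designs: dict[str, ArmDesign]
    truths: dict[str, CompoundTruth]  # compound name -> truth; not for fitting
    noise_cv: float
    seed: int
    truth_mode: str

    def datasets_for(self, compound_name: str) -> list[ConcentrationSeries]:
        return [d for d in self.datasets if d.compound == compound_name]


def _draw_ionization(cls: str, rng: np.random.Generator) -> IonizationSpec:
    if cls == "neutral":
        return IonizationSpec(cls="neutral")
    if cls == "zwitterion":
        return IonizationSpec(
            cls="zwitterion",
            pka_acid=rng.uniform(*PKA_RANGES["monoprotic_acid"]),
            pka_base=rng.uniform(7.0, 10.0),
        )
    lo, hi = PKA_RANGES[cls]
    if cls == "monoprotic_acid":
        return IonizationSpec(cls=cls, pka_acid=rng.uniform(lo, hi))
    return IonizationSpec(cls=cls, pka_base=rng.uniform(lo, hi))


def truth_partition_set(
    compound: CompoundProfile,
    truth: CompoundTruth,
    physiology: SubjectPhysiology,
) -> PartitionSet:
    """The data-generating partition set for one compound."""
    if truth.mode == "kp":
        return build_partition_set(
            compound, physiology, "kp_optimized", kp_scalar=truth.kp_scalar
        )
    return build_partition_set(
        compound, physiology, "rodgers_logp_optimized", logp_override=truth.logp
    )


def _truth_compound(compound: CompoundProfile, truth: CompoundTruth) -> CompoundProfile:
    return replace(
        compound, ka=truth.ka, bp_ratio=truth.bp_ratio, f_oral=truth.f_oral
    )


def sample_compound_library(
    n: int,
    class_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    physiology: Optional[SubjectPhysiology] = None,
    truth_mode: str = "kp",
    half_life_range: tuple[float, float] = (4.0, 12.0),
) -> tuple[list[CompoundProfile], dict[str, CompoundTruth]]:
    """Draw ``n`` compounds spanning the requested ionization-class mix.

    Public parameters: logP ~ U[-1, 5], class-specific pKa, fup ~ U[0.01, 1],
    B:P ≥ 1 − Hct, ka ~ LogUniform[0.1, 3] h⁻¹.  Clearance is drawn so the
    data-generating terminal half-life lands in ``half_life_range`` (hours)
    while total clearance stays far below cardiac output — every compound
    passes the pre-fit consistency checks by construction.
    """
    if n < 1:
        raise SyntheticError("n must be >= 1")
    if truth_mode not in ("kp", "logp"):
        raise SyntheticError(f"unknown truth_mode: {truth_mode}")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise SyntheticError("class proportions must sum to 1")
    if any(v < 0 for v in mix.values()):
        raise SyntheticError("class proportions must be non-negative")
    physiology = physiology or default_human()
    rng = np.random.default_rng([seed, 101])
    classes = list(mix)
    # deterministic class counts: largest-remainder apportionment
    quotas = {c: n * mix[c] for c in classes}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    remainder = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: quotas[c] - counts[c], reverse=True)[
        :remainder
    ]:
        counts[c] += 1
    assigned = [c for c in classes for _ in range(counts[c])]

    compounds, truths = [], {}
    for i, cls in enumerate(assigned):
        for _attempt in range(200):
            logp = rng.uniform(-1.0, 5.0)
            ion = _draw_ionization(cls, rng)
            fup = rng.uniform(0.01, 1.0)
            hct = physiology.hematocrit
            bp = (
                rng.uniform(1.0 - hct + 0.1, 2.5)
                if cls == "monoprotic_base_strong"
                else rng.uniform(1.0 - hct, 2.0)
            )
            ka = 10.0 ** rng.uniform(math.log10(0.1), math.log10(3.0))
            f_oral = rng.uniform(0.5, 1.0)
            kp_scalar = (
                10.0 ** rng.uniform(math.log10(0.5), math.log10(8.0))
                if truth_mode == "kp"
                else None
            )
            candidate = CompoundProfile(
                name=f"SYN{i:03d}",
                logp=logp,
                ionization=ion,
                fup=fup,
                bp_ratio=bp,
                cl_hepatic=10.0,  # provisional; set from half-life below
                cl_renal=0.0,
                ka=ka,
                f_oral=f_oral,
            )
            truth = CompoundTruth(
                mode=truth_mode,
                kp_scalar=kp_scalar,
                logp=logp,
                ka=ka,
                bp_ratio=bp,
                f_oral=f_oral,
            )
            try:
                pset = truth_partition_set(candidate, truth, physiology)
            except Exception:
                continue
            vss = analytic_vdss(physiology, pset, candidate)
            t_half = rng.uniform(*half_life_range)
            cl_total = math.log(2.0) * vss / (t_half * bp)  # blood clearance
            if not 1.0 <= cl_total <= 70.0:
                continue
            renal_frac = rng.uniform(0.0, 0.4)
            candidate = replace(
                candidate,
                cl_hepatic=cl_total * (1 - renal_frac),
                cl_renal=cl_total * renal_frac,
            )
            if validate_compound(candidate, physiology).ok:
                compounds.append(candidate)
                truths[candidate.name] = truth
                break
        else:
            raise SyntheticError(f"could not sample a feasible {cls} compound")
    return compounds, truths


def generate_dataset(
    compound: CompoundProfile,
    truth: CompoundTruth,
    physiology: SubjectPhysiology,
    design: ArmDesign,
    noise_cv: float = 0.15,
    seed: int = 0,
    dataset_id: Optional[str] = None,
) -> ConcentrationSeries:
    """Forward-simulate one dose arm from the truth record and add
    multiplicative log-normal noise (σ = sqrt(ln(1 + cv²)); cv=0 reproduces
    the noiseless curve exactly)."""
    truth_cmp = _truth_compound(compound, truth)
    pset = truth_partition_set(truth_cmp, truth, physiology)
    t_end = float(design.times[-1])
    res = simulate(
        truth_cmp,
        physiology,
        pset,
        [DoseEvent(route=design.route, amount=design.dose)],
        t_end,
        output_times=design.times,
    )
    plasma = venous_plasma_series(res, truth_cmp.bp_ratio)
    conc = plasma.conc.copy()
    if noise_cv > 0:
        rng = np.random.default_rng([seed, 211])
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        conc = conc * np.exp(rng.normal(0.0, sigma, size=conc.shape))
    return ConcentrationSeries(
        dataset_id=dataset_id or f"{compound.name}-{design.route}",
        times=design.times,
        conc=conc,
        dose=design.dose,
        route=design.route,
        compound=compound.name,
    )


def default_arm_designs(n_arms: int) -> list[ArmDesign]:
    """Alternating IV / oral arms; repeat arms get escalated doses."""
    designs = []
    for arm in range(n_arms):
        if arm % 2 == 0:
            designs.append(
                ArmDesign("iv_bolus", DEFAULT_DOSE_UG * (1 + arm // 2), IV_DESIGN_TIMES)
            )
        else:
            designs.append(
                ArmDesign("oral", 2.0 * DEFAULT_DOSE_UG * (1 + arm // 2), ORAL_DESIGN_TIMES)
            )
    return designs


def generate_study(
    n_compounds: int,
    datasets_per_compound: int = 2,
    noise_cv: float = 0.15,
    seed: int = 0,
    class_mix: Optional[dict[str, float]] = None,
    physiology: Optional[SubjectPhysiology] = None,
    truth_mode: str = "kp",
) -> StudyBundle:
    """A full reproducible study: library plus per-compound dose arms."""
    if n_compounds < 1 or datasets_per_compound < 1:
        raise SyntheticError("counts must be >= 1")
    physiology = physiology or default_human()
    compounds, truths = sample_compound_library(
        n_compounds,
        class_mix=class_mix,
        seed=seed,
        physiology=physiology,
        truth_mode=truth_mode,
    )
    datasets = []
    designs: dict[str, ArmDesign] = {}
    arms = default_arm_designs(datasets_per_compound)
    for i, compound in enumerate(compounds):
        for a, design in enumerate(arms):
            ds_id = f"{compound.name}-arm{a}-{design.route}"
            datasets.append(
                generate_dataset(
                    compound,
                    truths[compound.name],
                    physiology,
                    design,
                    noise_cv=noise_cv,
                    seed=seed * 10_000 + i * 100 + a,
                    dataset_id=ds_id,
                )
            )
            designs[ds_id] = design
    return StudyBundle(
        compounds=compounds,
        datasets=datasets,
        designs=designs,
        truths=truths,
        noise_cv=noise_cv,
        seed=seed,
        truth_mode=truth_mode,
    )
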