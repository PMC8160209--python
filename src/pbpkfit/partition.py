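"""Tissue:plasma partition coefficients.

Distribution is summarised per tissue by the equilibrium partition
coefficient Kp = C_tissue / C_plasma (total:total).  Three routes produce a
full per-tissue set:

* ``rodgers_fixed`` — the Rodgers–Rowland tissue-composition equations
  evaluated at the compound's measured octanol–water logP;
* ``rodgers_logp_optimized`` — the same equations at a fitted effective logP;
* ``kp_optimized`` — a single fitted effective Kp applied to every tissue.

The mechanistic equations predict Kpu, the tissue to *unbound*-plasma
coefficient; Kp = Kpu · fup.  Moderate-to-strong monoprotic bases
(pKa ≥ 7) partition into acidic phospholipid, with the affinity constant
back-calculated from the blood:plasma ratio via erythrocyte composition;
acids, weak bases, neutrals and zwitterions instead carry an albumin-type
protein term back-calculated from fup.  Adipose neutral-lipid partitioning
uses the vegetable-oil scale log P_vo:w = 1.115·logP − 1.35 in place of the
octanol value.

A physiological cap guards against runaway predictions: any Kp above the
cap is truncated to it and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .physiology import SubjectPhysiology, TissueComposition, TISSUES

#: pKa at or above which a monoprotic base is treated as moderate-to-strong
#: (acidic-phospholipid binding class).
STRONG_BASE_PKA_THRESHOLD = 7.0

#: Neutral phospholipid behaves as 30% neutral lipid + 70% water.
_NP_LIPID_FRACTION = 0.3

CLASS1 = "monoprotic_base_strong"
CLASS2 = ("monoprotic_acid", "monoprotic_base_weak", "neutral", "zwitterion")
IONIZATION_CLASSES = (CLASS1,) + CLASS2


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class IonizationSpec:
    """Ionization class and dissociation constants of a compound."""

    cls: str
    pka_acid: Optional[float] = None
    pka_base: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cls not in IONIZATION_CLASSES:
            raise PartitionError(f"unknown ionization class: {self.cls}")
        if self.cls == "neutral" and (
            self.pka_acid is not None or self.pka_base is not None
        ):
            raise PartitionError("neutral compounds take no pKa")
        if self.cls == "monoprotic_acid" and self.pka_acid is None:
            raise PartitionError("monoprotic_acid requires pka_acid")
        if self.cls in ("monoprotic_base_strong", "monoprotic_base_weak"):
            if self.pka_base is None:
                raise PartitionError(f"{self.cls} requires pka_base")
            if (
                self.cls == "monoprotic_base_strong"
                and self.pka_base < STRONG_BASE_PKA_THRESHOLD
            ):
                raise PartitionError(
                    f"monoprotic_base_strong requires pKa >= "
                    f"{STRONG_BASE_PKA_THRESHOLD}, got {self.pka_base}"
                )
        if self.cls == "zwitterion" and (
            self.pka_acid is None or self.pka_base is None
        ):
            raise PartitionError("zwitterion requires both pKa values")


@dataclass(frozen=True)
class PartitionSet:
    """Per-tissue Kp values with provenance."""

    kp: dict[str, float]
    method: str
    capped: frozenset[str] = field(default_factory=frozenset)
    kp_cap_value: float = math.inf

    def __post_init__(self) -> None:
        bad = {t: v for t, v in self.kp.items() if not v > 0}
        if bad:
            raise PartitionError(f"non-positive Kp: {bad}")
        if not self.capped <= set(self.kp):
            raise PartitionError("capped tissues not in kp map")


def _lipid_term(logp: float, comp: TissueComposition, adipose: bool) -> float:
    """P·f_nl + (0.3·P + 0.7)·f_np, with the vegetable-oil P for adipose f_nl."""
    p_oct = 10.0 ** logp
    p_nl = 10.0 ** (1.115 * logp - 1.35) if adipose else p_oct
    return p_nl * comp.f_nl + (
        _NP_LIPID_FRACTION * p_oct + (1 - _NP_LIPID_FRACTION)
    ) * comp.f_np


def kpu_class1_base(
    compound,
    tissue: TissueComposition,
    ka_ap: float,
    plasma_ph: float,
    logp: Optional[float] = None,
    adipose: bool = False,
) -> float:
    """Kpu for a moderate-to-strong monoprotic base.

    Ionized drug associates with tissue acidic phospholipid (affinity
    ``ka_ap``); only the neutral species sees the lipid fractions.
    """
    if compound.ionization.cls != CLASS1:
        raise PartitionError(
            f"kpu_class1_base requires {CLASS1}, got {compound.ionization.cls}"
        )
    if ka_ap < 0:
        raise PartitionError("ka_ap must be >= 0")
    if logp is None:
        logp = compound.logp
    pka = compound.ionization.pka_base
    x = 10.0 ** (pka - tissue.ph_iw)  # ionized:neutral, intracellular
    y = 10.0 ** (pka - plasma_ph)  # ionized:neutral, plasma
    return (
        tissue.f_ew
        + (1 + x) / (1 + y) * tissue.f_iw
        + ka_ap * tissue.ap_conc * x / (1 + y)
        + _lipid_term(logp, tissue, adipose) / (1 + y)
    )


def kaap_from_blood(
    compound,
    blood_cells: TissueComposition,
    hematocrit: float,
    plasma_ph: float,
    logp: Optional[float] = None,
) -> float:
    """Back-calculate the acidic-phospholipid affinity constant from B:P.

    The erythrocyte:unbound-plasma coefficient
    Kpu_BC = (B:P − (1 − Hct)) / (Hct · fup) is observable; inverting the
    class-1 equation applied to erythrocyte composition isolates ka_ap.
    Clamped at zero when Kpu_BC falls below the non-phospholipid terms.
    """
    if compound.ionization.cls != CLASS1:
        raise PartitionError(
            f"kaap_from_blood requires {CLASS1}, got {compound.ionization.cls}"
        )
    if logp is None:
        logp = compound.logp
    bp, fup = compound.bp_ratio, compound.fup
    if bp <= 1.0 - hematocrit:
        raise PartitionError(
            f"no cell partitioning: B:P {bp:g} <= 1 - Hct {1 - hematocrit:g}"
        )
    kpu_bc = (bp - (1.0 - hematocrit)) / (hematocrit * fup)
    pka = compound.ionization.pka_base
    x_bc = 10.0 ** (pka - blood_cells.ph_iw)
    y = 10.0 ** (pka - plasma_ph)
    non_ap = (
        blood_cells.f_ew
        + (1 + x_bc) / (1 + y) * blood_cells.f_iw
        + _lipid_term(logp, blood_cells, adipose=False) / (1 + y)
    )
    ka_ap = (kpu_bc - non_ap) * (1 + y) / (blood_cells.ap_conc * x_bc)
    return max(ka_ap, 0.0)


def _ionized_ratios(ionization: IonizationSpec, ph_iw: float, ph_p: float):
    """(X, Y): intracellular and plasma ionized:neutral concentration ratios."""
    cls = ionization.cls
    if cls == "neutral":
        return 0.0, 0.0
    if cls == "monoprotic_acid":
        return 10.0 ** (ph_iw - ionization.pka_acid), 10.0 ** (ph_p - ionization.pka_acid)
    if cls == "monoprotic_base_weak":
        return 10.0 ** (ionization.pka_base - ph_iw), 10.0 ** (ionization.pka_base - ph_p)
    if cls == "zwitterion":
        x = 10.0 ** (ph_iw - ionization.pka_acid) + 10.0 ** (ionization.pka_base - ph_iw)
        y = 10.0 ** (ph_p - ionization.pka_acid) + 10.0 ** (ionization.pka_base - ph_p)
        return x, y
    raise PartitionError(f"kpu_class2 does not handle class {cls}")


def kpu_class2(
    compound,
    tissue: TissueComposition,
    plasma_ph: float,
    fup: Optional[float] = None,
    plasma_f_nl: float = 0.0023,
    plasma_f_np: float = 0.0013,
    logp: Optional[float] = None,
    adipose: bool = False,
) -> float:
    """Kpu for acids, weak bases, neutrals and zwitterions.

    These classes bind albumin-type protein rather than acidic phospholipid;
    the protein association is back-calculated from fup using plasma lipid
    composition, scaled to tissue by the tissue:plasma protein ratio, and
    clamped at zero.
    """
    if compound.ionization.cls not in CLASS2:
        raise PartitionError(
            f"kpu_class2 does not handle class {compound.ionization.cls}"
        )
    if fup is None:
        fup = compound.fup
    if not 0.0 < fup <= 1.0:
        raise PartitionError(f"fup={fup} outside (0, 1]")
    if logp is None:
        logp = compound.logp
    x, y = _ionized_ratios(compound.ionization, tissue.ph_iw, plasma_ph)
    p_oct = 10.0 ** logp
    plasma_lipid = p_oct * plasma_f_nl + (
        _NP_LIPID_FRACTION * p_oct + (1 - _NP_LIPID_FRACTION)
    ) * plasma_f_np
    ka_pr_plasma = max(1.0 / fup - 1.0 - plasma_lipid / (1 + y), 0.0)
    return (
        tissue.f_ew
        + (1 + x) / (1 + y) * tissue.f_iw
        + _lipid_term(logp, tissue, adipose) / (1 + y)
        + ka_pr_plasma * tissue.protein_ratio
    )


def compute_kp_cap(
    observed_vdss: Optional[float] = None, body_volume: Optional[float] = None
) -> float:
    """Physiological Kp ceiling: max(50, 5·Vdss_obs/V_body) when an observed
    Vdss exists, else 50."""
    if observed_vdss is None or body_volume is None:
        return 50.0
    return max(50.0, 5.0 * observed_vdss / body_volume)


def apply_kp_cap(kps: PartitionSet, cap: float) -> PartitionSet:
    """Truncate every Kp above ``cap`` to the cap and record the tissues."""
    if not cap > 0:
        raise PartitionError("cap must be > 0")
    capped = frozenset(t for t, v in kps.kp.items() if v > cap)
    if not capped:
        return replace(kps, kp_cap_value=cap)
    new_kp = {t: (cap if t in capped else v) for t, v in kps.kp.items()}
    return replace(kps, kp=new_kp, capped=kps.capped | capped, kp_cap_value=cap)


def rodgers_kpu(
    compound,
    physiology: SubjectPhysiology,
    tissue_name: str,
    logp: Optional[float] = None,
) -> float:
    """Class-dispatched Kpu for one named tissue of a subject."""
    comp = physiology.tissues[tissue_name].composition
    adipose = tissue_name == "adipose"
    if compound.ionization.cls == CLASS1:
        ka_ap = kaap_from_blood(
            compound,
            physiology.blood_cell_composition,
            physiology.hematocrit,
            physiology.plasma_ph,
            logp=logp,
        )
        return kpu_class1_base(
            compound, comp, ka_ap, physiology.plasma_ph, logp=logp, adipose=adipose
        )
    return kpu_class2(
        compound,
        comp,
        physiology.plasma_ph,
        plasma_f_nl=physiology.plasma_f_nl,
        plasma_f_np=physiology.plasma_f_np,
        logp=logp,
        adipose=adipose,
    )


def build_partition_set(
    compound,
    physiology: SubjectPhysiology,
    method: str,
    logp_override: Optional[float] = None,
    kp_scalar: Optional[float] = None,
    kp_cap: Optional[float] = None,
    scalar_includes_eliminating: bool = True,
) -> PartitionSet:
    """Assemble the full per-tissue Kp map for one distribution configuration.

    ``rodgers_fixed`` evaluates the mechanistic equations at the compound's
    own logP; ``rodgers_logp_optimized`` at ``logp_override``; ``kp_optimized``
    assigns ``kp_scalar`` to every tissue compartment (eliminating organs
    included unless ``scalar_includes_eliminating`` is False, in which case
    liver and kidney fall back to the mechanistic value).  The cap rule is
    applied last; ``kp_cap=None`` uses the default ceiling, ``math.inf``
    disables it.
    """
    if kp_cap is None:
        kp_cap = compute_kp_cap()
    if method == "kp_optimized":
        if kp_scalar is None:
            raise PartitionError("kp_optimized requires kp_scalar")
        kp = {t: float(kp_scalar) for t in TISSUES}
        if not scalar_includes_eliminating:
            for t in ("liver", "kidney"):
                kp[t] = rodgers_kpu(compound, physiology, t) * compound.fup
    elif method in ("rodgers_fixed", "rodgers_logp_optimized"):
        if method == "rodgers_logp_optimized":
            if logp_override is None:
                raise PartitionError("rodgers_logp_optimized requires logp_override")
            logp = logp_override
        else:
            logp = compound.logp
        kp = {
            t: rodgers_kpu(compound, physiology, t, logp=logp) * compound.fup
            for t in TISSUES
        }
    else:
        raise PartitionError(f"unknown partition method: {method}")
    return apply_kp_cap(PartitionSet(kp=kp, method=method), kp_cap)
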