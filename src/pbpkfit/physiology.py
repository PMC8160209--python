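"""Subject physiology: organ volumes, blood flows, tissue composition.

A whole-body model subject is a fixed roster of 14 compartments — lung,
arterial blood, venous blood, and eleven perfused tissues (adipose, bone,
brain, gut, heart, kidney, liver, muscle, skin, spleen, rest-of-body).  The
liver flow listed in the table is the hepatic artery only; gut and spleen
venous outflow drains portally into the liver, so total hepatic inflow is
Q_ha + Q_gut + Q_spleen.  Flow closure therefore requires the eleven systemic
(non-lung, non-blood) flows to sum to cardiac output, and the lung — in
series between venous and arterial blood — to carry cardiac output itself.

Data-consistency rules applied to a compound before any fit live here too:
total clearance below cardiac output, blood:plasma ratio at or above
1 − hematocrit, and (when an observed value exists) NCA Vdss at or above
blood volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

#: The fixed compartment roster; every loaded physiology must provide all 14.
COMPARTMENTS = (
    "venous_blood",
    "arterial_blood",
    "lung",
    "adipose",
    "bone",
    "brain",
    "gut",
    "heart",
    "kidney",
    "liver",
    "muscle",
    "skin",
    "spleen",
    "rest_of_body",
)

#: Perfused tissue compartments (everything except the two blood pools).
TISSUES = COMPARTMENTS[2:]

#: Tissues whose arterial supply is part of the systemic flow balance
#: (lung is in series with the heart and excluded).
SYSTEMIC_TISSUES = COMPARTMENTS[3:]

#: Organs carrying an elimination clearance term.
ELIMINATING_TISSUES = ("liver", "kidney")

#: Tissues draining portally into the liver.
PORTAL_TISSUES = ("gut", "spleen")


class PhysiologyError(ValueError):
    """Raised when a physiology table violates its structural invariants."""


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions and binding-relevant composition of one tissue.

    Fractions are volume fractions of total tissue; ``ap_conc`` is acidic
    phospholipid in mg per g tissue; ``protein_ratio`` is the tissue-to-plasma
    concentration ratio of the binding protein (albumin for acids/neutrals).
    """

    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    ap_conc: float
    ph_iw: float
    protein_ratio: float

    def __post_init__(self) -> None:
        for name in ("f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhysiologyError(f"{name}={v} outside [0, 1]")
        if self.f_ew + self.f_iw + self.f_nl + self.f_np > 1.0 + 1e-9:
            raise PhysiologyError("tissue volume fractions sum above 1")
        if not 6.0 <= self.ph_iw <= 8.0:
            raise PhysiologyError(f"ph_iw={self.ph_iw} outside [6, 8]")
        if self.ap_conc < 0 or self.protein_ratio < 0:
            raise PhysiologyError("ap_conc and protein_ratio must be >= 0")


@dataclass(frozen=True)
class TissueEntry:
    volume: float  # L
    blood_flow: float  # L/h
    composition: TissueComposition


@dataclass(frozen=True)
class SubjectPhysiology:
    """One subject's organ volumes, flows and compositions plus blood scalars."""

    tissues: dict[str, TissueEntry]
    cardiac_output: float  # L/h
    hematocrit: float
    blood_volume: float  # L
    plasma_ph: float
    body_weight: float  # kg
    blood_cell_composition: TissueComposition
    plasma_f_nl: float
    plasma_f_np: float

    def __post_init__(self) -> None:
        missing = [c for c in COMPARTMENTS if c not in self.tissues]
        if missing:
            raise PhysiologyError(f"missing tissue: {', '.join(missing)}")
        for name, entry in self.tissues.items():
            if entry.volume <= 0:
                raise PhysiologyError(f"non-positive volume: {name}")
            if entry.blood_flow <= 0:
                raise PhysiologyError(f"non-positive flow: {name}")
        if not 0.0 < self.hematocrit < 1.0:
            raise PhysiologyError("hematocrit outside (0, 1)")
        systemic = sum(self.tissues[t].blood_flow for t in SYSTEMIC_TISSUES)
        if abs(systemic - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise PhysiologyError(
                f"flow balance: systemic flows sum to {systemic:.6g} L/h, "
                f"cardiac output is {self.cardiac_output:.6g} L/h"
            )
        if abs(self.tissues["lung"].blood_flow - self.cardiac_output) > (
            1e-6 * self.cardiac_output
        ):
            raise PhysiologyError("flow balance: lung flow must equal cardiac output")

    @property
    def liver_total_inflow(self) -> float:
        """Hepatic artery plus portal (gut + spleen) flow, L/h."""
        return (
            self.tissues["liver"].blood_flow
            + self.tissues["gut"].blood_flow
            + self.tissues["spleen"].blood_flow
        )


@dataclass
class ValidationReport:
    """Outcome of the pre-fit data-consistency checks; empty == clean."""

    violations: list[dict] = field(default_factory=list)

    def add(self, rule: str, message: str, value: float, bound: float) -> None:
        self.violations.append(
            {"rule": rule, "message": message, "value": value, "bound": bound}
        )

    @property
    def ok(self) -> bool:
        return not self.violations

    def rules(self) -> set[str]:
        return {v["rule"] for v in self.violations}


_COLUMNS = [
    "tissue",
    "volume_L",
    "flow_L_per_h",
    "f_ew",
    "f_iw",
    "f_nl",
    "f_np",
    "ap_mg_per_g",
    "ph_iw",
    "protein_ratio",
]


def load_physiology(
    table: str | Path, globals_file: Optional[str | Path] = None
) -> SubjectPhysiology:
    """Load a subject from a tissue CSV plus its sidecar global config.

    ``table`` has one row per compartment with the columns listed in
    ``_COLUMNS``; ``globals_file`` (default: same stem with ``_global.yaml``
    replacing ``_tissues.csv``, else ``<stem>.yaml``) carries whole-body
    scalars and the plasma / erythrocyte composition.
    """
    table = Path(table)
    if globals_file is None:
        stem = table.stem
        if stem.endswith("_tissues"):
            globals_file = table.with_name(stem[: -len("_tissues")] + "_global.yaml")
        else:
            globals_file = table.with_suffix(".yaml")
    df = pd.read_csv(table)
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise PhysiologyError(f"missing columns: {', '.join(missing_cols)}")
    with open(globals_file) as fh:
        g = yaml.safe_load(fh)

    tissues: dict[str, TissueEntry] = {}
    for _, row in df.iterrows():
        name = str(row["tissue"])
        if float(row["volume_L"]) <= 0:
            raise PhysiologyError(f"non-positive volume: {name}")
        if float(row["flow_L_per_h"]) <= 0:
            raise PhysiologyError(f"non-positive flow: {name}")
        comp = TissueComposition(
            f_ew=float(row["f_ew"]),
            f_iw=float(row["f_iw"]),
            f_nl=float(row["f_nl"]),
            f_np=float(row["f_np"]),
            ap_conc=float(row["ap_mg_per_g"]),
            ph_iw=float(row["ph_iw"]),
            protein_ratio=float(row["protein_ratio"]),
        )
        tissues[name] = TissueEntry(
            volume=float(row["volume_L"]),
            blood_flow=float(row["flow_L_per_h"]),
            composition=comp,
        )

    bc = g["blood_cell_composition"]
    return SubjectPhysiology(
        tissues=tissues,
        cardiac_output=float(g["cardiac_output_L_per_h"]),
        hematocrit=float(g["hematocrit"]),
        blood_volume=float(g["blood_volume_L"]),
        plasma_ph=float(g["plasma_ph"]),
        body_weight=float(g["body_weight_kg"]),
        blood_cell_composition=TissueComposition(
            f_ew=float(bc.get("f_ew", 0.0)),
            f_iw=float(bc["f_iw"]),
            f_nl=float(bc["f_nl"]),
            f_np=float(bc["f_np"]),
            ap_conc=float(bc["ap_mg_per_g"]),
            ph_iw=float(bc["ph_iw"]),
            protein_ratio=float(bc.get("protein_ratio", 0.0)),
        ),
        plasma_f_nl=float(g["plasma_composition"]["f_nl"]),
        plasma_f_np=float(g["plasma_composition"]["f_np"]),
    )


def default_human() -> SubjectPhysiology:
    """The bundled healthy-adult human reference subject (70 kg, CO 336 L/h)."""
    root = resources.files("pbpkfit") / "data"
    with resources.as_file(root / "human_adult_tissues.csv") as csv_path:
        return load_physiology(
            csv_path, Path(csv_path).with_name("human_adult_global.yaml")
        )


def validate_compound(
    compound,
    physiology: SubjectPhysiology,
    observed_vdss: Optional[float] = None,
) -> ValidationReport:
    """Pre-fit consistency checks on a compound record. Never raises.

    Rules: ``cl_vs_co`` — total (hepatic + renal) clearance must be below
    cardiac output on a blood-flow basis; ``bp_floor`` — blood:plasma ratio
    cannot fall below 1 − hematocrit (a drug excluded from erythrocytes still
    occupies the plasma fraction of blood); ``vdss_floor`` — an *observed*
    NCA Vdss below blood volume is physically impossible and flags bad data.
    """
    report = ValidationReport()
    cl_total = compound.cl_hepatic + compound.cl_renal
    if cl_total >= physiology.cardiac_output:
        report.add(
            "cl_vs_co",
            f"total clearance {cl_total:g} L/h >= cardiac output "
            f"{physiology.cardiac_output:g} L/h",
            cl_total,
            physiology.cardiac_output,
        )
    bp_floor = 1.0 - physiology.hematocrit
    if compound.bp_ratio < bp_floor:
        report.add(
            "bp_floor",
            f"B:P {compound.bp_ratio:g} below 1 - hematocrit = {bp_floor:g}",
            compound.bp_ratio,
            bp_floor,
        )
    if observed_vdss is not None and observed_vdss < physiology.blood_volume:
        report.add(
            "vdss_floor",
            f"observed Vdss {observed_vdss:g} L below blood volume "
            f"{physiology.blood_volume:g} L",
            observed_vdss,
            physiology.blood_volume,
        )
    return report
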