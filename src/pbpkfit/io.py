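"""File formats: concentration CSV + manifest, compound configs, fit reports.

Concentration data travel as tidy CSV with columns
``dataset_id,time_h,conc_ug_per_L`` and a YAML manifest carrying per-dataset
metadata (dose_ug, route, compound, subject).  Compound parameters travel as
a YAML/JSON mapping mirroring CompoundProfile plus an optional doses list.
All units are fixed package-wide: h, µg, µg/L, L, L/h.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .nca import ConcentrationSeries
from .optimize import OptimizationResult
from .partition import IonizationSpec
from .pbpk import CompoundProfile, DoseEvent
from .synthetic import StudyBundle

REQUIRED_CONC_COLUMNS = ("dataset_id", "time_h", "conc_ug_per_L")


class IOError_(ValueError):
    pass


def read_concentration_csv(
    path: str | Path, manifest: Optional[str | Path] = None
) -> list[ConcentrationSeries]:
    """Read concentration series grouped by dataset_id, times ascending.

    ``manifest`` defaults to ``<path stem>_manifest.yaml``.  Malformed rows
    (negative concentration, unparsable numbers) and duplicate
    (dataset_id, time) pairs are reported with their CSV line number.
    """
    path = Path(path)
    if manifest is None:
        manifest = path.with_name(path.stem + "_manifest.yaml")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CONC_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    with open(manifest) as fh:
        meta = yaml.safe_load(fh)

    # csv line number = dataframe index + 2 (header on line 1)
    for col in ("time_h", "conc_ug_per_L"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise IOError_(f"{path}: malformed {col} at line {bad[0] + 2}")
        df[col] = vals
    neg = df.index[df["conc_ug_per_L"] < 0]
    if len(neg):
        raise IOError_(f"{path}: negative concentration at line {neg[0] + 2}")
    dup = df.index[df.duplicated(subset=["dataset_id", "time_h"])]
    if len(dup):
        raise IOError_(f"{path}: duplicate (dataset_id, time) at line {dup[0] + 2}")

    series = []
    for ds_id, group in df.groupby("dataset_id", sort=True):
        if ds_id not in meta:
            raise IOError_(f"{path}: dataset {ds_id} missing from manifest")
        m = meta[ds_id]
        group = group.sort_values("time_h")
        series.append(
            ConcentrationSeries(
                dataset_id=str(ds_id),
                times=group["time_h"].to_numpy(),
                conc=group["conc_ug_per_L"].to_numpy(),
                dose=float(m["dose_ug"]),
                route=str(m["route"]),
                compound=str(m.get("compound", "")),
                subject=str(m.get("subject", "")),
            )
        )
    return series


def write_concentration_csv(
    series: Sequence[ConcentrationSeries],
    path: str | Path,
    manifest: Optional[str | Path] = None,
) -> None:
    path = Path(path)
    if manifest is None:
        manifest = path.with_name(path.stem + "_manifest.yaml")
    frames = [
        pd.DataFrame(
            {"dataset_id": s.dataset_id, "time_h": s.times, "conc_ug_per_L": s.conc}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = {
        s.dataset_id: {
            "dose_ug": float(s.dose),
            "route": s.route,
            "compound": s.compound,
            "subject": s.subject,
        }
        for s in series
    }
    with open(manifest, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def compound_from_dict(d: dict) -> CompoundProfile:
    ion = d["ionization"]
    return CompoundProfile(
        name=str(d["name"]),
        logp=float(d["logp"]),
        ionization=IonizationSpec(
            cls=str(ion["class"]),
            pka_acid=None if ion.get("pka_acid") is None else float(ion["pka_acid"]),
            pka_base=None if ion.get("pka_base") is None else float(ion["pka_base"]),
        ),
        fup=float(d["fup"]),
        bp_ratio=float(d["bp_ratio"]),
        cl_hepatic=float(d.get("cl_hepatic_L_per_h", 0.0)),
        cl_renal=float(d.get("cl_renal_L_per_h", 0.0)),
        ka=float(d.get("ka_per_h", 1.0)),
        f_oral=float(d.get("f_oral", 1.0)),
    )


def compound_to_dict(c: CompoundProfile) -> dict:
    return {
        "name": c.name,
        "logp": c.logp,
        "ionization": {
            "class": c.ionization.cls,
            "pka_acid": c.ionization.pka_acid,
            "pka_base": c.ionization.pka_base,
        },
        "fup": c.fup,
        "bp_ratio": c.bp_ratio,
        "cl_hepatic_L_per_h": c.cl_hepatic,
        "cl_renal_L_per_h": c.cl_renal,
        "ka_per_h": c.ka,
        "f_oral": c.f_oral,
    }


def read_compound_config(path: str | Path) -> tuple[CompoundProfile, list[DoseEvent]]:
    """Compound YAML/JSON with an optional ``doses`` list."""
    path = Path(path)
    with open(path) as fh:
        d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    compound = compound_from_dict(d)
    doses = [
        DoseEvent(
            route=str(e["route"]),
            amount=float(e["amount_ug"]),
            start_time=float(e.get("start_time_h", 0.0)),
            duration=float(e.get("duration_h", 0.0)),
        )
        for e in d.get("doses", [])
    ]
    return compound, doses


def write_fit_report(result: OptimizationResult, out_dir: str | Path) -> None:
    """Structured fit report plus the trajectory table for convergence plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{result.compound or 'fit'}_{result.method or 'fit'}"
    with open(out_dir / f"{stem}_report.json", "w") as fh:
        json.dump(
            {
                "compound": result.compound,
                "method": result.method,
                "best_params": result.best_params,
                "best_cost": result.best_cost,
                "converged": result.converged,
                "phase_boundary": result.phase_boundary,
                "n_evaluations": result.n_evaluations,
            },
            fh,
            indent=2,
        )
    pd.DataFrame(result.trajectory, columns=["evaluation", "cost"]).to_csv(
        out_dir / f"{stem}_trajectory.csv", index=False
    )


def write_study_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write a synthetic study in the exact format the fit pipeline reads.

    The truth record goes to a separate ``truth.json`` that fitting commands
    refuse to read.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_concentration_csv(bundle.datasets, out_dir / "concentrations.csv")
    with open(out_dir / "compounds.yaml", "w") as fh:
        yaml.safe_dump([compound_to_dict(c) for c in bundle.compounds], fh)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": bundle.seed,
                "noise_cv": bundle.noise_cv,
                "truth_mode": bundle.truth_mode,
                "truths": {k: asdict(v) for k, v in bundle.truths.items()},
            },
            fh,
            indent=2,
        )
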