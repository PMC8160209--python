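"""Fold-error accuracy statistics for predicted vs observed PK outputs.

Bias and spread of predictions are summarised on the fold scale:

    AFE  = 10^( mean log10(pred/obs) )      — geometric bias (1 = unbiased)
    AAFE = 10^( mean |log10(pred/obs)| )    — geometric spread (1 = perfect)

plus the percentage of predictions within an n-fold band, the squared
Pearson correlation r², and a per-configuration geometric mean fold error
(GMFE): the AAFE pooled over all PK outputs × datasets.  The Table-style
accuracy report applies the terminal-phase exclusion rule — datasets whose
*observed* profile lacks a sufficient terminal phase are dropped from the
extrapolated rows (AUC0-inf, MRT, Vdss) only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nca import PKOutputs
from .partition import PartitionSet

#: Report rows, in display order.
REPORT_METRICS = ("cmax", "tmax", "auc_0t", "aumc_0t", "auc_inf", "mrt", "vdss")
#: Rows subject to the terminal-phase exclusion rule.
EXTRAPOLATED_METRICS = frozenset({"auc_inf", "mrt", "vdss"})


class MetricError(ValueError):
    pass


def _log_ratios(pred: Sequence[float], obs: Sequence[float]) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise MetricError("pred and obs must be 1-D and equal length")
    if len(pred) == 0:
        raise MetricError("empty input")
    bad = np.nonzero((pred <= 0) | (obs <= 0))[0]
    if len(bad):
        i = int(bad[0])
        raise MetricError(
            f"nonpositive value at index {i}: pred={pred[i]}, obs={obs[i]}"
        )
    return np.log10(pred / obs)


def afe(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Average fold error, 10^(mean log10(pred/obs))."""
    return float(10.0 ** np.mean(_log_ratios(pred, obs)))


def aafe(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Absolute average fold error, 10^(mean |log10(pred/obs)|)."""
    return float(10.0 ** np.mean(np.abs(_log_ratios(pred, obs))))


def gmfe(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Pooled geometric mean fold error — identical in form to AAFE, applied
    to ratios pooled across PK outputs and datasets."""
    return aafe(pred, obs)


def summary_stats(
    pred: Sequence[float], obs: Sequence[float], fold: float = 3.0
) -> dict[str, Optional[float]]:
    """%-within-fold, r² (squared Pearson on raw values) and the AAFE/AFE pair."""
    lr = _log_ratios(pred, obs)
    within = 100.0 * float(np.mean(np.abs(lr) <= math.log10(fold)))
    out: dict[str, Optional[float]] = {
        "afe": float(10.0 ** lr.mean()),
        "aafe": float(10.0 ** np.abs(lr).mean()),
        "pct_within_fold": within,
        "n": len(lr),
        "r2": None,
    }
    if len(lr) >= 2:
        p = np.asarray(pred, dtype=float)
        o = np.asarray(obs, dtype=float)
        if np.ptp(p) > 0 and np.ptp(o) > 0:
            r, _ = stats.pearsonr(p, o)
            out["r2"] = float(r * r)
        else:
            out["r2"] = 1.0 if np.allclose(p / o, p[0] / o[0]) else None
    return out


@dataclass
class AccuracyReport:
    """Table-style grid: per PK output × configuration accuracy statistics."""

    rows: dict[str, dict[str, dict]] = field(default_factory=dict)
    gmfe: dict[str, float] = field(default_factory=dict)
    fold: float = 3.0

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for metric, by_cfg in self.rows.items():
            for cfg, cell in by_cfg.items():
                records.append({"metric": metric, "configuration": cfg, **cell})
        return pd.DataFrame.from_records(records)


def accuracy_report(
    observed: Mapping[str, PKOutputs],
    simulated: Mapping[str, Mapping[str, PKOutputs]],
    fold: float = 3.0,
    log_r2: bool = False,
) -> AccuracyReport:
    """Build the accuracy grid across distribution configurations.

    ``observed`` maps dataset_id → NCA outputs of the observed profile;
    ``simulated`` maps configuration name → {dataset_id → NCA outputs}.
    Datasets whose observed profile is terminal-insufficient contribute to
    the first-order rows but are excluded from AUC0-inf/MRT/Vdss rows.
    ``log_r2`` computes r² on log10-transformed values instead of raw ones.
    """
    report = AccuracyReport(fold=fold)
    for cfg, sims in simulated.items():
        missing = set(observed) - set(sims)
        if missing:
            raise MetricError(
                f"configuration {cfg} missing datasets: {sorted(missing)}"
            )
        pooled_pred: list[float] = []
        pooled_obs: list[float] = []
        for metric in REPORT_METRICS:
            pred, obs = [], []
            for ds_id, obs_out in observed.items():
                if metric in EXTRAPOLATED_METRICS and not obs_out.terminal_sufficient:
                    continue
                o = obs_out.metric(metric)
                p = sims[ds_id].metric(metric)
                if o is None or p is None or o <= 0 or p <= 0:
                    continue
                pred.append(p)
                obs.append(o)
            if not pred:
                continue
            if log_r2:
                cell = summary_stats(pred, obs, fold)
                lp, lo = np.log10(pred), np.log10(obs)
                if len(lp) >= 2 and np.ptp(lp) > 0 and np.ptp(lo) > 0:
                    r, _ = stats.pearsonr(lp, lo)
                    cell["r2"] = float(r * r)
            else:
                cell = summary_stats(pred, obs, fold)
            report.rows.setdefault(metric, {})[cfg] = cell
            pooled_pred.extend(pred)
            pooled_obs.extend(obs)
        report.gmfe[cfg] = gmfe(pooled_pred, pooled_obs)
    return report


def kp_method_comparison(
    set_a: Sequence[PartitionSet],
    set_b: Sequence[PartitionSet],
    tissue: str,
) -> dict[str, Optional[float]]:
    """Compare two partitioning methods for one tissue across compounds.

    Ordinary least squares of log10 Kp_b on log10 Kp_a (pairing by position),
    plus the mean absolute fold difference 10^(mean |log10(Kp_b/Kp_a)|).
    """
    if len(set_a) != len(set_b):
        raise MetricError("partition-set lists must pair by compound")
    a = np.array([s.kp[tissue] for s in set_a])
    b = np.array([s.kp[tissue] for s in set_b])
    if np.any(a <= 0) or np.any(b <= 0):
        raise MetricError("Kp values must be positive")
    la, lb = np.log10(a), np.log10(b)
    out: dict[str, Optional[float]] = {
        "slope": None,
        "intercept": None,
        "r2": None,
        "mean_abs_fold_difference": float(10.0 ** np.mean(np.abs(lb - la))),
        "n": len(a),
    }
    if len(a) >= 2 and np.ptp(la) > 0:
        res = stats.linregress(la, lb)
        out["slope"] = float(res.slope)
        out["intercept"] = float(res.intercept)
        out["r2"] = float(res.rvalue**2)
    return out
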