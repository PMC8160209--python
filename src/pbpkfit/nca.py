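"""Non-compartmental analysis of concentration-time profiles.

Model-free PK summaries: Cmax/Tmax by scan, AUC and AUMC by the linear
trapezoid rule, terminal slope by log-linear least squares, and the
extrapolated outputs AUC0-inf, AUMC0-inf, MRT = AUMC/AUC and
Vdss = Dose·MRT/AUC.  Extrapolated outputs are only reported when the
terminal phase is sufficiently sampled: the last observed concentration must
have fallen below 0.25·Cmax, or the post-peak window must span at least two
terminal half-lives.  Observed and simulated profiles go through the same
code path so that accuracy comparisons are like-for-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Terminal-phase sufficiency: last concentration below this fraction of Cmax.
TERMINAL_CONC_FRACTION = 0.25
#: ... or the post-Tmax window spans at least this many terminal half-lives.
TERMINAL_HALFLIFE_SPAN = 2.0


class NCAError(ValueError):
    pass


@dataclass(frozen=True)
class ConcentrationSeries:
    """One dose-arm plasma concentration-time profile (observed or simulated).

    Times in h (strictly increasing, non-negative), concentrations in µg/L,
    dose in µg.
    """

    dataset_id: str
    times: np.ndarray
    conc: np.ndarray
    dose: float
    route: str = "iv_bolus"
    compound: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        if self.times.shape != self.conc.shape or self.times.ndim != 1:
            raise NCAError("times and conc must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise NCAError(f"times not strictly increasing in {self.dataset_id}")
        if len(self.times) and self.times[0] < 0:
            raise NCAError("negative time")
        if np.any(self.conc < 0):
            raise NCAError(f"negative concentration in {self.dataset_id}")
        if not self.dose > 0:
            raise NCAError("dose must be > 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PKOutputs:
    """NCA summary for one profile; extrapolated fields absent (None) when the
    terminal phase is insufficiently sampled."""

    dataset_id: str
    cmax: float  # µg/L
    tmax: float  # h
    auc_0t: float  # µg·h/L
    aumc_0t: float  # µg·h²/L
    route: str = "iv_bolus"
    lambda_z: Optional[float] = None  # 1/h
    auc_inf: Optional[float] = None
    aumc_inf: Optional[float] = None
    mrt: Optional[float] = None  # h
    vdss: Optional[float] = None  # L
    terminal_sufficient: bool = False
    sufficiency_basis: tuple[str, ...] = field(default_factory=tuple)

    def metric(self, name: str) -> Optional[float]:
        return getattr(self, name)


def auc_linear_trapezoid(series: ConcentrationSeries) -> float:
    """Linear-trapezoid AUC0-t, µg·h/L."""
    if len(series) < 2:
        raise NCAError("NCA requires at least 2 points")
    return float(np.trapezoid(series.conc, series.times))


def aumc_linear_trapezoid(series: ConcentrationSeries) -> float:
    """Linear-trapezoid AUMC0-t (area under t·C), µg·h²/L."""
    if len(series) < 2:
        raise NCAError("NCA requires at least 2 points")
    return float(np.trapezoid(series.times * series.conc, series.times))


def _loglinear_fit(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of ln(c) on t and its r²."""
    ln_c = np.log(c)
    slope, intercept = np.polyfit(t, ln_c, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((ln_c - pred) ** 2))
    ss_tot = float(np.sum((ln_c - ln_c.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def terminal_slope(
    series: ConcentrationSeries, n_points: int = 3, max_points: int = 6
) -> Optional[float]:
    """Terminal elimination rate constant λz (1/h), or None.

    Log-linear least squares on the last ``n_points`` positive concentrations
    after Tmax, extended one point at a time while the fit r² improves (up to
    ``max_points``).  Requires at least 3 usable points and a positive slope
    of decline.
    """
    i_max = int(np.argmax(series.conc))
    idx = np.nonzero(series.conc > 0)[0]
    idx = idx[idx > i_max]
    if len(idx) < n_points or n_points < 3:
        return None
    t, c = series.times[idx], series.conc[idx]
    best_lz, best_r2 = None, -np.inf
    for n in range(n_points, min(max_points, len(idx)) + 1):
        slope, r2 = _loglinear_fit(t[-n:], c[-n:])
        if r2 > best_r2:
            best_r2, best_lz = r2, -slope
        else:
            break  # adding earlier points stopped helping
    if best_lz is None or best_lz <= 0:
        return None
    return best_lz


def compute_pk_outputs(series: ConcentrationSeries) -> PKOutputs:
    """Full NCA of one profile, applying the terminal-sufficiency rule.

    MRT and Vdss are computed for oral profiles too (MRT then includes mean
    absorption time); the route tag lets downstream reporting distinguish.
    """
    i_max = int(np.argmax(series.conc))  # ties -> earliest time
    cmax = float(series.conc[i_max])
    tmax = float(series.times[i_max])
    out = PKOutputs(
        dataset_id=series.dataset_id,
        cmax=cmax,
        tmax=tmax,
        auc_0t=auc_linear_trapezoid(series),
        aumc_0t=aumc_linear_trapezoid(series),
        route=series.route,
    )
    lz = terminal_slope(series)
    out.lambda_z = lz
    basis = []
    if series.conc[-1] < TERMINAL_CONC_FRACTION * cmax:
        basis.append("conc_below_quarter_cmax")
    if lz is not None and (series.times[-1] - tmax) >= (
        TERMINAL_HALFLIFE_SPAN * math.log(2) / lz
    ):
        basis.append("two_halflives_spanned")
    out.sufficiency_basis = tuple(basis)
    out.terminal_sufficient = bool(basis)
    if out.terminal_sufficient and lz is not None:
        c_last = float(series.conc[-1])
        t_last = float(series.times[-1])
        out.auc_inf = out.auc_0t + c_last / lz
        out.aumc_inf = out.aumc_0t + c_last * t_last / lz + c_last / lz**2
        out.mrt = out.aumc_inf / out.auc_inf
        out.vdss = series.dose * out.mrt / out.auc_inf
    return out
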