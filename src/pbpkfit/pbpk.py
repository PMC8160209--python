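"""Whole-body 14-compartment PBPK simulation.

Each organ is a well-mixed, perfusion-limited compartment.  For a
non-eliminating tissue the mass balance is

    V_t dC_t/dt = Q_t (C_ab - C_t · B:P / (Kpu_t · fup))

where C_ab is afferent (arterial) blood concentration and the second term is
the venous outflow at its partition-equilibrium blood concentration; note
Kpu_t·fup = Kp_t, so C_out,blood = C_t·B:P/Kp_t.  Liver and kidney carry an
additional elimination term −CL_organ · C_out,blood.  The lung sits in series
between venous and arterial blood; gut and spleen drain portally into the
liver, so oral first-pass loss emerges mechanistically.  Oral doses enter a
gut-lumen depot with first-order absorption (rate ka) and fraction f_oral
reaching gut tissue; IV boluses are initial conditions in venous blood and
infusions a constant-rate venous input.

All mechanisms are linear, so the system is integrated as dA/dt = M·A + u(t)
(amount basis, µg) with an adaptive stiff-capable solver and the exact
Jacobian M.  Cumulative hepatic, renal and unabsorbed amounts are carried as
extra states, making the mass-balance residual directly observable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .nca import ConcentrationSeries
from .partition import IonizationSpec, PartitionSet
from .physiology import (
    COMPARTMENTS,
    PORTAL_TISSUES,
    SubjectPhysiology,
    TISSUES,
)

ROUTES = ("iv_bolus", "iv_infusion", "oral")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CompoundProfile:
    """Drug-specific inputs: physicochemistry plus PK parameters.

    ``cl_hepatic`` lumps hepatic metabolism and biliary elimination into a
    single blood clearance (L/h, referenced to liver outflow blood);
    ``f_oral`` is the fraction of an oral dose reaching portal blood
    (fraction absorbed × gut escape) — hepatic first pass is simulated, not
    folded into f_oral.
    """

    name: str
    logp: float
    ionization: IonizationSpec
    fup: float
    bp_ratio: float
    cl_hepatic: float = 0.0
    cl_renal: float = 0.0
    ka: float = 1.0  # 1/h
    f_oral: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fup <= 1.0:
            raise ValueError(f"fup={self.fup} outside (0, 1]")
        if not self.bp_ratio > 0:
            raise ValueError("bp_ratio must be > 0")
        if self.cl_hepatic < 0 or self.cl_renal < 0:
            raise ValueError("clearances must be >= 0")
        if not self.ka > 0:
            raise ValueError("ka must be > 0")
        if not 0.0 < self.f_oral <= 1.0:
            raise ValueError(f"f_oral={self.f_oral} outside (0, 1]")


@dataclass(frozen=True)
class DoseEvent:
    route: str
    amount: float  # µg
    start_time: float = 0.0  # h
    duration: float = 0.0  # h; > 0 only for iv_infusion

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route: {self.route}")
        if not self.amount > 0:
            raise ValueError("dose amount must be > 0")
        if self.duration < 0 or (self.duration > 0 and self.route != "iv_infusion"):
            raise ValueError("duration > 0 only for iv_infusion")
        if self.route == "iv_infusion" and not self.duration > 0:
            raise ValueError("iv_infusion requires duration > 0")


# state vector layout: the 14 compartments, then bookkeeping states
_EXTRA = ("gut_lumen", "elim_hepatic", "elim_renal", "elim_unabsorbed")
STATE_NAMES = COMPARTMENTS + _EXTRA
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)


@dataclass
class SimulationResult:
    times: np.ndarray  # h
    amounts: dict[str, np.ndarray]  # µg per state over times
    venous_plasma: ConcentrationSeries  # µg/L
    dose_total: float  # µg administered
    diagnostics: dict = field(default_factory=dict)

    def total_in_body(self) -> np.ndarray:
        """Amount in the 14 body compartments (excludes lumen and eliminated)."""
        return sum(self.amounts[c] for c in COMPARTMENTS)

    def total_eliminated(self) -> np.ndarray:
        return (
            self.amounts["elim_hepatic"]
            + self.amounts["elim_renal"]
            + self.amounts["elim_unabsorbed"]
        )

    def mass_balance_residual(self) -> np.ndarray:
        """|administered − (body + lumen + eliminated)| / administered."""
        accounted = (
            self.total_in_body() + self.amounts["gut_lumen"] + self.total_eliminated()
        )
        dosed = self.diagnostics["dose_administered_by_time"]
        scale = max(self.dose_total, 1e-300)
        return np.abs(dosed - accounted) / scale


def _build_matrix(
    compound: CompoundProfile,
    physiology: SubjectPhysiology,
    partition_set: PartitionSet,
) -> np.ndarray:
    """Constant coefficient matrix M of dA/dt = M·A (+ inputs)."""
    missing = [t for t in TISSUES if t not in partition_set.kp]
    if missing:
        raise SimulationError(f"partition set missing Kp for: {', '.join(missing)}")
    bp = compound.bp_ratio
    tis = physiology.tissues
    co = physiology.cardiac_output
    m = np.zeros((N_STATES, N_STATES))

    def k_out(t: str) -> float:
        # venous-outflow blood concentration per unit tissue amount, 1/L
        return bp / (partition_set.kp[t] * tis[t].volume)

    i_ven, i_art, i_lung = _IDX["venous_blood"], _IDX["arterial_blood"], _IDX["lung"]
    inv_v_ven = 1.0 / tis["venous_blood"].volume
    inv_v_art = 1.0 / tis["arterial_blood"].volume

    # lung in series: venous -> lung -> arterial
    m[i_lung, i_ven] += co * inv_v_ven
    m[i_ven, i_ven] -= co * inv_v_ven
    m[i_art, i_lung] += co * k_out("lung")
    m[i_lung, i_lung] -= co * k_out("lung")

    liver_inflow = 0.0
    for t in TISSUES:
        if t == "lung":
            continue
        i_t = _IDX[t]
        q = tis[t].blood_flow
        m[i_t, i_art] += q * inv_v_art
        m[i_art, i_art] -= q * inv_v_art
        if t in PORTAL_TISSUES:  # drains into liver
            m[_IDX["liver"], i_t] += q * k_out(t)
            m[i_t, i_t] -= q * k_out(t)
            liver_inflow += q
        elif t == "liver":
            liver_inflow += q
        else:
            m[i_ven, i_t] += q * k_out(t)
            m[i_t, i_t] -= q * k_out(t)

    i_liv = _IDX["liver"]
    m[i_ven, i_liv] += liver_inflow * k_out("liver")
    m[i_liv, i_liv] -= liver_inflow * k_out("liver")

    # elimination: separate -CL_organ * C_out,blood terms with running totals
    if compound.cl_hepatic > 0:
        rate = compound.cl_hepatic * k_out("liver")
        m[i_liv, i_liv] -= rate
        m[_IDX["elim_hepatic"], i_liv] += rate
    if compound.cl_renal > 0:
        i_kid = _IDX["kidney"]
        rate = compound.cl_renal * k_out("kidney")
        m[i_kid, i_kid] -= rate
        m[_IDX["elim_renal"], i_kid] += rate

    # oral absorption from the gut-lumen depot
    i_lum = _IDX["gut_lumen"]
    m[i_lum, i_lum] -= compound.ka
    m[_IDX["gut"], i_lum] += compound.f_oral * compound.ka
    m[_IDX["elim_unabsorbed"], i_lum] += (1.0 - compound.f_oral) * compound.ka
    return m


def _rk4_fixed(rhs, t0, t1, y0, h):
    """Classic fixed-step RK4 over [t0, t1]; parity mode for the legacy
    fixed-step integration (not the default path)."""
    n = max(1, int(math.ceil((t1 - t0) / h)))
    h = (t1 - t0) / n
    y = y0.copy()
    t = t0
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


def simulate(
    compound: CompoundProfile,
    physiology: SubjectPhysiology,
    partition_set: PartitionSet,
    doses: Sequence[DoseEvent],
    t_end: float,
    output_times: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    fixed_step: Optional[float] = None,
    dataset_id: str = "sim",
) -> SimulationResult:
    """Integrate the whole-body model and return per-compartment amounts plus
    the venous plasma concentration series.

    ``output_times`` defaults to 601 evenly spaced points on [0, t_end].
    ``fixed_step`` switches to a fixed-step RK4 integration at that step (h)
    for parity with legacy fixed-step runs; the default is adaptive LSODA
    with the exact Jacobian.
    """
    if not doses:
        raise SimulationError("at least one dose event required")
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 601)
    output_times = np.asarray(output_times, dtype=float)
    if output_times[0] < 0 or output_times[-1] > t_end + 1e-12:
        raise SimulationError("output_times must lie in [0, t_end]")

    m = _build_matrix(compound, physiology, partition_set)
    i_ven, i_lum = _IDX["venous_blood"], _IDX["gut_lumen"]

    # segment boundaries at every dose start/stop
    breaks = {0.0, float(t_end)}
    for d in doses:
        breaks.add(min(d.start_time, t_end))
        if d.route == "iv_infusion":
            breaks.add(min(d.start_time + d.duration, t_end))
    breaks = sorted(breaks)

    y = np.zeros(N_STATES)
    out = np.empty((N_STATES, len(output_times)))
    dosed_by_time = np.zeros(len(output_times))
    dosed_so_far = 0.0
    n_steps = 0

    for seg_start, seg_end in zip(breaks[:-1], breaks[1:]):
        # instantaneous doses at the segment start
        for d in doses:
            if abs(d.start_time - seg_start) < 1e-12:
                if d.route == "iv_bolus":
                    y[i_ven] += d.amount
                    dosed_so_far += d.amount
                elif d.route == "oral":
                    y[i_lum] += d.amount
                    dosed_so_far += d.amount
        u = np.zeros(N_STATES)
        infusion_rate = 0.0
        for d in doses:
            if (
                d.route == "iv_infusion"
                and d.start_time <= seg_start + 1e-12
                and seg_end <= d.start_time + d.duration + 1e-12
            ):
                rate = d.amount / d.duration
                u[i_ven] += rate
                infusion_rate += rate

        mask = (output_times >= seg_start - 1e-12) & (output_times <= seg_end + 1e-12)
        t_eval_seg = output_times[mask]
        rhs = lambda t, yy: m @ yy + u  # noqa: E731

        if fixed_step is not None:
            prev_t, cur = seg_start, y.copy()
            vals = []
            for te in t_eval_seg:
                cur = _rk4_fixed(rhs, prev_t, te, cur, fixed_step)
                vals.append(cur.copy())
                prev_t = te
            y = _rk4_fixed(rhs, prev_t, seg_end, cur, fixed_step)
            if vals:
                out[:, mask] = np.array(vals).T
        else:
            need_end = not len(t_eval_seg) or abs(t_eval_seg[-1] - seg_end) > 1e-12
            t_eval = (
                np.append(t_eval_seg, seg_end) if need_end else t_eval_seg
            )
            sol = solve_ivp(
                rhs,
                (seg_start, seg_end),
                y,
                method="LSODA",
                t_eval=np.clip(t_eval, seg_start, seg_end),
                jac=lambda t, yy: m,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"solver failed on [{seg_start}, {seg_end}]: {sol.message}"
                )
            n_steps += sol.nfev
            if len(t_eval_seg):
                out[:, mask] = sol.y[:, : len(t_eval_seg)]
            y = sol.y[:, -1]
        dosed_by_time[mask] = dosed_so_far
        if infusion_rate > 0:
            dosed_by_time[mask] += infusion_rate * (t_eval_seg - seg_start)
            dosed_so_far += infusion_rate * (seg_end - seg_start)

    amounts = {name: out[_IDX[name]] for name in STATE_NAMES}
    dose_total = sum(d.amount for d in doses)
    v_ven = physiology.tissues["venous_blood"].volume
    # negative values at round-off level are clipped in the reported series
    plasma = amounts["venous_blood"] / v_ven / compound.bp_ratio
    result = SimulationResult(
        times=output_times,
        amounts=amounts,
        venous_plasma=ConcentrationSeries(
            dataset_id=dataset_id,
            times=output_times,
            conc=np.maximum(plasma, 0.0),
            dose=dose_total,
            route=doses[0].route,
            compound=compound.name,
        ),
        dose_total=dose_total,
        diagnostics={
            "nfev": n_steps,
            "dose_administered_by_time": dosed_by_time,
            "venous_volume": v_ven,
            "bp_ratio": compound.bp_ratio,
        },
    )
    result.diagnostics["max_mass_residual"] = float(
        result.mass_balance_residual().max()
    )
    return result


def venous_plasma_series(
    result: SimulationResult, bp_ratio: float, dataset_id: Optional[str] = None
) -> ConcentrationSeries:
    """Venous *plasma* concentration (µg/L): blood concentration / B:P."""
    v_ven = result.diagnostics["venous_volume"]
    conc = result.amounts["venous_blood"] / v_ven / bp_ratio
    return replace(
        result.venous_plasma,
        conc=np.maximum(conc, 0.0),
        dataset_id=dataset_id or result.venous_plasma.dataset_id,
    )


def analytic_vdss(
    physiology: SubjectPhysiology,
    partition_set: PartitionSet,
    compound: CompoundProfile,
) -> float:
    """Plasma-referenced steady-state distribution volume of the model.

    At distribution equilibrium with plasma concentration C_p, blood holds
    (V_ven + V_art)·B:P·C_p and each tissue V_t·Kp_t·C_p, so
    Vdss = (V_ven + V_art)·B:P + Σ_t V_t·Kp_t.
    """
    tis = physiology.tissues
    v_blood = tis["venous_blood"].volume + tis["arterial_blood"].volume
    return v_blood * compound.bp_ratio + sum(
        tis[t].volume * partition_set.kp[t] for t in TISSUES
    )
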