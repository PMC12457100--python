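"""Per-subject calibration: initial-condition allocation and RMSE fits.

The observed quantity is tumor volume, so a single measured volume must be
divided among the model populations to seed a simulation.  For untreated
(control) animals the population fractions at small volumes are known from
the experimental reference: ``f_T = 0.96`` tumor cells, ``f_A = 0.035``
microglia (assumed entirely anti-tumor initially) and ``f_P = 0.005`` MDM.
Treated animals start at far larger volumes (mean ~41.5 mm^3 versus ~3
mm^3), so their initial fractions are predicted from linear regressions of
population proportion on relative volume, learned from the fitted control
trajectories.

Free parameters are estimated per subject by minimizing the RMSE between
model volume and the observed volume series with a derivative-free simplex
search (Nelder-Mead): ``rho_T`` alone for control subjects, ``(rho_T,
S_T)`` jointly for irradiated subjects.  Fits run on unconstrained scales
(``log rho_T``, ``logit S_T``) and use a small deterministic multi-start
to guard against local minima (an engineering addition over the original
single-start procedure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import (
    ModelParams,
    PopulationState,
    Trajectory,
    simulate,
)
from .radiation import Schedule

__all__ = [
    "SubjectRecord",
    "InitialFractions",
    "FitResult",
    "ProportionMaps",
    "DEFAULT_FRACTIONS",
    "allocate_initial_state",
    "proportion_regression",
    "fit_control",
    "fit_treated",
    "records_from_frame",
    "fit_report_frame",
]

#: Minimum observation count for a fit (subjects with fewer are excluded).
MIN_POINTS = 3

#: Solver tolerances used inside the fitting loop (looser than the
#: reporting default for speed; the objective is volume RMSE in mm^3).
FIT_RTOL = 1e-6
FIT_ATOL = 1.0


@dataclass(frozen=True)
class SubjectRecord:
    """Observed (time, volume) series for one animal."""

    subject_id: str
    group: str  # "control" | "treated"
    times: Tuple[float, ...]
    volumes: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.group not in ("control", "treated"):
            raise ValueError("group must be 'control' or 'treated'")
        t = tuple(float(x) for x in self.times)
        v = tuple(float(x) for x in self.volumes)
        if len(t) != len(v):
            raise ValueError("times and volumes must have equal length")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        if any(x <= 0 for x in v):
            raise ValueError("volumes must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)

    @property
    def first_volume(self) -> float:
        return self.volumes[0]

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class InitialFractions:
    """Population (count) fractions used to split an observed volume."""

    f_T: float = 0.96
    f_A: float = 0.035
    f_P: float = 0.005

    def __post_init__(self) -> None:
        for name in ("f_T", "f_A", "f_P"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not math.isclose(self.f_T + self.f_A + self.f_P, 1.0, rel_tol=1e-9):
            raise ValueError("fractions of the modeled pools must sum to 1")


#: Experimental fractions for untreated tumors at small volume.
DEFAULT_FRACTIONS = InitialFractions()


@dataclass
class FitResult:
    """Outcome of a per-subject RMSE fit."""

    subject_id: str
    group: str
    rho_T: float
    s_t: Optional[float]  # None for control fits
    rmse: float
    residuals: np.ndarray  # model - observed, per time point (mm^3)
    n_points: int
    converged: bool
    n_iter: int
    fractions: InitialFractions = field(default=DEFAULT_FRACTIONS)

    def objective_from_residuals(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))


def allocate_initial_state(
    V0: float, fractions: InitialFractions, params: ModelParams
) -> PopulationState:
    """Split an observed volume ``V0`` into initial compartment counts.

    ``T0 = f_T * V0 / (v_T f_T + v_A f_A + v_P f_P)`` and analogously for
    ``A0`` and ``P0``, with all macrophage unit volumes equal to ``v_M``.
    ``P0`` is divided equally between the MG-derived and MDM-derived
    subpopulations; the damaged pools start empty.  The reconstructed
    volume equals ``V0`` exactly (to roundoff).
    """
    if V0 <= 0:
        raise ValueError("V0 must be positive")
    denom = (
        params.v_T * fractions.f_T
        + params.v_M * fractions.f_A
        + params.v_M * fractions.f_P
    )
    if denom <= 0:
        raise ValueError("unit volumes produce a zero denominator")
    n_total = V0 / denom
    P0 = fractions.f_P * n_total
    return PopulationState(
        T=fractions.f_T * n_total,
        P1=0.5 * P0,
        P2=0.5 * P0,
        A=fractions.f_A * n_total,
    )


@dataclass(frozen=True)
class ProportionMaps:
    """Linear maps from relative tumor volume to population fractions.

    One ordinary-least-squares line per population, fitted on pooled
    control-trajectory samples of (V/V_max, count fraction).  Predictions
    are clipped to [0, 1] and renormalized to sum to 1.
    """

    coef: Dict[str, Tuple[float, float]]  # name -> (slope, intercept)

    def predict(self, relative_volume: float) -> InitialFractions:
        x = float(relative_volume)
        raw = {
            k: np.clip(m * x + b, 0.0, 1.0) for k, (m, b) in self.coef.items()
        }
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("all predicted fractions are zero")
        return InitialFractions(
            f_T=raw["f_T"] / total,
            f_A=raw["f_A"] / total,
            f_P=raw["f_P"] / total,
        )


def proportion_regression(
    control_trajectories: Sequence[Trajectory],
) -> ProportionMaps:
    """Learn fraction-versus-relative-volume lines from control dynamics.

    Each fitted control trajectory contributes samples of the live-pool
    count fractions (``T``, ``A``, ``P = P1+P2``) against its volume
    expressed as a fraction of the maximum volume it reaches.  Samples are
    pooled across trajectories and each fraction regressed on relative
    volume by OLS.
    """
    if len(control_trajectories) < 2:
        raise ValueError("need at least two control trajectories")
    xs: List[np.ndarray] = []
    fracs = {"f_T": [], "f_A": [], "f_P": []}
    for traj in control_trajectories:
        vols = traj.volumes()
        vmax = vols.max()
        if vmax <= 0:
            raise ValueError("trajectory with non-positive volume")
        T = traj.states[:, 0]
        P = traj.states[:, 1] + traj.states[:, 2]
        A = traj.states[:, 3]
        live = T + P + A
        ok = live > 0
        xs.append(vols[ok] / vmax)
        fracs["f_T"].append(T[ok] / live[ok])
        fracs["f_A"].append(A[ok] / live[ok])
        fracs["f_P"].append(P[ok] / live[ok])
    x = np.concatenate(xs)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate predictor: relative volume is constant")
    coef = {}
    for name, ys in fracs.items():
        y = np.concatenate(ys)
        slope, intercept = np.polyfit(x, y, 1)
        coef[name] = (float(slope), float(intercept))
    return ProportionMaps(coef=coef)


def _rmse(model_v: np.ndarray, obs_v: np.ndarray) -> float:
    return float(np.sqrt(np.mean((model_v - obs_v) ** 2)))


def _simulate_volumes(
    record: SubjectRecord,
    params: ModelParams,
    fractions: InitialFractions,
    schedule: Optional[Schedule],
    rtol: float,
    atol: float,
) -> np.ndarray:
    t0 = record.times[0]
    rel_times = np.asarray(record.times, float) - t0
    initial = allocate_initial_state(record.first_volume, fractions, params)
    if schedule is not None and t0 != 0.0:
        schedule = schedule.replace(
            ir_times=tuple(tj - t0 for tj in schedule.ir_times)
        )
    horizon = float(rel_times[-1]) if rel_times[-1] > 0 else 1.0
    traj = simulate(
        initial,
        params,
        schedule=schedule,
        horizon=horizon,
        output_grid=rel_times,
        rtol=rtol,
        atol=atol,
    )
    return traj.volume_at(rel_times)


def _nelder_mead(objective, x0: np.ndarray, max_iter: int = 500):
    return minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "xatol": 1e-6,
            "fatol": 1e-8,
            "adaptive": False,
        },
    )


def _check_record(record: SubjectRecord, group: str) -> None:
    if record.group != group:
        raise ValueError(f"record {record.subject_id} is not in group {group!r}")
    if record.n_points < MIN_POINTS:
        raise ValueError(
            f"record {record.subject_id} has {record.n_points} points; "
            f"at least {MIN_POINTS} are required for fitting"
        )


def fit_control(
    record: SubjectRecord,
    fixed: ModelParams,
    fractions: InitialFractions = DEFAULT_FRACTIONS,
    rho_T_init: float = 4.0e-4,
    n_starts: int = 3,
    max_iter: int = 500,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> FitResult:
    """Fit ``rho_T`` for an untreated subject by RMSE minimization.

    The initial state is allocated from the first observed volume with the
    control fractions; the simplex search runs on ``log rho_T`` from a few
    deterministic starting points around ``rho_T_init``.
    """
    _check_record(record, "control")
    obs = np.asarray(record.volumes, float)

    def objective(x: np.ndarray) -> float:
        p = fixed.replace(rho_T=float(np.exp(x[0])))
        try:
            model_v = _simulate_volumes(record, p, fractions, None, rtol, atol)
        except Exception:
            return 1e12
        return _rmse(model_v, obs)

    starts = [math.log(rho_T_init * f) for f in (1.0, 0.4, 2.5)][:n_starts]
    best = None
    for s in starts:
        res = _nelder_mead(objective, np.array([s]), max_iter)
        if best is None or res.fun < best.fun:
            best = res
    rho = float(np.exp(best.x[0]))
    model_v = _simulate_volumes(
        record, fixed.replace(rho_T=rho), fractions, None, rtol, atol
    )
    return FitResult(
        subject_id=record.subject_id,
        group="control",
        rho_T=rho,
        s_t=None,
        rmse=float(best.fun),
        residuals=model_v - obs,
        n_points=record.n_points,
        converged=bool(best.success),
        n_iter=int(best.nit),
        fractions=fractions,
    )


def fit_treated(
    record: SubjectRecord,
    fixed: ModelParams,
    schedule_template: Schedule,
    proportion_maps: Optional[ProportionMaps] = None,
    reference_max_volume: Optional[float] = None,
    fractions: Optional[InitialFractions] = None,
    rho_T_init: float = 4.0e-4,
    s_t_init: float = 0.5,
    n_starts: int = 3,
    max_iter: int = 500,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> FitResult:
    """Fit ``(rho_T, S_T)`` jointly for an irradiated subject.

    Initial fractions come either from ``fractions`` directly or from the
    proportion regressions evaluated at the subject's first volume
    relative to the reference control's maximum volume (ratio clipped to
    1).  The schedule template fixes the fraction times; the subject's
    ``S_T`` is the second free parameter.
    """
    _check_record(record, "treated")
    if fractions is None:
        if proportion_maps is None or reference_max_volume is None:
            raise ValueError(
                "either fractions or (proportion_maps, reference_max_volume) "
                "must be supplied"
            )
        rel = min(record.first_volume / reference_max_volume, 1.0)
        fractions = proportion_maps.predict(rel)
    obs = np.asarray(record.volumes, float)

    def objective(x: np.ndarray) -> float:
        rho = float(np.exp(x[0]))
        s_t = float(1.0 / (1.0 + np.exp(-x[1])))
        p = fixed.replace(rho_T=rho)
        sched = schedule_template.replace(s_t=s_t)
        try:
            model_v = _simulate_volumes(record, p, fractions, sched, rtol, atol)
        except Exception:
            return 1e12
        return _rmse(model_v, obs)

    def logit(p: float) -> float:
        return math.log(p / (1.0 - p))

    start_list = [
        (math.log(rho_T_init), logit(s_t_init)),
        (math.log(rho_T_init * 0.4), logit(min(s_t_init * 1.4, 0.9))),
        (math.log(rho_T_init * 2.5), logit(s_t_init * 0.6)),
    ][:n_starts]
    best = None
    for s in start_list:
        res = _nelder_mead(objective, np.array(s), max_iter)
        if best is None or res.fun < best.fun:
            best = res
    rho = float(np.exp(best.x[0]))
    s_t = float(1.0 / (1.0 + np.exp(-best.x[1])))
    model_v = _simulate_volumes(
        record,
        fixed.replace(rho_T=rho),
        fractions,
        schedule_template.replace(s_t=s_t),
        rtol,
        atol,
    )
    return FitResult(
        subject_id=record.subject_id,
        group="treated",
        rho_T=rho,
        s_t=s_t,
        rmse=float(best.fun),
        residuals=model_v - obs,
        n_points=record.n_points,
        converged=bool(best.success),
        n_iter=int(best.nit),
        fractions=fractions,
    )


def records_from_frame(df: pd.DataFrame) -> List[SubjectRecord]:
    """Build subject records from a long-format cohort table.

    Required columns: ``subject_id``, ``group``, ``day``, ``volume_mm3``.
    """
    required = {"subject_id", "group", "day", "volume_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    records = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("day")
        group = str(sub["group"].iloc[0])
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                group=group,
                times=tuple(sub["day"].astype(float)),
                volumes=tuple(sub["volume_mm3"].astype(float)),
            )
        )
    return records


def fit_report_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    """Flatten fit results into the report table dialect."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "group": [r.group for r in results],
            "rho_T": [r.rho_T for r in results],
            "S_T": [r.s_t if r.s_t is not None else np.nan for r in results],
            "rmse": [r.rmse for r in results],
            "n_points": [r.n_points for r in results],
            "converged": [r.converged for r in results],
        }
    )
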