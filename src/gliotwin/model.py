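"""Core tumor-macrophage dynamical system.

The model tracks six cell populations inside a growing glioma:

* ``T``  — tumor cells,
* ``P1`` — microglia-derived pro-tumor macrophages (hijacked MG),
* ``P2`` — monocyte-derived pro-tumor macrophages (infiltrating MDM),
* ``A``  — anti-tumor macrophages (initially the resident microglia),
* ``TD`` — radiation-damaged tumor cells,
* ``MD`` — radiation-damaged macrophages.

Tumor and macrophage populations are locked in a cooperative feedback:
each proliferates Gompertzianly only in the presence of the other, with
per-capita rate proportional to ``ln(K / V)`` where ``V`` is total tumor
volume and ``K`` the carrying capacity.  Anti-tumor macrophages kill tumor
cells at rate ``mu``; the tumor converts them to the pro-tumor phenotype
through a saturating (Michaelis-Menten) term; MDM influx from the
vasculature is proportional to tumor burden (``phi * T``); tumor expansion
recruits fresh microglia (the ``xi`` coupling); macrophages decay with
lifespan ``tau_M``.  Damaged pools decay exponentially and contribute to
volume but not to any interaction.

The pro-tumor pool is split into ``P1 + P2`` purely to track provenance
(MG versus MDM); the split never alters the pooled dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace, field
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .therapies import (
    EffectiveModifiers,
    TherapyModifiers,
    resolve_modifiers,
)

__all__ = [
    "ModelParams",
    "PopulationState",
    "Trajectory",
    "InvalidStateError",
    "IntegrationError",
    "MU_CONTROL",
    "MU_IR",
    "volume",
    "rhs",
    "simulate",
]

#: Tumor-killing rate presets (per day per cell) for the two experimental
#: groups: untreated control tumors versus the irradiated group, whose
#: larger tumors sit in a more immunosuppressed microenvironment.
MU_CONTROL = 1.2e-4
MU_IR = 5e-7


class InvalidStateError(ValueError):
    """A state or derivative evaluated to a non-finite value."""


class IntegrationError(RuntimeError):
    """The adaptive solver failed; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and geometry of the tumor-macrophage system.

    All rates are per day; unit volumes in mm^3 per cell; time constants
    in days.  ``rho_T`` is the per-subject free parameter; ``phi`` is the
    only parameter mutated during a simulation (escalated at IR fractions).

    The default set is the package's own calibration (most fixed values are
    not identifiable from volumetric data alone); it is chosen so that the
    synthetic study conditions hold: control tumors grow from ~3 mm^3
    toward fatal volumes within weeks, irradiated tumors regrow after a
    5-fraction course, MDM dominate the macrophage pool at recurrence, and
    macrophage-mediated killing stays below ~0.6 %/day under the IR-group
    ``mu`` preset.
    """

    rho_T: float = 3.0e-4     # tumor proliferation coefficient (/d/cell)
    rho_P: float = 1.0e-7     # pro-tumor macrophage proliferation (/d/cell)
    rho_A: float = 2.0e-7     # anti-tumor macrophage proliferation (/d/cell)
    mu: float = MU_CONTROL    # tumor killing by A (/d/cell)
    lam: float = 3.0e-6       # MG -> pro-tumor conversion coefficient
    K_lam: float = 1.0e4      # conversion saturation constant (cells)
    phi: float = 3.0e-4       # MDM influx coefficient (/d); escalates at IR
    xi: float = 5.0e-4        # MG recruitment per net new tumor cell
    tau_M: float = 15.0       # macrophage lifespan (d)
    K: float = 300.0          # carrying capacity (mm^3)
    v_T: float = 1.0e-4       # unit volume, tumor cell (mm^3)
    v_M: float = 1.0e-4       # unit volume, macrophage / damaged cell (mm^3)
    tau_TD: float = 3.0       # damaged tumor cell clearance (d)
    tau_MD: float = 3.0       # damaged macrophage clearance (d)
    S_M: float = 0.8          # macrophage survival fraction per IR fraction
    phi_D: float = 2.0e-3     # inflammation flux from damaged cells to A (/d)
    # Numerical / structural switches (not biology):
    conversion_form: str = "saturating"  # or "michaelis": lam*A*T/(K_lam+T)
    clamp_recruitment: bool = True       # clamp xi*dT/dt at 0 when dT/dt < 0

    def __post_init__(self) -> None:
        positive = (
            "rho_T rho_P rho_A mu lam K_lam xi tau_M K v_T v_M "
            "tau_TD tau_MD phi_D"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if not 0.0 <= self.S_M <= 1.0:
            raise ValueError("S_M must lie in [0, 1]")
        if self.conversion_form not in ("saturating", "michaelis"):
            raise ValueError("conversion_form must be 'saturating' or 'michaelis'")

    def replace(self, **changes) -> "ModelParams":
        return _dc_replace(self, **changes)

    def for_group(self, group: str) -> "ModelParams":
        """Return a copy with the mu preset for 'control' or 'treated'."""
        if group == "control":
            return self.replace(mu=MU_CONTROL)
        if group in ("treated", "ir"):
            return self.replace(mu=MU_IR)
        raise ValueError(f"unknown group {group!r}")

    def conversion_rate(self, T: float, A: float, lam_eff: float) -> float:
        """A->P conversion flux: saturating Michaelis-Menten in T."""
        if T <= 0 or A == 0:
            return 0.0
        if self.conversion_form == "saturating":
            return lam_eff * A * T * self.K_lam / (self.K_lam + T)
        return lam_eff * A * T / (self.K_lam + T)


class PopulationState(NamedTuple):
    """Instantaneous cell counts of the six compartments."""

    T: float
    P1: float
    P2: float
    A: float
    TD: float = 0.0
    MD: float = 0.0

    @property
    def P(self) -> float:
        """Pooled pro-tumor macrophages (MG-derived + MDM-derived)."""
        return self.P1 + self.P2

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "PopulationState":
        return cls(*(float(v) for v in y))

    def validate(self) -> None:
        for name, v in zip(self._fields, self):
            if not math.isfinite(v):
                raise InvalidStateError(f"compartment {name} is not finite")
            if v < 0:
                raise InvalidStateError(f"compartment {name} is negative")


STATE_FIELDS = PopulationState._fields


def volume(state, params: ModelParams) -> float:
    """Total tumor volume (mm^3): live + damaged cells weighted by unit volume.

    ``V = v_T*(T + TD) + v_M*(P1 + P2 + A + MD)``.  Before any IR event the
    damaged pools are empty and this is the live-cell volume law.
    """
    T, P1, P2, A, TD, MD = state
    return params.v_T * (T + TD) + params.v_M * (P1 + P2 + A + MD)


def rhs(
    t: float,
    state,
    params: ModelParams,
    modifiers: Optional[Sequence[TherapyModifiers] | TherapyModifiers | EffectiveModifiers] = None,
    ir_active: bool = False,
) -> np.ndarray:
    """Right-hand side of the system (counts per day).

    ``modifiers`` may be raw therapy windows (resolved at ``t``) or an
    already-resolved :class:`EffectiveModifiers`.  ``ir_active`` enables
    the inflammation flux ``phi_D * (TD + MD)`` into A, present from the
    first delivered IR fraction onward (before IR the damaged pools are
    empty, so the flag only makes the activation explicit).
    """
    if isinstance(modifiers, EffectiveModifiers):
        eff = modifiers
    else:
        eff = resolve_modifiers(modifiers, t)

    T, P1, P2, A, TD, MD = (max(float(v), 0.0) for v in state)
    P = P1 + P2
    V = params.v_T * (T + TD) + params.v_M * (P + A + MD)

    # Degenerate/empty system: growth terms vanish rather than ln(K/0).
    lnKV = math.log(params.K / V) if V > 0 else 0.0

    mu_eff = eff.mu_eff(params.mu)
    conv = params.conversion_rate(T, A, eff.lambda_eff(params.lam))

    dT = params.rho_T * T * P * lnKV - mu_eff * T * A

    # Microglia recruitment follows tumor expansion into new tissue; by
    # default a shrinking tumor recruits nothing (clamped at zero).
    growth = dT
    if params.clamp_recruitment and growth < 0:
        growth = 0.0

    dP1 = params.rho_P * P1 * T * lnKV + conv - P1 / params.tau_M
    dP2 = params.rho_P * P2 * T * lnKV + params.phi * T - P2 / params.tau_M
    dA = (
        params.rho_A * A * T * lnKV
        - conv
        + params.xi * growth
        - A / params.tau_M
    )
    if ir_active:
        dA += params.phi_D * (TD + MD)
    dTD = -TD / params.tau_TD
    dMD = -MD / params.tau_MD

    out = np.array([dT, dP1, dP2, dA, dTD, dMD])
    if not np.all(np.isfinite(out)):
        bad = STATE_FIELDS[int(np.argmax(~np.isfinite(out)))]
        raise InvalidStateError(
            f"non-finite derivative in compartment {bad} at t={t:g} (V={V:g})"
        )
    return out


@dataclass
class Trajectory:
    """Simulated time course on an output grid, with the applied events.

    ``states`` has one row per time point, columns in ``STATE_FIELDS``
    order.  ``event_log`` records each IR fraction (pre/post snapshots and
    phi escalation) and therapy-window boundary crossed.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams
    event_log: List[dict] = field(default_factory=list)

    def volumes(self) -> np.ndarray:
        p = self.params
        s = self.states
        return p.v_T * (s[:, 0] + s[:, 4]) + p.v_M * (
            s[:, 1] + s[:, 2] + s[:, 3] + s[:, 5]
        )

    def state_at(self, t: float) -> PopulationState:
        """Linearly interpolated state at time ``t`` within the span."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(
                f"t={t:g} outside trajectory span "
                f"[{self.times[0]:g}, {self.times[-1]:g}]"
            )
        row = [np.interp(t, self.times, self.states[:, j]) for j in range(6)]
        return PopulationState.from_array(row)

    def volume_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.volumes())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time_d", self.times)
        df["volume_mm3"] = self.volumes()
        return df


def _integrate_segment(y0, t0, t1, params, eff, ir_active, rtol, atol, grid):
    """Integrate the smooth system on [t0, t1].

    Returns ``(t_points, states, y_end)`` where ``t_points``/``states``
    are the reported samples inside the segment (the requested grid points
    if a grid was given, else the solver's natural adaptive points) and
    ``y_end`` is the exact state at ``t1`` used to continue integration.
    """
    if t1 <= t0:
        return np.empty(0), np.empty((0, 6)), y0
    fun = lambda t, y: rhs(t, y, params, eff, ir_active)
    if grid is not None:
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        # always integrate to t1 so the next segment starts exactly there
        need_end = len(t_eval) == 0 or t_eval[-1] < t1
        t_req = np.append(t_eval, t1) if need_end else t_eval
    else:
        t_eval = None
        t_req = None
        need_end = False
    sol = solve_ivp(
        fun,
        (t0, t1),
        y0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=t_req,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed: {sol.message}", last_valid_time=float(sol.t[-1])
        )
    y_end = sol.y[:, -1]
    if grid is not None and need_end:
        return sol.t[:-1], sol.y[:, :-1].T, y_end
    return sol.t, sol.y.T, y_end


def simulate(
    initial: PopulationState,
    params: ModelParams,
    schedule=None,
    horizon: float = 100.0,
    output_grid: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-3,
) -> Trajectory:
    """Integrate the system over ``[0, horizon]`` applying scheduled events.

    Integration proceeds piecewise with an adaptive explicit Runge-Kutta
    4(5) solver between consecutive events.  At each IR fraction time the
    impulsive survival-fraction map is applied (instantaneous transfer of
    ``1-S`` of each population to its damaged pool and escalation of the
    MDM-influx coefficient ``phi``), and integration restarts from the
    mapped state.  Therapy windows toggle the effective ``mu``/``lambda``/
    attenuation at their boundaries.

    Parameters
    ----------
    schedule : Schedule, optional
        IR fraction times, per-subject tumor survival fraction ``S_T`` and
        therapy windows.  ``None`` means untreated.
    output_grid : array, optional
        Times (days) at which the trajectory is reported.  Defaults to the
        solver's natural (adaptive) points plus event times.

    Returns
    -------
    Trajectory
    """
    from .radiation import Schedule, apply_ir_fraction  # local: avoid cycle

    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if schedule is None:
        schedule = Schedule()
    initial = PopulationState(*initial)
    initial.validate()

    modifiers = schedule.therapy_windows
    # Breakpoints: IR fractions and therapy window boundaries inside span.
    breaks = set()
    for tj in schedule.ir_times:
        if not 0.0 <= tj <= horizon:
            raise ValueError(f"IR fraction time {tj} outside [0, horizon]")
        breaks.add(float(tj))
    for mod in modifiers:
        start, end = mod.window
        if 0.0 < start < horizon:
            breaks.add(float(start))
        if end is not None and 0.0 < end < horizon:
            breaks.add(float(end))
    times = sorted(breaks | {0.0, float(horizon)})

    ir_times = set(float(tj) for tj in schedule.ir_times)
    grid = None if output_grid is None else np.asarray(output_grid, float)

    y = initial.as_array()
    work = params
    ir_active = False
    out_t: List[np.ndarray] = []
    out_y: List[np.ndarray] = []
    event_log: List[dict] = []

    for a, b in zip(times[:-1], times[1:]):
        if a in ir_times:
            pre = PopulationState.from_array(y)
            eff = resolve_modifiers(modifiers, a)
            phi_pre = work.phi
            post, work = apply_ir_fraction(pre, work, schedule.s_t, eff)
            ir_active = True
            event_log.append(
                {
                    "time": a,
                    "kind": "ir_fraction",
                    "pre": pre,
                    "post": post,
                    "phi_pre": phi_pre,
                    "phi_post": work.phi,
                }
            )
            y = post.as_array()
        elif a != 0.0:
            event_log.append({"time": a, "kind": "window_boundary"})

        eff = resolve_modifiers(modifiers, a)
        y = np.maximum(y, 0.0)
        seg_t, seg_y, y = _integrate_segment(
            y, a, b, work, eff, ir_active, rtol, atol, grid
        )
        out_t.append(seg_t)
        out_y.append(seg_y)

    t_all = np.concatenate(out_t) if out_t else np.array([0.0])
    y_all = np.vstack(out_y) if out_y else y[None, :]
    # De-duplicate points shared by adjacent segments.  Keep the *last*
    # occurrence so the reported state at an event time is the post-impulse
    # one (right-continuous convention for impulsive systems).
    keep = np.ones(len(t_all), bool)
    keep[:-1] = np.diff(t_all) > 0
    t_all, y_all = t_all[keep], y_all[keep]
    y_all = np.maximum(y_all, 0.0)
    return Trajectory(times=t_all, states=y_all, params=params, event_log=event_log)
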