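"""Impulsive radiotherapy: fraction schedules and the survival-fraction map.

Each IR fraction is modeled as an instantaneous event at time ``t_j``:

* a fraction ``1 - S_T`` of tumor cells transfers to the damaged pool
  ``TD`` and a fraction ``1 - S_M`` of all live macrophages (pro- and
  anti-tumor alike) transfers to ``MD`` — total cell count is conserved at
  the instant;
* the MDM-influx coefficient ``phi`` escalates by ``1/S_T`` (vascular
  damage recruits monocytes in proportion to therapeutic efficacy), unless
  an active therapy attenuates the escalation.

Damaged cells keep contributing to tumor volume but lose all functional
behavior; they clear exponentially with time constants ``tau_TD`` and
``tau_MD``.  Escalation compounds multiplicatively over a course: after
``n`` unmodified fractions ``phi = phi_0 * (1/S_T)**n``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Optional, Tuple

from .model import ModelParams, PopulationState
from .therapies import EffectiveModifiers, NEUTRAL, TherapyModifiers

__all__ = ["Schedule", "apply_ir_fraction", "standard_course"]

#: The standard course: five daily fractions.
STANDARD_N_FRACTIONS = 5
STANDARD_INTERVAL_DAYS = 1.0
STANDARD_START_DAY = 1.0


@dataclass(frozen=True)
class Schedule:
    """IR fraction times, per-subject radiosensitivity and therapy windows.

    Parameters
    ----------
    ir_times : tuple of float
        Strictly increasing fraction times (days).  Empty = untreated.
    s_t : float
        Tumor-cell survival fraction per fraction, in (0, 1]; the
        per-subject measure of treatment effectiveness.
    therapy_windows : tuple of TherapyModifiers
        Myeloid-therapy windows active during the simulation.
    """

    ir_times: Tuple[float, ...] = ()
    s_t: float = 1.0
    therapy_windows: Tuple[TherapyModifiers, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.s_t <= 1.0:
            raise ValueError("s_t must lie in (0, 1]")
        times = tuple(float(t) for t in self.ir_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("ir_times must be strictly increasing")
        object.__setattr__(self, "ir_times", times)
        object.__setattr__(
            self, "therapy_windows", tuple(self.therapy_windows)
        )

    def replace(self, **changes) -> "Schedule":
        return _dc_replace(self, **changes)

    def with_therapies(self, *mods: TherapyModifiers) -> "Schedule":
        return self.replace(therapy_windows=self.therapy_windows + mods)


def standard_course(
    s_t: float,
    start_day: float = STANDARD_START_DAY,
    n_fractions: int = STANDARD_N_FRACTIONS,
    interval_days: float = STANDARD_INTERVAL_DAYS,
    therapy_windows: Tuple[TherapyModifiers, ...] = (),
) -> Schedule:
    """Schedule of ``n_fractions`` fractions spaced ``interval_days`` apart.

    The standard protocol is five daily fractions starting on day 1;
    protracted radiotherapy varies the inter-fraction interval only.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    times = tuple(start_day + k * interval_days for k in range(n_fractions))
    return Schedule(ir_times=times, s_t=s_t, therapy_windows=therapy_windows)


def apply_ir_fraction(
    state: PopulationState,
    params: ModelParams,
    s_t: float,
    modifiers: Optional[EffectiveModifiers] = None,
) -> Tuple[PopulationState, ModelParams]:
    """Impulsive map applied at one IR fraction time.

    Returns the post-impulse ``(state, params)``:

    * ``T+ = S_T*T-``, ``TD+ = TD- + (1-S_T)*T-``;
    * ``P1+ = S_M*P1-``, ``P2+ = S_M*P2-``, ``A+ = S_M*A-``,
      ``MD+ = MD- + (1-S_M)*(P1- + P2- + A-)``;
    * ``phi+ = phi- * esc`` with unmodified escalation ``esc = 1/S_T``;
      an active influx attenuation ``a`` gives ``esc = 1 + a*(1/S_T - 1)``.

    Total cell count is conserved exactly at the instant.
    """
    if not 0.0 < s_t <= 1.0:
        raise ValueError("s_t must lie in (0, 1]")
    eff = NEUTRAL if modifiers is None else modifiers
    s_m = params.S_M
    T, P1, P2, A, TD, MD = state
    post = PopulationState(
        T=s_t * T,
        P1=s_m * P1,
        P2=s_m * P2,
        A=s_m * A,
        TD=TD + (1.0 - s_t) * T,
        MD=MD + (1.0 - s_m) * (P1 + P2 + A),
    )
    new_params = params.replace(phi=params.phi * eff.escalation(s_t))
    return post, new_params
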