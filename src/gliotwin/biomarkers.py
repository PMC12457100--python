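"""In silico analogues of the experimental biomarker panel.

The reference experiments report group-level percentages of macrophages
(Iba1+), apoptotic cells (CC3+), proliferating glioma cells (Ki67+) and
the MG/MDM split (CD49d-/CD49d+) at four epochs: untreated control, end of
the 5-day IR course, 21 days after IR initiation, and tumor recurrence.
The model-side definitions below are this package's own count-based
formulas (versioned here, not taken from any external source):

* ``macrophage_pct``   = 100 * (P1+P2+A+MD) / (T+TD+P1+P2+A+MD)
* ``apoptosis_pct``    = 100 * (TD+MD) / (T+TD+P1+P2+A+MD)
* ``proliferation_pct``= 100 * rho_T * P * ln(K/V) * tau_cycle, clipped to
  [0, 100] — the instantaneous per-cell growth rate converted to a
  Ki67-like labeled fraction via a cell-cycle window ``tau_cycle``
  (default 1 day)
* ``killing_pct``      = 100 * mu_eff * A — the per-day fractional loss of
  tumor cells to the macrophage kill term
* ``mg_pct``/``mdm_pct`` partition the *live* macrophage pool into
  microglia-derived (A + P1) and monocyte-derived (P2) parts; they sum to
  100 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelParams, PopulationState, Trajectory
from .therapies import EffectiveModifiers, resolve_modifiers

__all__ = [
    "BiomarkerPanel",
    "panel",
    "killing_pct",
    "time_averaged_killing",
    "epoch_times",
    "panel_frame",
]

#: Cell-cycle window (days) converting instantaneous per-cell growth rate
#: into a Ki67-like labeled fraction.
TAU_CYCLE_DAYS = 1.0


@dataclass(frozen=True)
class BiomarkerPanel:
    """One subject's panel at one named epoch."""

    subject_id: str
    epoch: str
    macrophage_pct: float
    apoptosis_pct: float
    proliferation_pct: float
    killing_pct_per_day: float
    mg_pct: float
    mdm_pct: float


def killing_pct(
    state: PopulationState,
    params: ModelParams,
    modifiers=None,
    t: float = 0.0,
) -> float:
    """Percent of tumor cells killed per day by anti-tumor macrophages.

    ``100 * mu_eff * A``: the per-day fractional loss of T to the kill
    term, independent of T itself.
    """
    eff = (
        modifiers
        if isinstance(modifiers, EffectiveModifiers)
        else resolve_modifiers(modifiers, t)
    )
    return 100.0 * eff.mu_eff(params.mu) * state.A


def panel(
    traj: Trajectory,
    t: float,
    params: Optional[ModelParams] = None,
    modifiers=None,
    subject_id: str = "",
    epoch: str = "",
    tau_cycle: float = TAU_CYCLE_DAYS,
) -> BiomarkerPanel:
    """Evaluate the biomarker panel at time ``t`` of a trajectory."""
    params = traj.params if params is None else params
    state = traj.state_at(t)  # raises if t outside span
    T, P1, P2, A, TD, MD = state
    total = T + TD + P1 + P2 + A + MD
    mac = P1 + P2 + A + MD
    macrophage = 100.0 * mac / total if total > 0 else 0.0
    apoptosis = 100.0 * (TD + MD) / total if total > 0 else 0.0

    V = params.v_T * (T + TD) + params.v_M * (P1 + P2 + A + MD)
    lnKV = math.log(params.K / V) if 0 < V else 0.0
    prolif = 100.0 * params.rho_T * (P1 + P2) * max(lnKV, 0.0) * tau_cycle
    prolif = float(np.clip(prolif, 0.0, 100.0))

    live_mac = P1 + P2 + A
    if live_mac > 0:
        mg = 100.0 * (A + P1) / live_mac
        mdm = 100.0 * P2 / live_mac
    else:
        mg, mdm = 0.0, 0.0

    return BiomarkerPanel(
        subject_id=subject_id,
        epoch=epoch,
        macrophage_pct=macrophage,
        apoptosis_pct=apoptosis,
        proliferation_pct=prolif,
        killing_pct_per_day=killing_pct(state, params, modifiers, t),
        mg_pct=mg,
        mdm_pct=mdm,
    )


def time_averaged_killing(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    modifiers=None,
) -> float:
    """Trapezoidal time-average of ``killing_pct`` over the trajectory span."""
    params = traj.params if params is None else params
    t = traj.times
    if len(t) < 2 or t[-1] <= t[0]:
        raise ValueError("trajectory span is empty")
    vals = np.array(
        [
            killing_pct(
                PopulationState.from_array(traj.states[i]),
                params,
                modifiers,
                float(t[i]),
            )
            for i in range(len(t))
        ]
    )
    return float(np.trapezoid(vals, t) / (t[-1] - t[0]))


def epoch_times(
    traj: Trajectory,
    ir_times: Sequence[float],
    day21_offset: float = 21.0,
) -> Dict[str, Optional[float]]:
    """Locate the four reporting epochs on a treated trajectory.

    * ``control``   — first time point (pre-treatment baseline);
    * ``post_course`` ("5 d") — end of the IR course (last fraction time);
    * ``day21``     — ``day21_offset`` days after IR initiation;
    * ``recurrence``— first time after the course at which volume
      re-attains its value at the first fraction (None if never).
    """
    t0 = float(traj.times[0])
    out: Dict[str, Optional[float]] = {"control": t0}
    if len(ir_times) == 0:
        out.update(post_course=None, day21=None, recurrence=None)
        return out
    first, last = float(ir_times[0]), float(ir_times[-1])
    out["post_course"] = min(last, float(traj.times[-1]))
    day21 = first + day21_offset
    out["day21"] = day21 if day21 <= traj.times[-1] else None

    v_pre = float(traj.volume_at(first))
    t = traj.times
    v = traj.volumes()
    mask = t > last
    rec = None
    if mask.any():
        idx = np.nonzero(mask & (v >= v_pre))[0]
        if len(idx) > 0:
            i = idx[0]
            if i > 0 and v[i] > v_pre and v[i - 1] < v_pre:
                # linear interpolation to the crossing
                f = (v_pre - v[i - 1]) / (v[i] - v[i - 1])
                rec = float(t[i - 1] + f * (t[i] - t[i - 1]))
            else:
                rec = float(t[i])
    out["recurrence"] = rec
    return out


def panel_frame(panels: Sequence[BiomarkerPanel]) -> pd.DataFrame:
    """Flatten panels into the CSV dialect."""
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in panels],
            "epoch": [p.epoch for p in panels],
            "macrophage_pct": [p.macrophage_pct for p in panels],
            "apoptosis_pct": [p.apoptosis_pct for p in panels],
            "proliferation_pct": [p.proliferation_pct for p in panels],
            "killing_pct": [p.killing_pct_per_day for p in panels],
            "mg_pct": [p.mg_pct for p in panels],
            "mdm_pct": [p.mdm_pct for p in panels],
        }
    )
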