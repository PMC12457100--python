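"""Virtual cohorts with the statistical structure of the mouse study.

The generator emulates the shape of the volumetric dataset the model was
built for: 4 untreated animals starting near 3 mm^3 and 10 irradiated
animals with much larger initial volumes (mean 41.5 mm^3), each observed
at 4-7 irregular time points, with inter-subject heterogeneity placed in
the tumor proliferation rate (log-normal), heterogeneous radiosensitivity
(uniform ``S_T``), and multiplicative log-normal measurement noise on
volume (default sigma = 0.1, i.e. ~10 % volumetric error typical of
small-animal volumetry).  The generated ground-truth table makes the
cohort usable as a parameter-recovery oracle for the fitting pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import epoch_times, panel, panel_frame
from .fitting import (
    DEFAULT_FRACTIONS,
    InitialFractions,
    SubjectRecord,
    allocate_initial_state,
)
from .model import ModelParams, Trajectory, simulate
from .radiation import Schedule, standard_course
from .trials import DEATH_THRESHOLD_FACTOR, DigitalTwin

__all__ = ["CohortSpec", "generate_cohort", "generate_biomarker_groups",
           "twins_from_truth"]


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the virtual cohort.

    Defaults mirror the reference study: 4 controls around 3 mm^3, 10
    treated animals with mean initial volume 41.5 mm^3, 4-7 irregular
    observation points per subject, proliferation-rate heterogeneity and
    per-subject radiosensitivity.

    The proliferation-rate distribution is group-specific.  Because the
    growth law couples tumor cells bilinearly to pro-tumor macrophages
    (whose count scales with tumor volume), a subject starting at 41.5
    mm^3 carries a ~14x larger macrophage pool than one starting at 3
    mm^3; comparable growth *rates* therefore require a much smaller
    per-cell coefficient in the treated group — the same reasoning that
    motivates the group-specific killing-rate presets.
    """

    n_control: int = 4
    n_treated: int = 10
    rho_T_median: float = 3.0e-4          # control group
    treated_rho_T_median: float = 5.0e-6  # treated group (see note below)
    rho_T_log_sd: float = 0.25
    s_t_range: Tuple[float, float] = (0.55, 0.8)
    control_v0_median: float = 3.0
    control_v0_log_sd: float = 0.2
    treated_v0_mean: float = 41.5
    treated_v0_log_sd: float = 0.3
    n_points_range: Tuple[int, int] = (4, 7)
    control_span_days: float = 16.0
    ir_start_day: float = 1.0
    n_fractions: int = 5
    noise_sigma: float = 0.1
    params: ModelParams = field(default_factory=ModelParams)
    fractions: InitialFractions = DEFAULT_FRACTIONS
    seed: int = 0

    def replace(self, **changes) -> "CohortSpec":
        return _dc_replace(self, **changes)

    @property
    def treated_v0_median(self) -> float:
        """Log-normal median giving the requested arithmetic mean."""
        return self.treated_v0_mean * math.exp(-0.5 * self.treated_v0_log_sd**2)


def _sample_times(
    rng: np.random.Generator, n_points: int, span: float
) -> np.ndarray:
    """Irregular sampling: day 0, sorted interior draws, and the endpoint.

    The last observation falls exactly at the follow-up endpoint,
    mirroring a study that follows each animal to its humane endpoint.
    """
    interior = np.sort(rng.uniform(2.0, span - 2.0, size=n_points - 2))
    times = np.concatenate([[0.0], interior, [span]])
    # enforce >= 1 day separation to keep records well conditioned
    for i in range(1, len(times)):
        if times[i] - times[i - 1] < 1.0:
            times[i] = times[i - 1] + 1.0
    times[-1] = span
    return times


#: Treated follow-up runs until the tumor re-exceeds this multiple of its
#: baseline volume (the regrowth endpoint), capped at MAX_FOLLOWUP_DAYS.
REGROWTH_ENDPOINT_FACTOR = 1.5
MAX_FOLLOWUP_DAYS = 150.0


def _treated_followup_span(
    s_t: float, v0: float, rho_T: float, spec: "CohortSpec"
) -> float:
    """First time the treated tumor regrows past 1.5x baseline.

    Animals are followed to their endpoint, so the observation span is
    subject-specific: the time at which post-IR regrowth passes
    ``REGROWTH_ENDPOINT_FACTOR * V0`` (floored at 15 days, capped at
    ``MAX_FOLLOWUP_DAYS``).  This keeps the last observation the largest,
    as in the reference data, makes the 1.2x death threshold exceed the
    initial volume, and keeps it well below the carrying capacity.
    """
    params = spec.params.for_group("treated").replace(rho_T=rho_T)
    initial = allocate_initial_state(v0, spec.fractions, params)
    schedule = standard_course(
        s_t, start_day=spec.ir_start_day, n_fractions=spec.n_fractions
    )
    grid = np.arange(0.0, MAX_FOLLOWUP_DAYS + 0.5, 0.5)
    traj = simulate(
        initial, params, schedule=schedule, horizon=MAX_FOLLOWUP_DAYS,
        output_grid=grid, rtol=1e-6, atol=1.0,
    )
    v = traj.volumes()
    after = traj.times > schedule.ir_times[-1]
    hit = after & (v >= REGROWTH_ENDPOINT_FACTOR * v0)
    if hit.any():
        t_cross = float(traj.times[int(np.argmax(hit))])
    else:
        t_cross = MAX_FOLLOWUP_DAYS
    return float(min(max(15.0, t_cross), MAX_FOLLOWUP_DAYS))


def _simulate_subject(
    sid: str,
    group: str,
    rho_T: float,
    s_t: float,
    v0: float,
    times: np.ndarray,
    spec: CohortSpec,
    rtol: float = 1e-8,
    atol: float = 1e-3,
) -> Tuple[Trajectory, np.ndarray, Optional[Schedule]]:
    params = spec.params.for_group(group).replace(rho_T=rho_T)
    initial = allocate_initial_state(v0, spec.fractions, params)
    schedule = None
    if group == "treated":
        schedule = standard_course(
            s_t, start_day=spec.ir_start_day, n_fractions=spec.n_fractions
        )
    horizon = float(times[-1])
    grid = np.union1d(np.arange(0.0, horizon + 0.25, 0.25), times)
    grid = grid[grid <= horizon]
    traj = simulate(
        initial, params, schedule=schedule, horizon=horizon,
        output_grid=grid, rtol=rtol, atol=atol,
    )
    true_v = traj.volume_at(times)
    return traj, true_v, schedule


def generate_cohort(
    spec: CohortSpec,
) -> Tuple[List[SubjectRecord], pd.DataFrame]:
    """Draw a cohort, simulate the true model, and sample noisy volumes.

    Returns the subject records (long-format observations) and a
    ground-truth table with columns ``subject_id, group, true_rho_T,
    true_S_T, V0, final_volume, n_points, seed``; ``final_volume`` is the
    noiseless model volume at the subject's last observation time (the
    basis of the digital-twin death threshold).
    """
    records: List[SubjectRecord] = []
    truth_rows = []
    plan = [("control", i) for i in range(spec.n_control)] + [
        ("treated", i) for i in range(spec.n_treated)
    ]
    # Per-subject independent substreams, with noise separated from the
    # design draws so changing noise_sigma leaves the design invariant.
    children = np.random.SeedSequence(spec.seed).spawn(len(plan))
    for (group, i), child in zip(plan, children):
        design_seed, noise_seed = child.spawn(2)
        rng = np.random.default_rng(design_seed)
        rng_noise = np.random.default_rng(noise_seed)
        sid = f"{group[0].upper()}{i + 1:02d}"
        median = (
            spec.rho_T_median if group == "control"
            else spec.treated_rho_T_median
        )
        rho = median * math.exp(rng.normal(0.0, spec.rho_T_log_sd))
        if group == "control":
            v0 = spec.control_v0_median * math.exp(
                rng.normal(0.0, spec.control_v0_log_sd)
            )
            span = spec.control_span_days
            s_t = 1.0
        else:
            v0 = spec.treated_v0_median * math.exp(
                rng.normal(0.0, spec.treated_v0_log_sd)
            )
            s_t = rng.uniform(*spec.s_t_range)
            span = _treated_followup_span(s_t, v0, rho, spec)
        n_pts = int(rng.integers(spec.n_points_range[0],
                                 spec.n_points_range[1] + 1))
        times = _sample_times(rng, n_pts, span)
        _, true_v, _ = _simulate_subject(sid, group, rho, s_t, v0, times, spec)
        noise = (
            np.exp(rng_noise.normal(0.0, spec.noise_sigma, size=len(times)))
            if spec.noise_sigma > 0
            else np.ones(len(times))
        )
        obs = true_v * noise
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                times=tuple(times),
                volumes=tuple(obs),
            )
        )
        truth_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "true_rho_T": rho,
                "true_S_T": s_t if group == "treated" else np.nan,
                "V0": v0,
                "final_volume": float(true_v[-1]),
                "n_points": n_pts,
                "seed": spec.seed,
            }
        )
    return records, pd.DataFrame(truth_rows)


def twins_from_truth(
    truth: pd.DataFrame, spec: CohortSpec, group: str = "treated"
) -> List[DigitalTwin]:
    """Ground-truth digital twins (no fitting): one per subject in ``group``.

    The death threshold is the ground-truth trajectory's final sampled
    volume increased by 20 %, mirroring the use of the last experimental
    observation.
    """
    twins = []
    for _, row in truth[truth["group"] == group].iterrows():
        params = spec.params.for_group(group).replace(
            rho_T=float(row["true_rho_T"])
        )
        initial = allocate_initial_state(
            float(row["V0"]), spec.fractions, params
        )
        s_t = float(row["true_S_T"]) if group == "treated" else 1.0
        twins.append(
            DigitalTwin(
                subject_id=str(row["subject_id"]),
                params=params,
                s_t=s_t,
                initial_state=initial,
                death_threshold=DEATH_THRESHOLD_FACTOR
                * float(row["final_volume"]),
                reference_schedule=standard_course(
                    s_t,
                    start_day=spec.ir_start_day,
                    n_fractions=spec.n_fractions,
                )
                if group == "treated"
                else None,
            )
        )
    return twins


def generate_biomarker_groups(
    truth: pd.DataFrame,
    spec: CohortSpec,
    epochs: Sequence[str] = ("control", "post_course", "day21", "recurrence"),
    noise_sd: float = 0.0,
    horizon: float = 120.0,
) -> pd.DataFrame:
    """Group-level biomarker panels of the treated cohort at named epochs.

    Re-simulates each treated subject's ground-truth trajectory to the
    given horizon, evaluates the in silico panel at each epoch, and adds
    optional additive Gaussian measurement noise (percent scale, clipped
    at 0).  Returns one row per subject x epoch.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for _, row in truth[truth["group"] == "treated"].iterrows():
        sid = str(row["subject_id"])
        rho = float(row["true_rho_T"])
        s_t = float(row["true_S_T"])
        params = spec.params.for_group("treated").replace(rho_T=rho)
        initial = allocate_initial_state(
            float(row["V0"]), spec.fractions, params
        )
        schedule = standard_course(
            s_t, start_day=spec.ir_start_day, n_fractions=spec.n_fractions
        )
        grid = np.arange(0.0, horizon + 0.25, 0.25)
        traj = simulate(
            initial, params, schedule=schedule, horizon=horizon,
            output_grid=grid, rtol=1e-6, atol=1.0,
        )
        etimes = epoch_times(traj, schedule.ir_times)
        for epoch in epochs:
            t = etimes.get(epoch)
            if t is None:
                continue
            p = panel(traj, t, params, subject_id=sid, epoch=epoch)
            rows.append(p)
    df = panel_frame(rows)
    if noise_sd > 0:
        cols = [c for c in df.columns if c.endswith("_pct") or c == "killing_pct"]
        for c in cols:
            df[c] = np.clip(
                df[c] + rng.normal(0.0, noise_sd, size=len(df)), 0.0, None
            )
    return df
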