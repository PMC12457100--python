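"""Configuration schema and (de)serialization for reproducible runs.

Everything a run needs — model parameters, schedule, therapy windows,
cohort spec, solver tolerances, seeds — round-trips through plain YAML so
a run directory fully describes how its outputs were produced.  Times are
days with origin at the first observation; volumes are mm^3.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .fitting import InitialFractions
from .model import ModelParams
from .radiation import Schedule, standard_course
from .synthetic import CohortSpec
from .therapies import (
    TherapyModifiers,
    alpha_cd49d,
    anti_cd47,
    csf1r_inhibitor,
)

__all__ = [
    "params_from_dict",
    "params_to_dict",
    "schedule_from_dict",
    "therapy_from_dict",
    "cohort_spec_from_dict",
    "load_config",
    "dump_config",
    "log_assumption_notices",
]

logger = logging.getLogger("gliotwin")

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def params_from_dict(d: Optional[Dict[str, Any]]) -> ModelParams:
    d = d or {}
    unknown = set(d) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
    return ModelParams(**d)


def params_to_dict(p: ModelParams) -> Dict[str, Any]:
    return dataclasses.asdict(p)


def therapy_from_dict(d: Dict[str, Any]) -> TherapyModifiers:
    """Build a therapy window from its config block.

    Required key ``therapy`` in {anti_cd47, alpha_cd49d, csf1r, custom};
    ``start``/``end`` give the window (end omitted or null = open-ended).
    """
    d = dict(d)
    kind = d.pop("therapy", None)
    window = (float(d.pop("start", 0.0)), d.pop("end", None))
    if window[1] is not None:
        window = (window[0], float(window[1]))
    if kind == "anti_cd47":
        return anti_cd47(multiplier=float(d.pop("multiplier", 3.0)), window=window)
    if kind == "alpha_cd49d":
        return alpha_cd49d(attenuation=float(d.pop("attenuation", 0.0)), window=window)
    if kind == "csf1r":
        kwargs = {}
        for k in ("mu_multiplier", "attenuation", "lambda_override", "lam"):
            if k in d:
                kwargs[k] = float(d.pop(k))
        return csf1r_inhibitor(window=window, **kwargs)
    if kind == "custom":
        return TherapyModifiers(window=window, **d)
    raise ValueError(f"unknown therapy kind: {kind!r}")


def schedule_from_dict(d: Optional[Dict[str, Any]]) -> Optional[Schedule]:
    """Schedule block: ir_start_day, n_fractions, interval_days, S_T,
    therapy_windows (list of therapy blocks).  ``None``/empty = untreated."""
    if not d:
        return None
    therapies = tuple(
        therapy_from_dict(t) for t in d.get("therapy_windows", [])
    )
    if "ir_times" in d:
        return Schedule(
            ir_times=tuple(float(t) for t in d["ir_times"]),
            s_t=float(d.get("S_T", 1.0)),
            therapy_windows=therapies,
        )
    if d.get("n_fractions", 0):
        return standard_course(
            s_t=float(d.get("S_T", 1.0)),
            start_day=float(d.get("ir_start_day", 1.0)),
            n_fractions=int(d.get("n_fractions", 5)),
            interval_days=float(d.get("interval_days", 1.0)),
            therapy_windows=therapies,
        )
    if therapies:
        return Schedule(therapy_windows=therapies)
    return None


def cohort_spec_from_dict(d: Optional[Dict[str, Any]]) -> CohortSpec:
    d = dict(d or {})
    if "params" in d:
        d["params"] = params_from_dict(d["params"])
    if "fractions" in d:
        d["fractions"] = InitialFractions(**d["fractions"])
    for tup in ("s_t_range", "n_points_range"):
        if tup in d:
            d[tup] = tuple(d[tup])
    return CohortSpec(**d)


def load_config(path: str | Path) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def dump_config(cfg: Dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


_NOTICES = (
    "biomarker panel formulas (macrophage/apoptosis/proliferation/killing "
    "percentages) are package definitions, not experimentally derived",
    "therapy effect magnitudes beyond the anti-CD47 multiplier of 3 "
    "(CSF-1R mu boost, lambda reversal magnitude, alpha-CD49d attenuation) "
    "are documented package assumptions",
    "fixed model parameters other than the printed mu presets are a "
    "package calibration, not reference values",
)


def log_assumption_notices() -> None:
    """Emit the assumption-flagged-default notices once per run."""
    for msg in _NOTICES:
        logger.info("assumption: %s", msg)
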