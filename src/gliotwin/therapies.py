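"""Myeloid-targeted interventions expressed as time-windowed parameter modifiers.

Three TAM-directed therapies are represented, each acting on a distinct term
of the tumor-macrophage system:

* **anti-CD47** — blocks the CD47/SIRPα "don't eat me" axis, enhancing
  macrophage phagocytosis of tumor cells.  Modeled as a multiplier on the
  tumor-killing rate ``mu``.
* **α-CD49d** — neutralizes integrin α4 (the VLA-4 subunit), limiting
  monocyte trafficking into the brain after irradiation.  Modeled as an
  attenuation of the IR-induced escalation of the MDM-influx coefficient
  ``phi``; the baseline (pre-IR) influx is untouched.
* **CSF-1R inhibition** — blockade of the primary growth-factor receptor
  governing macrophage survival and polarization.  Modeled as the
  combination of a ``mu`` boost, a ``phi``-escalation block, and a sign
  reversal of the microglia→pro-tumor conversion coefficient ``lambda``
  (net repolarization of pro-tumor macrophages back to the anti-tumor
  phenotype).

A modifier is *active* on the half-open interval ``[start, end)``; ``end``
may be ``None`` for open-ended (continuous) administration.  Neutral
settings reproduce the unmodified model exactly at the parameter level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

__all__ = [
    "TherapyModifiers",
    "EffectiveModifiers",
    "anti_cd47",
    "alpha_cd49d",
    "csf1r_inhibitor",
    "resolve_modifiers",
]

#: Default multiplier on mu for anti-CD47 (conservative 3x increase in
#: phagocytosis; the CSF-1R mu boost reuses it as a package assumption).
ANTI_CD47_MU_MULTIPLIER = 3.0

#: Default CSF-1R administration window length in days.
CSF1R_WINDOW_DAYS = 12.0


@dataclass(frozen=True)
class TherapyModifiers:
    """Windowed modification of the effective model parameters.

    Parameters
    ----------
    mu_multiplier : float
        Factor applied to the tumor-killing rate ``mu`` while active (>= 0).
    influx_attenuation : float
        Fraction ``a`` in [0, 1] of the IR-induced ``phi`` escalation let
        through: at an IR fraction inside the window the escalation factor
        becomes ``1 + a*(1/S_T - 1)`` instead of ``1/S_T``.  ``a = 1`` is
        no blockade, ``a = 0`` blocks the increase entirely.
    lambda_override : float, optional
        Signed coefficient replacing ``lambda`` while active.  A negative
        value reverses the A→P conversion through the same saturating term.
    window : (float, float or None)
        Active interval ``[start, end)`` in days; ``end=None`` is open-ended.
    label : str
        Identifier used in logs and event records.
    """

    mu_multiplier: float = 1.0
    influx_attenuation: float = 1.0
    lambda_override: Optional[float] = None
    window: Tuple[float, Optional[float]] = (0.0, None)
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.mu_multiplier < 0:
            raise ValueError("mu_multiplier must be >= 0")
        if not 0.0 <= self.influx_attenuation <= 1.0:
            raise ValueError("influx_attenuation must lie in [0, 1]")
        start, end = self.window
        if end is not None and end < start:
            raise ValueError("window end must be >= start")

    def active_at(self, t: float) -> bool:
        start, end = self.window
        return t >= start and (end is None or t < end)

    @property
    def is_neutral(self) -> bool:
        return (
            self.mu_multiplier == 1.0
            and self.influx_attenuation == 1.0
            and self.lambda_override is None
        )


@dataclass(frozen=True)
class EffectiveModifiers:
    """Instantaneous resolved effect of all active therapy windows."""

    mu_multiplier: float = 1.0
    influx_attenuation: float = 1.0
    lambda_override: Optional[float] = None

    def mu_eff(self, mu: float) -> float:
        return self.mu_multiplier * mu

    def lambda_eff(self, lam: float) -> float:
        return lam if self.lambda_override is None else self.lambda_override

    def escalation(self, s_t: float) -> float:
        """Per-fraction multiplier applied to phi at an IR impulse.

        Unmodified escalation is ``1/S_T`` (influx increase proportional to
        therapeutic efficacy); attenuation ``a`` interpolates linearly
        between no increase (a=0) and the full effect (a=1).
        """
        return 1.0 + self.influx_attenuation * (1.0 / s_t - 1.0)


NEUTRAL = EffectiveModifiers()


def resolve_modifiers(
    modifiers: Optional[Sequence[TherapyModifiers] | TherapyModifiers],
    t: float,
) -> EffectiveModifiers:
    """Combine all modifiers active at time ``t`` into one effective set.

    mu multipliers and influx attenuations compose multiplicatively (the
    therapies touch disjoint parameters, so composition is commutative).
    At most one active lambda override is allowed.
    """
    if modifiers is None:
        return NEUTRAL
    if isinstance(modifiers, TherapyModifiers):
        modifiers = (modifiers,)
    mu_mult = 1.0
    atten = 1.0
    lam_override: Optional[float] = None
    for mod in modifiers:
        if not mod.active_at(t):
            continue
        mu_mult *= mod.mu_multiplier
        atten *= mod.influx_attenuation
        if mod.lambda_override is not None:
            if lam_override is not None:
                raise ValueError(
                    "multiple active lambda overrides at t=%g" % t
                )
            lam_override = mod.lambda_override
    return EffectiveModifiers(mu_mult, atten, lam_override)


def anti_cd47(
    multiplier: float = ANTI_CD47_MU_MULTIPLIER,
    window: Tuple[float, Optional[float]] = (0.0, None),
) -> TherapyModifiers:
    """Phagocytosis-boosting antibody: ``mu_eff = multiplier * mu`` in window.

    The default window is open-ended from treatment start, reflecting a
    sustained phenotype change (duration is configurable).
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    return TherapyModifiers(
        mu_multiplier=multiplier, window=window, label="anti_cd47"
    )


def alpha_cd49d(
    attenuation: float = 0.0,
    window: Tuple[float, Optional[float]] = (0.0, None),
) -> TherapyModifiers:
    """Monocyte-trafficking blockade: attenuates IR-induced phi escalation.

    ``attenuation = 0`` (default) fully blocks the IR-induced increase in
    the MDM influx coefficient, the strongest reading of the intervention;
    baseline influx ``phi * T`` continues unchanged.
    """
    return TherapyModifiers(
        influx_attenuation=attenuation, window=window, label="alpha_cd49d"
    )


def csf1r_inhibitor(
    mu_multiplier: float = ANTI_CD47_MU_MULTIPLIER,
    attenuation: float = 0.0,
    lambda_override: Optional[float] = None,
    window: Tuple[float, Optional[float]] = (0.0, CSF1R_WINDOW_DAYS),
    lam: Optional[float] = None,
) -> TherapyModifiers:
    """Composite CSF-1R blockade: mu boost + influx block + lambda reversal.

    ``lambda_override`` defaults to ``-lam`` (equal magnitude, opposite
    sign) when the model's ``lam`` is supplied, inverting the A→P
    conversion.  The mu multiplier defaults to the anti-CD47 value (an
    assumption: the literature reports enhanced phagocytosis without a
    number).  The standard window is 12 days from treatment start;
    ``(start, None)`` models continuous administration.
    """
    if lambda_override is None and lam is not None:
        lambda_override = -lam
    return TherapyModifiers(
        mu_multiplier=mu_multiplier,
        influx_attenuation=attenuation,
        lambda_override=lambda_override,
        window=window,
        label="csf1r",
    )
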