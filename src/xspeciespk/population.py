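"""Population layer: covariate effects, between-subject variability, residual error.

Strain effects are multiplicative fold-changes on typical parameters
(e.g. a 1.34-fold higher clearance in CYP3A4-humanized mice relative to
wild type), matching how such effects are reported. Between-subject
variability is lognormal; the residual model is combined
proportional + additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structural import ConcentrationProfile, PKParameters, ValidationError, _PARAM_FIELDS

__all__ = [
    "CovariateEffect",
    "SubjectCovariates",
    "BSVModel",
    "ErrorModel",
    "apply_covariates",
    "draw_individual",
    "observe",
]

STRAINS = ("WT", "Cyp3aXAV", "human")


@dataclass(frozen=True)
class CovariateEffect:
    """Multiplicative fold-change on one parameter for subjects of one strain."""

    parameter: str
    strain: str
    fold_change: float

    def __post_init__(self):
        if self.parameter not in _PARAM_FIELDS:
            raise ValidationError(f"unknown parameter symbol {self.parameter!r}")
        if self.strain not in STRAINS:
            raise ValidationError(f"unknown strain {self.strain!r}")
        if not self.fold_change > 0:
            raise ValidationError(f"fold_change must be > 0, got {self.fold_change}")

    def matches(self, subject: "SubjectCovariates") -> bool:
        return subject.strain == self.strain


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject covariates; bodyweight in grams."""

    subject_id: str
    strain: str
    bodyweight: float
    dose_group: float = 0.0
    species: str = "mouse"

    def __post_init__(self):
        if self.strain not in STRAINS:
            raise ValidationError(f"unknown strain {self.strain!r}")
        if not self.bodyweight > 0:
            raise ValidationError("bodyweight must be > 0")
        if (self.strain == "human") != (self.species == "human"):
            raise ValidationError("strain 'human' if and only if species 'human'")


@dataclass(frozen=True)
class BSVModel:
    """Lognormal between-subject variability: per-parameter variance omega^2."""

    omega2: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, w2 in self.omega2.items():
            if name not in _PARAM_FIELDS:
                raise ValidationError(f"unknown parameter symbol {name!r}")
            if w2 < 0:
                raise ValidationError(f"omega^2 must be >= 0, got {w2} for {name}")


@dataclass(frozen=True)
class ErrorModel:
    """Residual error: y = c * (1 + eps_prop) + eps_add, sds unitless / ng/mL."""

    proportional_sd: float = 0.0
    additive_sd: float = 0.0

    def __post_init__(self):
        if self.proportional_sd < 0 or self.additive_sd < 0:
            raise ValidationError("error sds must be >= 0")
        if self.proportional_sd == 0 and self.additive_sd == 0:
            # degenerate but legal: exact observations (used in tests)
            pass

    def sd_at(self, pred: np.ndarray) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        return np.sqrt((self.proportional_sd * pred) ** 2 + self.additive_sd**2)


def apply_covariates(
    pop_params: PKParameters,
    effects,
    subject: SubjectCovariates,
) -> PKParameters:
    """Apply each matching strain effect multiplicatively, once.

    F above 1 after covariate application is clamped to 1 with a warning.
    """
    changes: dict = {}
    matched = []
    for eff in effects:
        if pop_params.__dict__.get(eff.parameter) is None:
            raise ValidationError(
                f"covariate effect on {eff.parameter!r} but parameter absent"
            )
        if eff.matches(subject):
            matched.append(eff)
    # sorted application makes the result bitwise order-independent
    for eff in sorted(matched, key=lambda e: (e.parameter, e.strain, e.fold_change)):
        base = changes.get(eff.parameter, pop_params.get(eff.parameter))
        changes[eff.parameter] = base * eff.fold_change
    if "F" in changes and changes["F"] > 1.0:
        warnings.warn(
            f"covariate-adjusted F {changes['F']:.3f} exceeds 1; clamped",
            stacklevel=2,
        )
        changes["F"] = 1.0
    return pop_params.replace(**changes) if changes else pop_params


def draw_individual(
    pop_params: PKParameters,
    bsv: BSVModel,
    rng,
) -> PKParameters:
    """Draw individual parameters: theta_i = theta_pop * exp(eta), eta ~ N(0, omega^2).

    ``rng`` is a ``numpy.random.Generator`` or an integer seed. F draws
    exceeding 1 are clamped to 1 (lognormal medians are preserved for
    all other parameters).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    changes = {}
    for name, w2 in sorted(bsv.omega2.items()):
        if w2 == 0:
            continue
        base = pop_params.get(name)
        val = base * np.exp(rng.normal(0.0, np.sqrt(w2)))
        if name == "F":
            val = min(val, 1.0)
        if name == "frac1" or name == "f_bile":
            val = min(val, 1.0)
        changes[name] = val
    return pop_params.replace(**changes) if changes else pop_params


def observe(profile: ConcentrationProfile, error: ErrorModel, rng):
    """Apply residual error to a simulated profile.

    Returns ``(observations, floored)``: observations ng/mL with
    negative values floored at 0, and a boolean flag array marking
    floored points.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    c = profile.concentrations
    eps_prop = rng.normal(0.0, 1.0, size=c.shape) * error.proportional_sd
    eps_add = rng.normal(0.0, 1.0, size=c.shape) * error.additive_sd
    y = c * (1.0 + eps_prop) + eps_add
    floored = y < 0
    return np.where(floored, 0.0, y), floored
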