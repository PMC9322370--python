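"""Mouse-to-human translation of a fitted model.

Typical clearances and volumes are scaled by standard allometry from
the 30 g mouse reference (exponent 0.75 for clearance-like, 1.0 for
volume-like parameters); rate constants, fractions and transit times
are left untouched. Tablet dissolution is emulated either as a
zero-order release window in the depot or as a shift of the mean
transit time, and for basic drugs whose stomach ionization differs
between species the oral bioavailability is corrected by the ratio of
ionized fractions (Henderson-Hasselbalch). Between- and within-subject
variability is never propagated: only typical values cross species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .structural import PKParameters, StructuralModelSpec, ValidationError

__all__ = [
    "ScalingPolicy",
    "IonizationSpec",
    "DissolutionCorrection",
    "allometric_scale",
    "fraction_ionized",
    "ionization_corrected_F",
    "apply_dissolution",
    "simplify_for_translation",
]


@dataclass(frozen=True)
class ScalingPolicy:
    """Allometric scaling policy (reference weight in grams)."""

    reference_weight: float = 30.0
    exponent_clearance: float = 0.75
    exponent_volume: float = 1.0
    clearance_like: frozenset = frozenset({"CL", "Q"})
    volume_like: frozenset = frozenset({"V1", "V2"})

    def __post_init__(self):
        if self.reference_weight <= 0:
            raise ValidationError("reference_weight must be > 0")
        object.__setattr__(self, "clearance_like", frozenset(self.clearance_like))
        object.__setattr__(self, "volume_like", frozenset(self.volume_like))


@dataclass(frozen=True)
class IonizationSpec:
    """Stomach pH pair and basic pKa for the ionized-fraction correction."""

    pKa: float
    pH_human_stomach: float = 1.75
    pH_mouse_stomach: float = 3.5

    def __post_init__(self):
        for name in ("pH_human_stomach", "pH_mouse_stomach"):
            v = getattr(self, name)
            if not 0.0 < v < 14.0:
                raise ValidationError(f"{name} must lie in (0, 14), got {v}")


@dataclass(frozen=True)
class DissolutionCorrection:
    """Tablet dissolution correction: zero-order release or an MTT shift (h)."""

    mode: str
    duration: float

    def __post_init__(self):
        if self.mode not in ("zero_order_release", "mtt_shift"):
            raise ValidationError(f"unknown dissolution mode {self.mode!r}")
        if self.duration <= 0:
            raise ValidationError("dissolution duration must be > 0")


def allometric_scale(
    params: PKParameters,
    bodyweight: float,
    policy: ScalingPolicy = ScalingPolicy(),
) -> PKParameters:
    """Scale typical parameters to an individual of the given bodyweight (g).

    Clearance-like symbols are multiplied by (BWT/ref)^0.75 and
    volume-like by (BWT/ref)^1.0. Scaling always starts from the mouse
    reference: re-scaling an already scaled parameter set raises.
    """
    if bodyweight <= 0:
        raise ValidationError("bodyweight must be > 0")
    if params.scaled_from_mouse:
        raise ValidationError(
            "parameters are already scaled from the mouse reference; "
            "allometric scaling must start from mouse typical values"
        )
    ratio = bodyweight / policy.reference_weight
    m_cl = ratio**policy.exponent_clearance
    m_v = ratio**policy.exponent_volume
    changes: dict = {"scaled_from_mouse": True}
    for name in sorted(policy.clearance_like):
        if getattr(params, name) is not None:
            changes[name] = params.get(name) * m_cl
    for name in sorted(policy.volume_like):
        if getattr(params, name) is not None:
            changes[name] = params.get(name) * m_v
    return params.replace(**changes)


def fraction_ionized(pH: float, pKa: float) -> float:
    """Ionized fraction of a base: fBH+ = 1 / (1 + 10^(pH - pKa))."""
    if not (math.isfinite(pH) and math.isfinite(pKa)):
        raise ValidationError("pH and pKa must be finite")
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def ionization_corrected_F(F_mouse: float, spec: IonizationSpec) -> float:
    """Translate oral bioavailability by the human/mouse ionized-fraction ratio.

    F_human = F_mouse * fBH+(human stomach) / fBH+(mouse stomach),
    clamped to 1 with a warning when the ratio pushes it above 1.
    """
    if not 0.0 < F_mouse <= 1.0:
        raise ValidationError(f"F_mouse must lie in (0, 1], got {F_mouse}")
    f_human = F_mouse * (
        fraction_ionized(spec.pH_human_stomach, spec.pKa)
        / fraction_ionized(spec.pH_mouse_stomach, spec.pKa)
    )
    if f_human > 1.0:
        warnings.warn(
            f"ionization-corrected F {f_human:.3f} exceeds 1; clamped to 1",
            stacklevel=2,
        )
        f_human = 1.0
    return f_human


def apply_dissolution(
    spec: StructuralModelSpec,
    params: PKParameters,
    correction: DissolutionCorrection,
    route: str = "oral_tablet",
):
    """Correct for tablet dissolution when translating a gavage-solution model.

    Zero-order release sets the depot input duration D_zero; the MTT
    shift adds the dissolution time to the mean transit time (for
    transit-absorption models where a release window is not available).
    Non-tablet routes are returned unchanged.
    """
    if route != "oral_tablet":
        return spec, params
    if correction.mode == "zero_order_release":
        return spec, params.replace(D_zero=correction.duration)
    if params.MTT is None:
        raise ValidationError(
            "mtt_shift dissolution correction requires a model with MTT"
        )
    return spec, params.replace(MTT=params.MTT + correction.duration)


def simplify_for_translation(spec: StructuralModelSpec) -> StructuralModelSpec:
    """Drop model properties redundant for cross-species translation.

    Enterohepatic recirculation and the exponential dose effect on F are
    removed (they are study-design- and species-specific); the caller
    must re-fit the simplified structure before scaling. A spec without
    these features is returned unchanged.
    """
    if not spec.features & {"ehc", "dose_on_F"}:
        return spec
    return spec.with_features_removed("ehc", "dose_on_F")
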