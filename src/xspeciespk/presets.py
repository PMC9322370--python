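"""Per-drug model presets.

Each of the four CYP3A4-substrate drugs ships two structural variants:
the *final* mouse model (best fit to the mouse data) and the
*optimized* model for mouse-to-human translation, in which properties
redundant for translation (enterohepatic recirculation, the exponential
dose effect on F) have been removed and, for fisogatinib, a peripheral
compartment added. Strain covariate fold-changes are the reported
estimates for each variant.

The mouse typical parameter values bundled here are synthetic
stand-ins: the original per-study estimates are not published in
machine-readable form, so plausible mouse-scale values are used to
drive synthetic studies and end-to-end runs. Covariate folds, human
doses, dissolution times and the ionization inputs are the reported
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .extrapolation import DissolutionCorrection, IonizationSpec
from .population import CovariateEffect
from .structural import PKParameters, StructuralModelSpec, ValidationError

__all__ = ["DrugPreset", "get_preset", "DRUGS"]

DRUGS = ("lorlatinib", "brigatinib", "ribociclib", "fisogatinib")


@dataclass(frozen=True)
class DrugPreset:
    name: str
    final_spec: StructuralModelSpec
    optimized_spec: StructuralModelSpec
    #: synthetic stand-in mouse typical values (final variant)
    mouse_params_final: PKParameters
    #: synthetic stand-in mouse typical values (optimized variant)
    mouse_params_optimized: PKParameters
    covariates_final: tuple
    covariates_optimized: tuple
    human_dose_mg: float
    dissolution: DissolutionCorrection | None = None
    ionization: IonizationSpec | None = None

    def spec(self, variant: str) -> StructuralModelSpec:
        return self._pick(variant, self.final_spec, self.optimized_spec)

    def mouse_params(self, variant: str) -> PKParameters:
        return self._pick(variant, self.mouse_params_final, self.mouse_params_optimized)

    def covariates(self, variant: str) -> tuple:
        return self._pick(variant, self.covariates_final, self.covariates_optimized)

    @staticmethod
    def _pick(variant, final, optimized):
        if variant == "final":
            return final
        if variant == "optimized":
            return optimized
        raise ValidationError(f"variant must be 'final' or 'optimized', got {variant!r}")


def _fold(param, value):
    return CovariateEffect(parameter=param, strain="Cyp3aXAV", fold_change=value)


_PRESETS = {}

# lorlatinib: 2-compartment, dual first-order absorption (same structure in
# both variants); human dose 100 mg; 45 min tablet dissolution.
_PRESETS["lorlatinib"] = DrugPreset(
    name="lorlatinib",
    final_spec=StructuralModelSpec(2, "dual_first_order"),
    optimized_spec=StructuralModelSpec(2, "dual_first_order"),
    mouse_params_final=PKParameters(
        CL=0.045, V1=0.10, V2=0.15, Q=0.05, ka1=2.5, ka2=0.4, frac1=0.6, F=0.7
    ),
    mouse_params_optimized=PKParameters(
        CL=0.045, V1=0.10, V2=0.15, Q=0.05, ka1=2.5, ka2=0.4, frac1=0.6, F=0.7
    ),
    covariates_final=(_fold("CL", 1.34), _fold("F", 0.71)),
    covariates_optimized=(_fold("CL", 1.34), _fold("F", 0.71)),
    human_dose_mg=100.0,
    dissolution=DissolutionCorrection("zero_order_release", 0.75),
)

# brigatinib: final = 2-compartment with exponential dose effect on F;
# optimized drops the dose effect; human dose 180 mg; 45 min dissolution.
_PRESETS["brigatinib"] = DrugPreset(
    name="brigatinib",
    final_spec=StructuralModelSpec(2, "first_order", features={"dose_on_F"}),
    optimized_spec=StructuralModelSpec(2, "first_order"),
    mouse_params_final=PKParameters(
        CL=0.025, V1=0.09, V2=0.12, Q=0.03, ka1=0.8, F=0.6,
        theta_dose=0.2, dose_ref=0.75,
    ),
    mouse_params_optimized=PKParameters(
        CL=0.025, V1=0.09, V2=0.12, Q=0.03, ka1=0.8, F=0.6
    ),
    covariates_final=(_fold("CL", 1.63),),
    covariates_optimized=(_fold("CL", 1.91),),
    human_dose_mg=180.0,
    dissolution=DissolutionCorrection("zero_order_release", 0.75),
)

# ribociclib: final = 2-compartment with EHC; optimized drops the EHC;
# human dose 600 mg; 30 min dissolution.
_PRESETS["ribociclib"] = DrugPreset(
    name="ribociclib",
    final_spec=StructuralModelSpec(2, "first_order", features={"ehc"}),
    optimized_spec=StructuralModelSpec(2, "first_order"),
    mouse_params_final=PKParameters(
        CL=0.06, V1=0.12, V2=0.30, Q=0.06, ka1=0.7, F=0.5,
        f_bile=0.3, k_bile=2.0, t_empty=4.0,
    ),
    mouse_params_optimized=PKParameters(
        CL=0.06, V1=0.12, V2=0.30, Q=0.06, ka1=0.7, F=0.5
    ),
    covariates_final=(_fold("CL", 3.53),),
    covariates_optimized=(_fold("F", 0.30),),
    human_dose_mg=600.0,
    dissolution=DissolutionCorrection("zero_order_release", 0.5),
)

# fisogatinib: final = 1-compartment with transit absorption and EHC;
# optimized = 2-compartment with transit absorption, no EHC. Dissolution is
# an MTT shift (+0.375 h); stomach-ionization correction applies (basic
# pKa 3.79; stomach pH 1.75 human vs 3.5 mouse).
_PRESETS["fisogatinib"] = DrugPreset(
    name="fisogatinib",
    final_spec=StructuralModelSpec(1, "transit_chain", features={"ehc"}, n_transit=3),
    optimized_spec=StructuralModelSpec(2, "transit_chain", n_transit=3),
    mouse_params_final=PKParameters(
        CL=0.05, V1=0.15, MTT=1.2, F=0.4, f_bile=0.25, k_bile=1.5, t_empty=3.0
    ),
    mouse_params_optimized=PKParameters(
        CL=0.05, V1=0.10, V2=0.12, Q=0.04, MTT=1.2, F=0.4
    ),
    covariates_final=(_fold("CL", 0.61), _fold("F", 0.57)),
    covariates_optimized=(_fold("CL", 0.61), _fold("F", 0.57)),
    human_dose_mg=600.0,
    dissolution=DissolutionCorrection("mtt_shift", 0.375),
    ionization=IonizationSpec(pKa=3.79),
)


def get_preset(drug: str) -> DrugPreset:
    try:
        return _PRESETS[drug]
    except KeyError:
        raise ValidationError(
            f"unknown drug {drug!r}; expected one of {', '.join(DRUGS)}"
        ) from None
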