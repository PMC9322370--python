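#!/usr/bin/env python
"""Translate fitted mouse models to human.

Re-fits each drug's translation-optimized structure (enterohepatic
recirculation and the dose effect on F removed), then applies standard
allometric scaling (exponent 0.75 for CL and Q, 1.0 for volumes, 30 g
reference), the tablet dissolution correction, and -- for the basic
drug fisogatinib -- the stomach-ionization bioavailability correction.
Writes per-strain human typical parameters at 70 kg under
results/extrapolation/.
"""

import json
from pathlib import Path

from xspeciespk import (
    allometric_scale,
    apply_dissolution,
    build_model,
    fit_pooled,
    get_preset,
    ionization_corrected_F,
)
from xspeciespk.io import read_dataset
from xspeciespk.presets import DRUGS

SEED = 20230915
DATA = Path("results/data")
OUT = Path("results/extrapolation")
FIXED = {"f_bile", "k_bile", "t_empty"}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, drug in enumerate(DRUGS):
        preset = get_preset(drug)
        ds = read_dataset(DATA / f"{drug}_mouse_study.csv")
        model = build_model(preset.optimized_spec)
        free = tuple(n for n in model.required_parameters if n not in FIXED)
        fit = fit_pooled(
            model, ds, preset.mouse_params_optimized, free=free,
            effects_init=preset.covariates_optimized, n_starts=2, seed=SEED + i,
        )
        (OUT / f"{drug}_optimized_fit.json").write_text(
            json.dumps(fit.to_dict(), indent=2)
        )
        out = {"drug": drug, "seed": SEED + i, "strains": {}}
        for strain in ("WT", "Cyp3aXAV"):
            p = fit.estimates
            for (param, s), fold in fit.fold_changes.items():
                if s == strain:
                    val = p.get(param) * fold
                    p = p.replace(**{param: min(val, 1.0) if param == "F" else val})
            spec, p = apply_dissolution(model.spec, p, preset.dissolution)
            if preset.ionization is not None:
                p = p.replace(F=ionization_corrected_F(p.get("F"), preset.ionization))
            human = allometric_scale(p, 70_000.0)
            out["strains"][strain] = human.as_dict()
            print(f"{drug:<12} {strain:<9} CL {human.CL:7.2f} L/h  "
                  f"V1 {human.V1:7.1f} L  F {human.F if human.F else float('nan'):.3f}")
        (OUT / f"{drug}_human_typical_70kg.json").write_text(
            json.dumps(out, indent=2)
        )
    print(f"\nwritten to {OUT}/")


if __name__ == "__main__":
    main()
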