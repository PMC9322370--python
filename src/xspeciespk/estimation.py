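"""Naive-pooled maximum-likelihood estimation and likelihood-ratio covariate tests.

The objective is the pooled -2 log-likelihood (OFV) of all observations
under the structural model with a combined proportional/additive
residual error; strain covariate effects enter as multiplicative
fold-changes estimated on the log scale. Nested models are compared by
the change in OFV against chi-squared quantiles; the working
significance rule for one extra parameter is dOFV < -6.64 (p < 0.01).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .population import CovariateEffect, ErrorModel, SubjectCovariates, apply_covariates
from .structural import CompiledModel, DoseEvent, PKParameters, ValidationError
from .synthetic import MouseStudyDataset

__all__ = ["FitResult", "LRTDecision", "neg2ll", "fit_pooled", "lrt_covariate"]

_LOG_2PI = math.log(2.0 * math.pi)

# parameters bounded above by 1 (fit on log scale with upper bound 0)
_UNIT_BOUNDED = {"F", "frac1", "f_bile"}


@dataclass
class FitResult:
    """Outcome of a pooled maximum-likelihood fit."""

    estimates: PKParameters
    fold_changes: dict
    error: ErrorModel
    ofv: float
    rse: dict
    converged: bool
    n_obs: int
    n_subjects: int
    n_params: int
    n_starts: int = 1
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.as_dict(),
            "fold_changes": {f"{p}:{s}": v for (p, s), v in self.fold_changes.items()},
            "error": {
                "proportional_sd": self.error.proportional_sd,
                "additive_sd": self.error.additive_sd,
            },
            "ofv": self.ofv,
            "rse_percent": self.rse,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_params": self.n_params,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class LRTDecision:
    """Likelihood-ratio decision for one nested comparison."""

    dOFV: float
    df: int
    alpha: float
    significant: bool
    threshold: float


class _PooledObjective:
    """Pooled OFV with per-group prediction caching.

    Subjects sharing strain, dosing and sampling schedule have identical
    predictions under a pooled model, so observations are grouped by
    that key and each group's profile is computed once per evaluation.
    """

    def __init__(self, model: CompiledModel, dataset: MouseStudyDataset):
        self.model = model
        groups: dict = {}
        frame = dataset.frame
        for sid, grp in frame.groupby("ID", sort=False):
            doses = grp[grp["EVID"] == 1]
            obs = grp[grp["EVID"] == 0]
            if obs.empty:
                continue
            strain = str(grp.iloc[0]["STRAIN"])
            dose_key = tuple(
                (float(r["TIME"]), float(r["AMT"]), str(r["ROUTE"]))
                for _, r in doses.iterrows()
            )
            times = tuple(float(t) for t in obs["TIME"])
            key = (strain, dose_key, times)
            groups.setdefault(key, []).append(obs["DV"].to_numpy(dtype=float))
        self.groups = []
        for (strain, dose_key, times), ys in groups.items():
            dose_events = [
                DoseEvent("grp", t, a, route=r) for (t, a, r) in dose_key
            ]
            self.groups.append(
                {
                    "strain": strain,
                    "doses": dose_events,
                    "times": np.asarray(times),
                    "y": np.stack(ys),  # (n_subjects_in_group, n_times)
                }
            )
        self.n_obs = sum(g["y"].size for g in self.groups)
        self.n_subjects = dataset.n_subjects

    def ofv(self, params_by_strain: dict, error: ErrorModel) -> float:
        total = 0.0
        for g in self.groups:
            p = params_by_strain[g["strain"]]
            pred = self.model.predict(p, g["doses"], g["times"])
            sd = error.sd_at(pred)
            if np.any(sd <= 0):
                raise ValidationError(
                    "prediction <= 0 with a purely proportional error model; "
                    "add an additive error floor"
                )
            r = (g["y"] - pred[None, :]) / sd[None, :]
            total += g["y"].shape[0] * np.sum(_LOG_2PI + 2.0 * np.log(sd))
            total += float(np.sum(r * r))
        return total


def _strain_params(pop: PKParameters, effects, strains):
    out = {}
    for s in strains:
        subj = SubjectCovariates(subject_id="pop", strain=s, bodyweight=30.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[s] = apply_covariates(pop, effects, subj)
    return out


def neg2ll(
    model: CompiledModel,
    params: PKParameters,
    error: ErrorModel,
    dataset: MouseStudyDataset,
    effects=(),
) -> float:
    """Pooled -2 log-likelihood of the dataset under the model.

    ``effects`` are applied per subject strain before prediction.
    Deterministic given its inputs.
    """
    obj = _PooledObjective(model, dataset)
    strains = {g["strain"] for g in obj.groups}
    return obj.ofv(_strain_params(params, effects, strains), error)


def fit_pooled(
    model: CompiledModel,
    dataset: MouseStudyDataset,
    init: PKParameters,
    bounds: dict | None = None,
    free: tuple | None = None,
    effects_init=(),
    error_init: ErrorModel = ErrorModel(0.2, 0.5),
    estimate_error: bool = True,
    fix_additive: bool = True,
    n_starts: int = 5,
    seed: int | None = None,
) -> FitResult:
    """Fit a structural + covariate model to a mouse dataset by pooled ML.

    Positive parameters are estimated on the log scale under a bounded
    quasi-Newton optimizer with optional seeded multi-start jitter.
    ``effects_init`` lists covariate fold-changes to estimate (their
    values are the starting folds); the proportional error sd is
    estimated by default with the additive sd held at its floor.

    Standard errors come from the finite-difference Hessian of the OFV;
    a singular Hessian yields missing (None) RSEs rather than guesses.
    """
    if dataset.n_observations == 0:
        raise ValidationError("dataset has no observations")
    free = tuple(free) if free is not None else model.required_parameters
    bounds = dict(bounds or {})
    for name in free:
        if init.__dict__.get(name) is None:
            raise ValidationError(f"missing required parameter(s): {name} (in init)")
        lo, hi = bounds.get(
            name, (1e-6, 1.0 if name in _UNIT_BOUNDED else 1e6)
        )
        v = init.get(name)
        if not lo <= v <= hi:
            raise ValidationError(
                f"init for {name} ({v}) violates bounds [{lo}, {hi}]"
            )
        bounds[name] = (lo, hi)

    effects_init = list(effects_init)
    names = list(free)
    x0 = [math.log(init.get(n)) for n in free]
    lb = [math.log(bounds[n][0]) for n in free]
    ub = [math.log(bounds[n][1]) for n in free]
    for eff in effects_init:
        names.append(f"fold:{eff.parameter}:{eff.strain}")
        x0.append(math.log(eff.fold_change))
        lb.append(math.log(1e-3))
        ub.append(math.log(1e3))
    if estimate_error:
        names.append("sigma_prop")
        x0.append(math.log(max(error_init.proportional_sd, 1e-3)))
        lb.append(math.log(1e-4))
        ub.append(math.log(10.0))
        if not fix_additive:
            names.append("sigma_add")
            x0.append(math.log(max(error_init.additive_sd, 1e-3)))
            lb.append(math.log(1e-6))
            ub.append(math.log(1e4))

    obj = _PooledObjective(model, dataset)
    strains = sorted({g["strain"] for g in obj.groups})
    n_fold = len(effects_init)

    def unpack(x):
        pop = init.replace(**{n: math.exp(v) for n, v in zip(free, x[: len(free)])})
        effects = [
            CovariateEffect(e.parameter, e.strain, math.exp(x[len(free) + j]))
            for j, e in enumerate(effects_init)
        ]
        k = len(free) + n_fold
        prop, add = error_init.proportional_sd, error_init.additive_sd
        if estimate_error:
            prop = math.exp(x[k])
            if not fix_additive:
                add = math.exp(x[k + 1])
        return pop, effects, ErrorModel(prop, add)

    def fun(x):
        try:
            pop, effects, err = unpack(x)
            return obj.ofv(_strain_params(pop, effects, strains), err)
        except (ValidationError, OverflowError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 0.25, size=x0.size)
        xs = np.clip(xs, lb, ub)
        res = minimize(
            fun, xs, method="L-BFGS-B", bounds=list(zip(lb, ub)),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    pop, effects, err = unpack(best.x)
    rse = _rse_from_hessian(fun, best.x, best.fun, names)
    return FitResult(
        estimates=pop,
        fold_changes={(e.parameter, e.strain): e.fold_change for e in effects},
        error=err,
        ofv=float(best.fun),
        rse=rse,
        converged=bool(best.success and np.isfinite(best.fun)),
        n_obs=obj.n_obs,
        n_subjects=obj.n_subjects,
        n_params=len(names),
        n_starts=max(1, n_starts),
        seed=seed,
    )


def _rse_from_hessian(fun, x, f0, names, h: float = 1e-4):
    """RSE%% via the central finite-difference Hessian of the OFV.

    For log-scale parameters the SE of the log equals the relative SE of
    the natural parameter, so RSE%% = 100 * sqrt(2 * H^-1)_ii.
    """
    n = x.size
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            fpp = fun(x + ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError
        return {name: float(100.0 * math.sqrt(d)) for name, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {name: None for name in names}


def lrt_covariate(
    base: FitResult, extended: FitResult, df: int, alpha: float = 0.01
) -> LRTDecision:
    """Likelihood-ratio test of a covariate extension against its base model.

    dOFV = OFV_extended - OFV_base; the extension is significant when
    dOFV < -chi2(1 - alpha, df), i.e. below -6.64 at alpha 0.01 with one
    degree of freedom.
    """
    if df <= 0:
        raise ValidationError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    dofv = extended.ofv - base.ofv
    threshold = -float(chi2.ppf(1.0 - alpha, df))
    return LRTDecision(
        dOFV=float(dofv),
        df=df,
        alpha=alpha,
        significant=bool(dofv < threshold),
        threshold=threshold,
    )
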