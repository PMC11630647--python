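"""Kinetic parameter estimation and term selection.

Each of the three rate equations is fitted separately to the observed rates
by globally minimizing the weighted sum of squared errors with differential
evolution (seeded, hence deterministic).  Insignificant terms are pruned by
backward elimination: fit the working model, refit once per removable term
with that term left out, compute an F-test p-value per term, and remove the
term with the highest p-value as long as it is >= the significance level
alpha.  The significance level is a hyperparameter chosen by leave-one-run-out
cross-validation on the prediction error of the final product-to-biomass
yield YPX.

The greedy removal order does not depend on alpha (alpha only sets the
stopping point), so the elimination path is computed once per rate and reused
across the whole alpha grid during cross-validation.

Positive parameters (scales, saturation and inhibition constants) are
searched in log10 space; the temperature law is searched as (rate value at a
31 degC reference, activation energy, half-inactivation temperature,
inactivation sharpness), which is far better conditioned than the raw
pre-exponential factor.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from scipy.stats import f as f_dist

from .params import (
    MODIFIERS,
    KineticParameterSet,
    RateLaw,
    TemperatureLawParams,
    temperature_factor,
)
from .records import ProcessRecord, RateObservations

logger = logging.getLogger(__name__)

__all__ = [
    "DEOptions",
    "FitResult",
    "EliminationTrace",
    "SelectionReport",
    "fit_rate",
    "f_test",
    "eliminate_terms",
    "elimination_path",
    "select_alpha",
    "aicc",
    "aicc_standard",
    "exhaustive_aicc_select",
    "goodness",
    "assemble_parameter_set",
    "DEFAULT_ALPHA_GRID",
    "T_REF_CELSIUS",
]

T_REF_CELSIUS = 31.0

#: 13 significance levels evaluated during cross-validation
DEFAULT_ALPHA_GRID = (
    0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30,
    0.40, 0.50,
)

_RATE_TARGET = {
    "uptake": "gamma_circ_hat",
    "maintenance": "gamma_alpha_hat",
    "production": "gamma_pi_hat",
}


@dataclass
class DEOptions:
    """Differential-evolution budget.  ``strict()`` is the high-budget preset
    (population 15 x dim, tolerance 1e-8, up to 2000 generations)."""

    maxiter: int = 600
    popsize: int = 30
    tol: float = 1e-10
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.7
    polish: bool = True
    init: str = "sobol"

    @classmethod
    def strict(cls) -> "DEOptions":
        return cls(maxiter=2000, popsize=15, tol=1e-8, init="latinhypercube")

    @classmethod
    def fast(cls) -> "DEOptions":
        return cls(maxiter=150, popsize=15, tol=1e-7)


@dataclass
class FitResult:
    rate: str
    rate_law: RateLaw
    rss: float
    residuals: np.ndarray
    weights: np.ndarray
    n_points: int
    n_params: int
    seed: int
    theta: np.ndarray
    param_names: tuple

    @property
    def tss(self) -> float:
        y = self.residuals + self._pred  # measured values
        w = self.weights
        ybar = float(np.sum(w * y) / np.sum(w))
        return float(np.sum(w * (y - ybar) ** 2))

    _pred: np.ndarray = field(default=None, repr=False)  # type: ignore


# --------------------------------------------------------------------------
# data preparation and parameter layout
# --------------------------------------------------------------------------

def _rate_rows(observations: RateObservations, rate: str):
    d = observations.data
    if rate == "uptake":
        d = d[d["valid_uptake"]]
    if len(d) == 0:
        raise ValueError(f"no valid observation rows for rate {rate!r}")
    y = d[_RATE_TARGET[rate]].to_numpy(dtype=float)
    covs = {
        "G": np.clip(d["G"].to_numpy(dtype=float), 0.0, None),
        "n": np.clip(d["n"].to_numpy(dtype=float), 0.0, None),
        "PX": np.clip(d["PX"].to_numpy(dtype=float), 0.0, None),
        "X": d["X"].to_numpy(dtype=float),
        "T": d["T"].to_numpy(dtype=float),
        "gamma_uptake": np.clip(d["gamma_circ_hat"].to_numpy(dtype=float), 0.0, None),
        "surplus": np.clip(d["surplus"].to_numpy(dtype=float), 0.0, None),
    }
    w = d["weight"].to_numpy(dtype=float)
    ok = np.isfinite(y)
    return y[ok], {k: v[ok] for k, v in covs.items()}, w[ok]


def _sat_covariate(rate: str):
    return "G" if rate == "uptake" else "surplus"


def _layout(rate: str, mask: dict, covs: dict, bounds: dict | None,
            y=None):
    """(names, bounds) of the free parameters for this mask.

    The rate-scale bounds are data-driven (like the K bounds): the scale is
    a rate cap, so its upper bound is a generous multiple of the largest
    observed rate rather than a fixed constant — a scale parameter far above
    every observation only exists on degenerate ridges where a collapsed
    saturation or inhibition factor cancels it.
    """
    bounds = bounds or {}
    names, lims = [], []

    def add(name, lo, hi):
        names.append(name)
        lims.append(tuple(bounds.get(name, (lo, hi))))

    scale_hi = 1.0
    if y is not None and np.size(y) and np.max(np.abs(y)) > 0:
        scale_hi = math.log10(30.0 * float(np.max(np.abs(y))))
    if mask["temp"]:
        add("temp.log10_ref", -4.0, scale_hi)
        add("temp.dG_cat", 1e4, 2e5)
        add("temp.T_eq", 300.0, 325.0)
        add("temp.dH_eq", 5e4, 1e6)
    else:
        add("log10_c", -4.0, scale_hi)
    # modifier constants: the upper side extends far enough that a term
    # driven to its bound is numerically indistinguishable from an absent
    # term (factor 1 to ~1e-6), keeping reduced models properly nested
    if mask.get("Km"):
        s = max(float(np.mean(np.abs(covs[_sat_covariate(rate)]))), 1e-6)
        add("log10_Km", math.log10(s) - 3, math.log10(s) + 3)
    for m in MODIFIERS[rate]:
        if mask[m]:
            s = max(float(np.mean(np.abs(covs[m]))), 1e-6)
            add(f"log10_K.{m}", math.log10(s) - 3, math.log10(s) + 6)
    return tuple(names), tuple(lims)


def _theta_to_rate_law(rate: str, mask: dict, names, theta) -> RateLaw:
    vals = dict(zip(names, theta))
    temp = None
    c = 0.0
    if mask["temp"]:
        temp = TemperatureLawParams.from_reference(
            rate_at_ref=10.0 ** vals["temp.log10_ref"],
            dG_cat=vals["temp.dG_cat"],
            T_eq=vals["temp.T_eq"],
            dH_eq=vals["temp.dH_eq"],
            T_ref_celsius=T_REF_CELSIUS,
        )
        c = 10.0 ** vals["temp.log10_ref"]
    else:
        c = 10.0 ** vals["log10_c"]
    Km = 10.0 ** vals["log10_Km"] if mask.get("Km") else None
    K = {m: 10.0 ** vals[f"log10_K.{m}"] for m in MODIFIERS[rate]
         if mask[m]}
    return RateLaw(kind=rate, c=c, temp=temp, Km=Km, K=K, mask=dict(mask))


def _temperature_factor_ratio(T_celsius, ref, dG, Teq, dH):
    """Temperature law expressed through its value at the reference
    temperature (the kB*T/h prefactor cancels in the ratio).  Broadcasts over
    both temperatures and parameter vectors."""
    from .constants import GAS_CONSTANT_R as R, celsius_to_kelvin

    TK = celsius_to_kelvin(np.asarray(T_celsius, dtype=float))
    TrefK = celsius_to_kelvin(T_REF_CELSIUS)

    def g(tk):
        return (tk * np.exp(-dG / (R * tk))
                / (1.0 + np.exp(dH / R * (1.0 / Teq - 1.0 / tk))))

    return ref * g(TK) / g(TrefK)


def _predict(rate: str, mask: dict, names, theta, covs):
    """Rate prediction from a flat parameter vector; mirrors RateLaw
    evaluation (checked by a consistency test).  ``theta`` may be one vector
    (dim,) or a population (dim, S); covariates broadcast accordingly."""
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    th = theta[:, None] if single else theta  # (dim, S)
    vals = dict(zip(names, th))

    def cov(name):
        return covs[name][:, None]  # (n, 1)

    if mask["temp"]:
        scale = _temperature_factor_ratio(
            cov("T"),
            10.0 ** vals["temp.log10_ref"],
            vals["temp.dG_cat"], vals["temp.T_eq"], vals["temp.dH_eq"],
        )
    else:
        scale = 10.0 ** vals["log10_c"] * np.ones((len(covs["T"]), 1))
    if rate == "maintenance":
        out = scale
        for m in MODIFIERS[rate]:
            if mask[m]:
                out = out * (1.0 + cov(m) / 10.0 ** vals[f"log10_K.{m}"])
    else:
        x = cov(_sat_covariate(rate))
        if mask.get("Km"):
            out = scale * x / (10.0 ** vals["log10_Km"] + x)
        else:
            out = scale * (x > 0)
        for m in MODIFIERS[rate]:
            if mask[m]:
                out = out / (1.0 + cov(m) / 10.0 ** vals[f"log10_K.{m}"])
    return out[:, 0] if single else out


def _full_mask(rate: str) -> dict:
    return {t: True for t in RateLaw(kind=rate).term_names}


def _coerce_mask(rate: str, mask) -> dict:
    if mask is None:
        return _full_mask(rate)
    if isinstance(mask, RateLaw):
        mask = mask.mask
    out = dict(RateLaw(kind=rate, mask=dict(mask)).mask)
    return out


def _n_params_of_mask(rate: str, mask: dict) -> int:
    return RateLaw(kind=rate, mask=dict(mask)).n_parameters()


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit_rate(
    observations: RateObservations,
    rate: str,
    mask: dict | RateLaw | None = None,
    bounds: dict | None = None,
    seed: int = 0,
    de_options: DEOptions | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit the mask-active parameters of one rate equation.

    Minimizes sum_i w_i * (model(covariates_i) - observed_i)^2 over all runs
    and time points with seeded differential evolution plus a local polish.
    ``x0`` optionally injects a warm-start vector into the initial
    population (the optimizer is elitist, so the result is never worse than
    the warm start).
    """
    if rate not in _RATE_TARGET:
        raise ValueError(f"unknown rate {rate!r}")
    opts = de_options or DEOptions()
    mask = _coerce_mask(rate, mask)
    y, covs, w = _rate_rows(observations, rate)
    names, lims = _layout(rate, mask, covs, bounds, y=y)
    for lo, hi in lims:
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("parameter bounds must be finite with lo < hi")

    def objective(theta):
        theta = np.asarray(theta, dtype=float)
        pred = _predict(rate, mask, names, theta, covs)
        if theta.ndim == 1:
            r = pred - y
            return float(np.sum(w * r * r))
        r = pred - y[:, None]
        return np.sum(w[:, None] * r * r, axis=0)

    init = opts.init
    if x0 is not None:
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in lims])
        hi = np.array([b[1] for b in lims])
        pop = rng.uniform(lo, hi, size=(max(opts.popsize * len(lims), 5),
                                        len(lims)))
        pop[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
        init = pop
    result = differential_evolution(
        objective,
        bounds=list(lims),
        seed=seed,
        maxiter=opts.maxiter,
        popsize=opts.popsize,
        tol=opts.tol,
        mutation=opts.mutation,
        recombination=opts.recombination,
        polish=opts.polish,
        init=init,
        updating="deferred",
        vectorized=True,
    )
    if not np.isfinite(result.fun):
        raise RuntimeError(f"optimizer failed for rate {rate}: {result.message}")
    theta = np.asarray(result.x, dtype=float)
    pred = _predict(rate, mask, names, theta, covs)
    return FitResult(
        rate=rate,
        rate_law=_theta_to_rate_law(rate, mask, names, theta),
        rss=float(np.sum(w * (pred - y) ** 2)),
        residuals=y - pred,
        weights=w,
        n_points=len(y),
        n_params=_n_params_of_mask(rate, mask),
        seed=seed,
        theta=theta,
        param_names=names,
        _pred=pred,
    )


def f_test(rss_full: float, rss_reduced: float, df_removed: int,
           df_residual: int) -> float:
    """Upper-tail p-value of the F-test for a nested model reduction.

    F = ((rss_reduced - rss_full)/df_removed) / (rss_full/df_residual).
    A reduced fit that (numerically) beats the full fit is floored at the
    full fit's error, giving p = 1; a perfect full fit makes any increase
    infinitely significant (p = 0).
    """
    if df_removed < 1 or df_residual < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if rss_full < 0 or rss_reduced < 0:
        raise ValueError("rss must be non-negative")
    rss_reduced = max(rss_reduced, rss_full)
    if rss_full == 0.0:
        return 0.0 if rss_reduced > 0 else 1.0
    F = (rss_reduced - rss_full) / df_removed / (rss_full / df_residual)
    return float(f_dist.sf(F, df_removed, df_residual))


def _refit_from_reduced(observations, rate, mask, bounds, fit_reduced,
                        removed_term, seed, de_options):
    """Refit the full mask warm-started from a reduced-mask solution.

    The removed term is re-inserted at a near-neutral value (its factor ~ 1;
    for the temperature unit, the shallowest admissible law at the reduced
    constant's level) and the warm start is injected into the optimizer's
    population, so the refit can only improve on it."""
    y, covs, w = _rate_rows(observations, rate)
    names, lims = _layout(rate, mask, covs, bounds, y=y)
    red_vals = dict(zip(fit_reduced.param_names, fit_reduced.theta))
    theta0 = []
    for name, (lo, hi) in zip(names, lims):
        if name in red_vals:
            theta0.append(float(np.clip(red_vals[name], lo, hi)))
        elif name == "temp.log10_ref":
            theta0.append(float(np.clip(red_vals.get("log10_c", lo), lo, hi)))
        elif name in ("temp.dG_cat", "temp.dH_eq"):
            theta0.append(lo)  # shallowest admissible temperature response
        elif name == "temp.T_eq":
            theta0.append(hi)  # inactivation pushed out of the data range
        elif name == "log10_Km":
            theta0.append(lo)  # Km -> 0: saturation factor ~ 1
        else:  # inhibition/activation constant: K -> inf, factor ~ 1
            theta0.append(hi)
    return fit_rate(observations, rate, mask, bounds, seed, de_options,
                    x0=np.asarray(theta0))


@dataclass
class EliminationStep:
    iteration: int
    candidates: dict  # term -> (rss_without, F, p)
    rss_with: float
    removed: str | None
    max_p: float


@dataclass
class EliminationTrace:
    rate: str
    steps: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for term, (rss_wo, F, p) in s.candidates.items():
                rows.append(
                    {"iteration": s.iteration, "term": term,
                     "rss_with": s.rss_with, "rss_without": rss_wo,
                     "F": F, "p": p, "removed": term == s.removed}
                )
        return pd.DataFrame(rows)


MAX_ELIMINATION_ITERATIONS = 7  # removable terms per rate equation plus one


def elimination_path(
    observations: RateObservations,
    rate: str,
    seed: int = 0,
    bounds: dict | None = None,
    de_options: DEOptions | None = None,
    start_mask: dict | None = None,
):
    """Greedy backward-elimination path, independent of alpha.

    Returns a list of nodes ``(mask, fit, step)``: the working mask, its fit,
    and the :class:`EliminationStep` holding every candidate's p-value at
    that node.  The path removes the highest-p removable term at every node
    until none are left (or the iteration cap is hit); a stopping rule for a
    concrete alpha is applied afterwards.
    """
    mask = _coerce_mask(rate, start_mask)
    template = RateLaw(kind=rate)
    path = []
    for it in range(MAX_ELIMINATION_ITERATIONS):
        fit_full = fit_rate(observations, rate, mask, bounds, seed, de_options)
        removable = [t for t in mask if mask[t] and template.removable[t]]
        candidates = {}
        best_term, best_p = None, -1.0
        loo_fits = {}
        full_vals = dict(zip(fit_full.param_names, fit_full.theta))
        for term in removable:
            m2 = dict(mask)
            m2[term] = False
            # warm-start from the projected full solution: if the term is
            # spurious its fitted constant sits near the neutral bound, so
            # the projection is already near the reduced optimum
            y2, covs2, _ = _rate_rows(observations, rate)
            names2, _ = _layout(rate, m2, covs2, bounds, y=y2)
            x0 = np.array([
                full_vals.get(nm, full_vals.get("temp.log10_ref", 0.0)
                              if nm == "log10_c" else 0.0)
                for nm in names2
            ])
            loo_fits[term] = fit_rate(observations, rate, m2, bounds, seed,
                                      de_options, x0=x0)
        # a nested reduced model can never genuinely beat the full model; if
        # one does, the full fit under-converged -- refine it by polishing
        # from the best reduced solution extended with a neutral parameter
        best_loo = min(loo_fits, default=None,
                       key=lambda t: loo_fits[t].rss)
        if best_loo is not None and loo_fits[best_loo].rss < fit_full.rss:
            refined = _refit_from_reduced(observations, rate, mask, bounds,
                                          loo_fits[best_loo], best_loo,
                                          seed, de_options)
            if refined.rss < fit_full.rss:
                fit_full = refined
        df_res = max(fit_full.n_points - fit_full.n_params, 1)
        for term in removable:
            fit_wo = loo_fits[term]
            df_removed = fit_full.n_params - fit_wo.n_params
            p = f_test(fit_full.rss, fit_wo.rss, df_removed, df_res)
            rss_wo = max(fit_wo.rss, fit_full.rss)
            F = ((rss_wo - fit_full.rss) / df_removed
                 / (fit_full.rss / df_res) if fit_full.rss > 0 else np.inf)
            candidates[term] = (fit_wo.rss, F, p)
            if p > best_p:
                best_term, best_p = term, p
        step = EliminationStep(
            iteration=it, candidates=candidates, rss_with=fit_full.rss,
            removed=best_term, max_p=best_p,
        )
        path.append((dict(mask), fit_full, step))
        if not removable:
            break
        mask[best_term] = False
    return path


def eliminate_terms(
    observations: RateObservations,
    rate: str,
    alpha: float,
    seed: int = 0,
    bounds: dict | None = None,
    de_options: DEOptions | None = None,
    path=None,
):
    """Backward elimination at significance level ``alpha``.

    Walks the (alpha-independent) removal path and stops at the first node
    whose least-significant term has p < alpha.  Returns
    ``(final_mask, final_fit, EliminationTrace)``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if path is None:
        path = elimination_path(observations, rate, seed, bounds, de_options)
    steps = []
    for mask, fit, step in path:
        if not step.candidates or step.max_p < alpha:
            steps.append(EliminationStep(step.iteration, step.candidates,
                                         step.rss_with, None, step.max_p))
            return dict(mask), fit, EliminationTrace(rate=rate, steps=steps)
        steps.append(step)
    mask, fit, _ = path[-1]
    return dict(mask), fit, EliminationTrace(rate=rate, steps=steps)


def assemble_parameter_set(fits: dict, Y_XrG: float, Y_PG: float) -> KineticParameterSet:
    """Combine per-rate fit results into a full parameter set."""
    return KineticParameterSet(
        uptake=fits["uptake"].rate_law,
        maintenance=fits["maintenance"].rate_law,
        production=fits["production"].rate_law,
        Y_XrG=Y_XrG,
        Y_PG=Y_PG,
    )


# --------------------------------------------------------------------------
# information criteria and goodness of fit
# --------------------------------------------------------------------------

def aicc(rss: float, n_params: int, n_points: int) -> float:
    """Corrected Akaike information criterion, exactly as used here:

    AICC = #p*(log(RSS/#v) + 1) + 2*#v + #v*(1+#v)/(#p - #v - 3)

    with #p points and #v parameters.  Note RSS is divided by the parameter
    count inside the log and the small-sample denominator is #p - #v - 3;
    see :func:`aicc_standard` for the textbook form.
    """
    if n_points - n_params - 3 <= 0:
        raise ValueError("AICc undefined: need n_points - n_params - 3 > 0")
    if rss <= 0 or n_params < 1:
        raise ValueError("need rss > 0 and n_params >= 1")
    return (
        n_points * (math.log(rss / n_params) + 1.0)
        + 2.0 * n_params
        + n_params * (1.0 + n_params) / (n_points - n_params - 3.0)
    )


def aicc_standard(rss: float, n_params: int, n_points: int) -> float:
    """Textbook small-sample AICc (Gaussian errors, RSS/#p variance)."""
    if n_points - n_params - 1 <= 0:
        raise ValueError("AICc undefined: need n_points - n_params - 1 > 0")
    return (
        n_points * math.log(rss / n_points)
        + 2.0 * n_params
        + 2.0 * n_params * (n_params + 1.0) / (n_points - n_params - 1.0)
    )


def exhaustive_aicc_select(
    observations: RateObservations,
    rate: str,
    seed: int = 0,
    bounds: dict | None = None,
    de_options: DEOptions | None = None,
):
    """Fit every admissible mask of one rate and pick the lowest AICc.

    The uptake saturation constant is always present; the temperature law is
    one on/off unit.  Returns ``(best_mask, table)`` with the full AICc table.
    """
    template = RateLaw(kind=rate)
    toggles = [t for t in template.term_names if template.removable[t]]
    rows = []
    best_key, best_mask = (np.inf, np.inf), None
    for states in itertools.product((True, False), repeat=len(toggles)):
        mask = {t: True for t in template.term_names}
        mask.update(dict(zip(toggles, states)))
        fit = fit_rate(observations, rate, mask, bounds, seed, de_options)
        try:
            score = aicc(max(fit.rss, 1e-300), fit.n_params, fit.n_points)
        except ValueError:
            score = np.inf
        rows.append({**{f"use_{t}": s for t, s in zip(toggles, states)},
                     "n_params": fit.n_params, "rss": fit.rss, "aicc": score})
        key = (score, fit.n_params)  # equal AICc -> fewer parameters wins
        if key < best_key:
            best_key, best_mask = key, mask
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    return best_mask, table


def goodness(values_pred, values_meas, n_vars: int) -> dict:
    """Coefficient of determination, adjusted version, relative errors.

    R2 = 1 - RSS/TSS with TSS taken around the mean of the measured values;
    R2_adj = 1 - (RSS/df_res)/(TSS/df_tot) with df_res = #points - #vars - 1
    and df_tot = #points - 1.  Relative errors are (measured - predicted)
    over the measured mean.
    """
    pred = np.asarray(values_pred, dtype=float)
    meas = np.asarray(values_meas, dtype=float)
    if len(pred) != len(meas) or len(pred) < 3:
        raise ValueError("need >= 3 paired points")
    n = len(meas)
    mean_meas = float(np.mean(meas))
    rss = float(np.sum((meas - pred) ** 2))
    tss = float(np.sum((meas - mean_meas) ** 2))
    if tss == 0:
        raise ValueError("R^2 undefined for constant measurements")
    df_res = n - n_vars - 1
    df_tot = n - 1
    if df_res <= 0:
        raise ValueError("adjusted R^2 undefined: too few points")
    return {
        "R2": 1.0 - rss / tss,
        "R2_adj": 1.0 - (rss / df_res) / (tss / df_tot),
        "rel_err": (meas - pred) / mean_meas,
    }


# --------------------------------------------------------------------------
# alpha selection by cross-validation
# --------------------------------------------------------------------------

@dataclass
class SelectionReport:
    chosen_alpha: float
    cv_table: pd.DataFrame  # columns: alpha, cv_error
    masks: dict  # rate -> final mask at chosen alpha (fit on all data)
    fits: dict  # rate -> FitResult at chosen alpha (fit on all data)
    seed: int


def _final_ypx(record: ProcessRecord) -> float:
    return float(record.P_meas[-1] / record.X_meas[-1])


def predict_final_ypx(params: KineticParameterSet, record: ProcessRecord) -> float:
    """Simulate the record's controls under ``params``; return final P/X."""
    from .process_model import ControlProfile, ProcessState, simulate

    controls = ControlProfile(
        t_knots=record.t_online,
        feed_values=record.f_online,
        T_values=record.T_online,
        Gf=record.Gf,
        tend=record.tend,
    )
    G0 = record.G_meas[0] if np.isfinite(record.G_meas[0]) else 0.0
    P0 = min(float(record.P_meas[0]), record.X0 * 0.5)
    x0 = ProcessState(t=0.0, X=record.X0, P=P0, G=float(G0), V=record.V0)
    traj = simulate(params, controls, record.sampling_events, x0,
                    grid=record.sample_times, base=record.base_params)
    last = traj.iloc[-1]
    return float(last["P"] / last["X"])


def select_alpha(
    records: list[ProcessRecord],
    yields: tuple,
    alpha_grid=DEFAULT_ALPHA_GRID,
    seed: int = 0,
    smoothing: dict | None = None,
    bounds: dict | None = None,
    de_options: DEOptions | None = None,
    max_folds: int | None = None,
) -> SelectionReport:
    """Choose the elimination significance level by leave-one-run-out CV.

    For every alpha, each run is predicted from a model eliminated and fitted
    on the remaining runs; the score is the mean squared error of the
    predicted final YPX.  Ties prefer the smaller alpha (more pruning
    downstream).  ``max_folds`` caps the number of held-out runs (taken in
    a fixed round-robin order) to bound the cost.
    """
    from .rate_estimation import estimate_rates

    if len(records) < 3:
        raise ValueError("cross-validation needs at least 3 runs")
    alpha_grid = tuple(alpha_grid)
    fold_ids = list(range(len(records)))
    if max_folds is not None:
        fold_ids = fold_ids[: max_folds]

    errors = {a: [] for a in alpha_grid}
    for i in fold_ids:
        train = [r for j, r in enumerate(records) if j != i]
        held = records[i]
        obs = estimate_rates(train, yields, smoothing=smoothing)
        paths = {
            rate: elimination_path(obs, rate, seed=seed, bounds=bounds,
                                   de_options=de_options)
            for rate in _RATE_TARGET
        }
        for a in alpha_grid:
            fits = {}
            for rate in _RATE_TARGET:
                _, fit, _ = eliminate_terms(obs, rate, a, seed=seed,
                                            path=paths[rate])
                fits[rate] = fit
            params = assemble_parameter_set(fits, *yields)
            try:
                pred = predict_final_ypx(params, held)
            except Exception as exc:  # simulation failure on a bad candidate
                logger.warning("CV fold %d alpha %.3g: simulation failed (%s)",
                               i, a, exc)
                pred = np.nan
            meas = _final_ypx(held)
            err = (pred - meas) ** 2 if np.isfinite(pred) else np.inf
            errors[a].append(err)

    cv = pd.DataFrame(
        {"alpha": alpha_grid,
         "cv_error": [float(np.mean(errors[a])) for a in alpha_grid]}
    )
    best = cv.sort_values(["cv_error", "alpha"], kind="stable").iloc[0]
    chosen = float(best["alpha"])

    obs_all = estimate_rates(records, yields, smoothing=smoothing)
    masks, fits = {}, {}
    for rate in _RATE_TARGET:
        mask, fit, _ = eliminate_terms(obs_all, rate, chosen, seed=seed,
                                       bounds=bounds, de_options=de_options)
        masks[rate], fits[rate] = mask, fit
    return SelectionReport(chosen_alpha=chosen, cv_table=cv, masks=masks,
                           fits=fits, seed=seed)
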