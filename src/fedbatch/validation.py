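"""Simulation-study utilities used to validate the pipeline.

These helpers generate controlled test problems (exact rate observations,
spurious-term replicates, collocation refinement studies, held-out
prediction folds) and measure the pipeline's behavior on them.  They are
used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_fitting import (
    DEOptions,
    assemble_parameter_set,
    eliminate_terms,
    f_test,
    fit_rate,
    predict_final_ypx,
)
from .params import KineticParameterSet
from .process_model import ProcessState, evaluate_rates, simulate
from .rate_estimation import estimate_rates
from .records import RateObservations
from .synthetic import NoiseSpec, generate_run

__all__ = [
    "exact_rate_observations",
    "spurious_retention_rate",
    "collocation_errors",
    "heldout_ypx_errors",
    "parameter_errors",
]


def exact_rate_observations(params: KineticParameterSet, n: int = 150,
                            seed: int = 0, noise: float = 0.0
                            ) -> RateObservations:
    """Rate observations computed directly from a parameter set on random
    covariates (no trajectories, no splines): the fitting stage's idealized
    input."""
    rng = np.random.default_rng(seed)
    G = rng.uniform(0.05, 8.0, n)
    gens = rng.uniform(0.0, 1.2, n)
    PX = rng.uniform(0.0, 0.25, n)
    X = rng.uniform(20.0, 60.0, n)
    T = rng.uniform(28.0, 34.0, n)
    r = evaluate_rates(params, G, gens, PX, X, T)
    noise_f = 1.0 + noise * rng.standard_normal(n)
    d = pd.DataFrame({
        "run_id": "exact", "t": np.arange(n, dtype=float),
        "gamma_circ_hat": r["gamma_circ"] * noise_f,
        "gamma_alpha_hat": r["gamma_alpha"],
        "gamma_pi_hat": r["gamma_pi"],
        "gamma_mu_hat": r["gamma_mu"],
        "G": G, "n": gens, "PX": PX, "X": X, "T": T,
        "surplus": r["gamma_circ"] - r["gamma_alpha"],
        "weight": 1.0, "valid_uptake": True,
    })
    return RateObservations(data=d, Y_XrG=params.Y_XrG, Y_PG=params.Y_PG)


def spurious_retention_rate(n_replicates: int = 200, alpha: float = 0.05,
                            seed0: int = 1000, n_rows: int = 200,
                            rel_noise: float = 0.05) -> float:
    """Fraction of replicates in which an F-test would retain (p < alpha) an
    inhibition term that is absent from the generating model."""
    opts = DEOptions.fast()
    retained = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed0 + rep)
        G = rng.uniform(0.05, 5.0, n_rows)
        X = rng.uniform(20, 60, n_rows)
        gens = rng.uniform(0, 1.2, n_rows)
        PX = rng.uniform(0, 0.2, n_rows)
        y = 1.4 * G / (1.0 + G)  # truth: scale and Km only
        y = y * (1 + rel_noise * rng.standard_normal(n_rows))
        d = pd.DataFrame({
            "run_id": "r", "t": np.arange(n_rows, dtype=float),
            "gamma_circ_hat": y, "gamma_alpha_hat": 0.0,
            "gamma_pi_hat": 0.0, "gamma_mu_hat": y,
            "G": G, "n": gens, "PX": PX, "X": X,
            "T": np.full(n_rows, 31.0), "surplus": y,
            "weight": 1.0, "valid_uptake": True,
        })
        obs = RateObservations(data=d, Y_XrG=0.55, Y_PG=0.9)
        m_red = {"temp": False, "Km": True, "G": False, "n": False,
                 "PX": False, "X": False}
        m_full = dict(m_red)
        m_full["X"] = True  # the spurious candidate
        f_full = fit_rate(obs, "uptake", m_full, seed=rep, de_options=opts)
        f_red = fit_rate(obs, "uptake", m_red, seed=rep, de_options=opts)
        p = f_test(f_full.rss, f_red.rss,
                   f_full.n_params - f_red.n_params,
                   f_full.n_points - f_full.n_params)
        retained += int(p < alpha)
    return retained / n_replicates


def collocation_errors(params: KineticParameterSet, constraints,
                       element_counts=(24, 48, 96)) -> dict:
    """Max relative state error of the frozen-control collocated rollout
    against a fine-tolerance reference integration, per element count."""
    from .optimal_control import CollocationConfig, collocated_rollout, transcribe

    x0 = ProcessState(t=0, X=constraints.X0, P=constraints.P0,
                      G=constraints.G0, V=constraints.V0)
    errs = {}
    for ne in element_counts:
        nlp = transcribe(params, CollocationConfig(n_elements=ne), constraints)
        z = collocated_rollout(nlp, nlp.initial_guess())
        tc = nlp.trajectory(z)
        ref = simulate(params, nlp.control_profile(z), constraints.events,
                       x0, grid=nlp.t, base=constraints.base, rtol=1e-10,
                       atol=(1e-10, 1e-11, 1e-11, 1e-12))
        rb = ref.groupby("t", as_index=False).last().set_index("t").reindex(
            nlp.t, method="nearest")
        errs[ne] = {
            s: float(np.max(np.abs(tc[s].values - rb[s].values)
                            / np.maximum(np.abs(rb[s].values), 1e-9)))
            for s in ("X", "P", "G", "V")
        }
    return errs


def heldout_ypx_errors(truth: KineticParameterSet, records, folds,
                       alpha: float = 0.2, seed: int = 1,
                       de_options: DEOptions | None = None) -> list:
    """Leave-one-run-out final-yield prediction errors against the
    generator's noise-free endpoint for the held-out design point."""
    errors = []
    for hold in folds:
        train = [r for i, r in enumerate(records) if i != hold]
        obs = estimate_rates(train, (truth.Y_XrG, truth.Y_PG))
        fits = {}
        for rate in ("uptake", "maintenance", "production"):
            _, fit, _ = eliminate_terms(obs, rate, alpha, seed=seed,
                                        de_options=de_options)
            fits[rate] = fit
        params = assemble_parameter_set(fits, truth.Y_XrG, truth.Y_PG)
        held = records[hold]
        pred = predict_final_ypx(params, held)
        ref = generate_run(truth, held.design_point, noise=NoiseSpec(0, 0, 0),
                           seed=0, run_id="ref")
        true_ypx = float(ref.P_meas[-1] / ref.X_meas[-1])
        errors.append(abs(pred - true_ypx) / true_ypx)
    return errors


def parameter_errors(truth: KineticParameterSet,
                     fitted: KineticParameterSet) -> dict:
    """Relative error of every truth-active parameter.  Temperature laws are
    compared on their natural scale (value at 31 degC plus the three shape
    parameters) because the raw pre-exponential factor is exponentially
    sensitive to the activation energy."""
    errs = {}
    for kind, t_rl in truth.rates.items():
        f_rl = fitted.rates[kind]
        if t_rl.mask["temp"]:
            errs[f"{kind}.temp.ref31"] = (
                float(f_rl.temp.value(31.0)) / float(t_rl.temp.value(31.0))
                - 1.0)
            for attr in ("dG_cat", "T_eq", "dH_eq"):
                errs[f"{kind}.temp.{attr}"] = (
                    getattr(f_rl.temp, attr) / getattr(t_rl.temp, attr) - 1.0)
        else:
            errs[f"{kind}.c"] = f_rl.c / t_rl.c - 1.0
        if t_rl.mask.get("Km"):
            errs[f"{kind}.Km"] = f_rl.Km / t_rl.Km - 1.0
        for m, tv in t_rl.K.items():
            if t_rl.mask[m]:
                errs[f"{kind}.K.{m}"] = f_rl.K[m] / tv - 1.0
    return errs
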