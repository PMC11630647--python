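"""Synthetic training-data generator.

Emulates the statistical structure the fitting stage assumes: a central
composite design over the exponential-feed coefficient mu_f and the set
temperature T (4 center replicates + 4 star + 4 factorial = 12 runs), a 12 h
production phase sampled every 2 h with 35 mL withdrawals, and multiplicative
measurement noise (3% biomass, 15% product, 5% substrate by default).

The ``reduced_default`` truth parameter set is a documented synthetic
stand-in: its mask has the reduced-model structure (3 uptake + 3 maintenance
+ 6 production = 12 active parameters) and its values are chosen so that the
12 runs span informative ranges of every active covariate (substrate stays
quantifiable, roughly one biomass doubling, product reaching ~15-20% of
biomass, a production-rate temperature optimum a few degrees above the design
center).  Correctness of the pipeline is defined through recovery of this
truth, not through any external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import KineticParameterSet, RateLaw, TemperatureLawParams
from .process_model import (
    BaseFeedParams,
    ControlProfile,
    FeedSpec,
    ProcessState,
    SamplingEvent,
    simulate,
    uptake_rate,
)
from .records import ProcessRecord

__all__ = [
    "DesignSpec",
    "NoiseSpec",
    "make_truth_params",
    "generate_run",
    "generate_dataset",
    "quasi_steady_substrate",
]


@dataclass
class DesignSpec:
    """Central composite design over (mu_f, T)."""

    center: tuple = (0.12, 31.0)  # (1/h, degC)
    step: tuple = (0.03, 2.0)
    n_center: int = 4
    star_alpha: float = math.sqrt(2.0)

    def points(self) -> list:
        """(mu_f, T, label) for every run; 12 runs with the defaults."""
        mu0, T0 = self.center
        dmu, dT = self.step
        a = self.star_alpha
        pts = [(mu0, T0, "center") for _ in range(self.n_center)]
        pts += [
            (mu0 + a * dmu, T0, "star"),
            (mu0 - a * dmu, T0, "star"),
            (mu0, T0 + a * dT, "star"),
            (mu0, T0 - a * dT, "star"),
        ]
        pts += [
            (mu0 + s_mu * dmu, T0 + s_T * dT, "factorial")
            for s_mu in (-1, 1)
            for s_T in (-1, 1)
        ]
        return pts


@dataclass
class NoiseSpec:
    """Multiplicative log-normal measurement noise (never negative)."""

    rel_sd_X: float = 0.03
    rel_sd_P: float = 0.15
    rel_sd_G: float = 0.05

    def perturb(self, values, rel_sd, rng):
        values = np.asarray(values, dtype=float)
        if rel_sd == 0:
            return values.copy()
        sigma = math.sqrt(math.log1p(rel_sd**2))
        z = rng.standard_normal(values.shape)
        return values * np.exp(sigma * z - 0.5 * sigma**2)


def make_truth_params(preset: str = "reduced_default") -> KineticParameterSet:
    """Documented synthetic truth parameter sets.

    ``reduced_default``: 12 active parameters in the reduced-model structure
    (uptake: constant scale, Km, substrate self-inhibition; maintenance:
    constant baseline with uptake and product-load activation; production:
    4-parameter temperature law, surplus saturation, generation inhibition).
    ``full_default``: every term active (27 fittable parameters).
    """
    if preset not in ("reduced_default", "full_default"):
        raise ValueError(f"unknown preset {preset!r}")

    uptake = RateLaw(
        kind="uptake",
        c=1.4, Km=1.0,
        K={"G": 10.0, "n": 50.0, "PX": 20.0, "X": 2000.0},
        mask={"temp": False, "Km": True, "G": True, "n": False, "PX": False,
              "X": False},
    )
    maintenance = RateLaw(
        kind="maintenance",
        c=0.04,
        K={"gamma_uptake": 0.25, "G": 100.0, "n": 50.0, "PX": 0.1, "X": 2000.0},
        mask={"temp": False, "gamma_uptake": True, "G": False, "n": False,
              "PX": True, "X": False},
    )
    production_temp = TemperatureLawParams.from_reference(
        rate_at_ref=0.08, dG_cat=120e3, T_eq=308.5, dH_eq=400e3,
        T_ref_celsius=31.0,
    )
    production = RateLaw(
        kind="production",
        c=0.08, temp=production_temp, Km=0.1,
        K={"G": 100.0, "n": 1.0, "PX": 20.0, "X": 2000.0},
        mask={"temp": True, "Km": True, "G": False, "n": True, "PX": False,
              "X": False},
    )
    params = KineticParameterSet(
        uptake=uptake, maintenance=maintenance, production=production,
        Y_XrG=0.55, Y_PG=0.9,
    )
    if preset == "full_default":
        for rl in params.rates.values():
            for t in rl.mask:
                rl.mask[t] = True
            if rl.temp is None:
                rl.temp = TemperatureLawParams.from_reference(
                    rate_at_ref=rl.c, dG_cat=60e3, T_eq=312.0, dH_eq=300e3,
                    T_ref_celsius=31.0,
                )
    params.validate()
    return params


def quasi_steady_substrate(params: KineticParameterSet, demand: float,
                           n=0.0, PX=0.0, X=30.0, T=31.0) -> float:
    """Substrate level where kinetic uptake equals ``demand`` (g/g Xr/h).

    Solves uptake(G) = demand on the rising branch; raises if the demand
    exceeds the kinetic maximum over G (overfeeding).
    """

    def resid(G):
        return float(uptake_rate(G, n, PX, X, T, params)) - demand

    # uptake has an interior maximum in G when self-inhibition is active
    grid = np.geomspace(1e-6, 200.0, 400)
    vals = np.array([resid(g) for g in grid])
    if vals.max() < 0:
        raise ValueError("feed demand exceeds maximal kinetic uptake capacity")
    i_peak = int(np.argmax(vals))
    if resid(grid[0]) >= 0:
        return float(grid[0])
    return float(brentq(resid, grid[0], grid[i_peak]))


DEFAULT_EVENTS = (2.0, 4.0, 6.0, 8.0, 10.0)


def generate_run(
    truth: KineticParameterSet,
    point: tuple,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    run_id: str = "run",
    X0: float = 30.0,
    V0: float = 1.3,
    Gf: float = 390.0,
    tend: float = 12.0,
    sample_interval: float = 2.0,
    sample_volume: float = 0.035,
    base: BaseFeedParams | None = None,
    G_loq: float = 0.1,
) -> ProcessRecord:
    """Simulate one fed-batch run and corrupt the offline measurements.

    The exponential feed seed value is f0 = mu_f*X0*V0/Y_XrG (the classical
    choice that would sustain growth at mu_f if all uptake went to growth).
    The initial substrate level is the quasi-steady value matching the feed
    at t=0: the emulated protocol induces production during a running
    fed-batch, so substrate is at its working level, not zero.  Online feed
    and temperature are stored noise-free.
    """
    mu_f, T_set = float(point[0]), float(point[1])
    noise = noise or NoiseSpec()
    base = base if base is not None else BaseFeedParams()
    rng = np.random.default_rng(seed)

    f0 = mu_f * X0 * V0 / truth.Y_XrG  # g/h
    spec = FeedSpec(kind="exponential", Gf=Gf, f0=f0, mu_f=mu_f)
    G0 = quasi_steady_substrate(truth, f0 / (X0 * V0), X=X0, T=T_set)
    controls = ControlProfile.from_feed_spec(spec, T_set, tend)
    events = [SamplingEvent(t, sample_volume) for t in DEFAULT_EVENTS
              if t < tend]
    sample_times = np.arange(0.0, tend + 1e-9, sample_interval)
    x0 = ProcessState(t=0.0, X=X0, P=0.0, G=G0, V=V0)
    traj = simulate(truth, controls, events, x0, grid=sample_times, base=base)
    # first row at each sample time (pre-event values at event times)
    traj_s = traj.groupby("t", as_index=False).first()
    traj_s = traj_s[np.isin(traj_s["t"].values.round(9),
                            sample_times.round(9))]

    X_true = traj_s["X"].to_numpy()
    P_true = traj_s["P"].to_numpy()
    G_true = traj_s["G"].to_numpy()
    X_meas = noise.perturb(X_true, noise.rel_sd_X, rng)
    P_meas = np.minimum(noise.perturb(P_true, noise.rel_sd_P, rng), X_meas)
    G_meas = noise.perturb(G_true, noise.rel_sd_G, rng)
    G_meas = np.where(G_meas < G_loq, np.nan, G_meas)  # censor below LOQ

    t_online = np.arange(0.0, tend + 1e-9, 0.05)
    return ProcessRecord(
        run_id=run_id,
        sample_times=sample_times,
        X_meas=X_meas,
        P_meas=P_meas,
        G_meas=G_meas,
        t_online=t_online,
        f_online=spec(t_online),
        T_online=np.full_like(t_online, T_set),
        V0=V0,
        X0=X0,
        Gf=Gf,
        sampling_events=events,
        design_point=(mu_f, T_set),
        base_params=base,
        G_loq=G_loq,
    )


def generate_dataset(
    truth: KineticParameterSet,
    design: DesignSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
    **run_kwargs,
) -> list[ProcessRecord]:
    """One record per design point (12 with the default design)."""
    design = design or DesignSpec()
    noise = noise or NoiseSpec()
    seeds = np.random.SeedSequence(seed).spawn(len(design.points()))
    records = []
    for i, ((mu_f, T, label), ss) in enumerate(zip(design.points(), seeds)):
        rid = f"run{i:02d}_{label}"
        records.append(
            generate_run(
                truth, (mu_f, T), noise=noise,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                run_id=rid, **run_kwargs,
            )
        )
    return records
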