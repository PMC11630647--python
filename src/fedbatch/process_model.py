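"""Fed-batch process model: state ODEs, kinetic rate laws, feeds, simulator.

State variables (concentrations in the broth, volume of the broth):

    Xdot = mu*X  - (f/V)*X
    Pdot = pi*X  - (f/V)*P
    Gdot = -gamma*X + (f/V)*(Gf - G)
    Vdot = f

with total biomass X (g/L), intracellular product P (g/L, part of the
biomass), substrate G (g/L) and volume V (L).  ``f`` is the total volumetric
feed (substrate feed converted via the feed concentration Gf, plus base feed
for pH control).  Only the metabolically active residual biomass
Xr = X - P grows and produces, which introduces the factor Xr/X in the rate
partitioning:

    gamma_circ = gamma_mu + gamma_pi + gamma_alpha      (additive uptake split)
    pi = gamma_pi * Y_PG * Xr/X
    mu = pi + gamma_mu * Y_XrG * Xr/X
    gamma (per total biomass) = gamma_circ * Xr/X

Sampling events remove broth volume instantaneously; concentrations are
unchanged across an event.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import KineticParameterSet, temperature_factor  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessState",
    "FeedSpec",
    "BaseFeedParams",
    "SamplingEvent",
    "ControlProfile",
    "SimulationError",
    "uptake_rate",
    "maintenance_rate",
    "production_uptake_rate",
    "growth_partition",
    "evaluate_rates",
    "ode_rhs",
    "feed_rate",
    "base_feed",
    "generations",
    "simulate",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class ProcessState:
    """Process state at one time point."""

    t: float  # h
    X: float  # g/L total biomass
    P: float  # g/L product
    G: float  # g/L substrate
    V: float  # L broth volume

    def validate(self) -> None:
        if not all(math.isfinite(v) for v in (self.t, self.X, self.P, self.G, self.V)):
            raise ValueError("non-finite state")
        if self.X < 0 or self.P < 0 or self.G < 0 or self.V <= 0:
            raise ValueError(f"invalid state: X={self.X}, P={self.P}, G={self.G}, V={self.V}")
        if self.P > self.X * (1 + 1e-6):
            raise ValueError("product exceeds total biomass (P > X)")

    @property
    def Xr(self) -> float:
        return self.X - self.P


@dataclass
class FeedSpec:
    """Substrate feed law, as substrate mass flow (g/h).

    kinds: ``exponential`` f0*exp(mu_f*t); ``linear`` phi1 + phi2*t;
    ``piecewise`` linear interpolation between (knot_times, knot_values).
    Converted to volumetric flow by dividing by the feed concentration Gf.
    """

    kind: str
    Gf: float  # g/L
    f0: float | None = None  # g/h
    mu_f: float | None = None  # 1/h
    phi1: float | None = None  # g/h
    phi2: float | None = None  # g/h^2
    knot_times: np.ndarray | None = None
    knot_values: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("exponential", "linear", "piecewise"):
            raise ValueError(f"unknown feed kind {self.kind!r}")
        if self.Gf <= 0:
            raise ValueError("feed substrate concentration Gf must be > 0")

    def __call__(self, t):
        return feed_rate(t, self)


def feed_rate(t, spec: FeedSpec):
    """Substrate mass feed (g/h) at time t (h).  Vectorized over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12):
        raise ValueError("feed evaluated at negative time")
    if spec.kind == "exponential":
        out = spec.f0 * np.exp(spec.mu_f * t)
    elif spec.kind == "linear":
        out = spec.phi1 + spec.phi2 * t
        if np.any(out < 0):
            logger.warning("linear feed went negative; clamped at 0")
            out = np.maximum(out, 0.0)
    else:
        out = np.interp(t, spec.knot_times, spec.knot_values)
    return np.maximum(out, 0.0)


@dataclass
class BaseFeedParams:
    """Linear base-addition model fbase = X*V*(a*mu + b), clamped at 0.

    Units: with X in g/L, V in L and mu in 1/h, ``a`` and ``b`` are empirical
    coefficients giving fbase in L/h.
    """

    a: float = 13900e-7
    b: float = -1.1e-7


def base_feed(X, V, mu, p: BaseFeedParams):
    """Base feed (L/h), clamped at 0.  Vectorized."""
    return np.maximum(np.asarray(X) * np.asarray(V) * (p.a * np.asarray(mu) + p.b), 0.0)


@dataclass
class SamplingEvent:
    t_sample: float  # h
    volume_removed: float = 0.035  # L


@dataclass
class ControlProfile:
    """Piecewise-linear feed (g/h substrate) and temperature (degC) profiles."""

    t_knots: np.ndarray
    feed_values: np.ndarray  # g/h
    T_values: np.ndarray  # degC
    Gf: float  # g/L
    tend: float  # h

    def __post_init__(self):
        self.t_knots = np.asarray(self.t_knots, dtype=float)
        self.feed_values = np.asarray(self.feed_values, dtype=float)
        self.T_values = np.asarray(self.T_values, dtype=float)
        if np.any(np.diff(self.t_knots) <= 0):
            raise ValueError("control knots must be strictly increasing")
        if np.any(self.feed_values < -1e-12):
            raise ValueError("feed must be non-negative")
        if self.tend <= 0:
            raise ValueError("tend must be positive")

    @classmethod
    def from_feed_spec(
        cls, spec: FeedSpec, T, tend: float, n_knots: int = 121
    ) -> "ControlProfile":
        t = np.linspace(0.0, tend, n_knots)
        T_arr = np.full_like(t, float(T)) if np.ndim(T) == 0 else np.interp(
            t, np.linspace(0, tend, len(T)), T
        )
        return cls(
            t_knots=t,
            feed_values=feed_rate(t, spec),
            T_values=T_arr,
            Gf=spec.Gf,
            tend=float(tend),
        )

    def feed(self, t):
        return np.interp(t, self.t_knots, self.feed_values)

    def temperature(self, t):
        return np.interp(t, self.t_knots, self.T_values)


# --------------------------------------------------------------------------
# kinetic rate laws
# --------------------------------------------------------------------------

def _check_nonneg(**kwargs):
    for name, v in kwargs.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"negative {name} passed to a rate law")


def uptake_rate(G, n, PX, X, T, params: KineticParameterSet):
    """Specific substrate uptake gamma_circ (g/g/h), per residual biomass.

    Michaelis-Menten in G with optional non-competitive inhibition by
    G, n, P/X and X.
    """
    _check_nonneg(G=G, n=n, PX=PX, X=X)
    rl = params.uptake
    scale = rl.scale(T)
    sat = np.asarray(G, dtype=float) / (rl.Km + np.asarray(G, dtype=float))
    return scale * sat * rl.modifier_factor({"G": G, "n": n, "PX": PX, "X": X})


def maintenance_rate(gamma_uptake, G, n, PX, X, T, params: KineticParameterSet):
    """Specific maintenance demand gamma_alpha (g/g/h).

    Baseline gamma_min multiplied by active linear activation terms.
    """
    _check_nonneg(gamma_uptake=gamma_uptake, G=G, n=n, PX=PX, X=X)
    rl = params.maintenance
    scale = rl.scale(T)
    return scale * rl.modifier_factor(
        {"gamma_uptake": gamma_uptake, "G": G, "n": n, "PX": PX, "X": X}
    )


def production_uptake_rate(gamma_uptake, gamma_alpha, G, n, PX, X, T,
                           params: KineticParameterSet):
    """Specific production-directed uptake gamma_pi (g/g/h).

    Michaelis-Menten in the surplus uptake s = max(gamma_circ - gamma_alpha, 0)
    (production cannot run on a negative surplus) with optional
    non-competitive inhibitions.
    """
    rl = params.production
    scale = rl.scale(T)
    s = np.maximum(np.asarray(gamma_uptake, dtype=float)
                   - np.asarray(gamma_alpha, dtype=float), 0.0)
    if rl.mask["Km"]:
        sat = s / (rl.Km + s)
    else:
        sat = (s > 0).astype(float)
    return scale * sat * rl.modifier_factor({"G": G, "n": n, "PX": PX, "X": X})


def growth_partition(gamma_uptake, gamma_pi, gamma_alpha,
                     params: KineticParameterSet, Xr, X):
    """Split uptake into growth flux and convert to observable rates.

    Returns (gamma_mu, mu, pi).  gamma_mu may be negative (starvation /
    product-degradation regimes); it is not floored.
    """
    Xr = np.asarray(Xr, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0) or np.any(Xr <= 0) or np.any(Xr > X * (1 + 1e-9)):
        raise ValueError("growth partition requires 0 < Xr <= X")
    gamma_mu = np.asarray(gamma_uptake) - np.asarray(gamma_pi) - np.asarray(gamma_alpha)
    frac = Xr / X
    pi = np.asarray(gamma_pi) * params.Y_PG * frac
    mu = pi + gamma_mu * params.Y_XrG * frac
    return gamma_mu, mu, pi


def evaluate_rates(params: KineticParameterSet, G, n, PX, X, T):
    """Evaluate all specific rates at given covariates.  Vectorized.

    Returns a dict with gamma_circ, gamma_alpha, gamma_pi, gamma_mu, mu, pi.
    """
    g_circ = uptake_rate(G, n, PX, X, T, params)
    g_alpha = maintenance_rate(g_circ, G, n, PX, X, T, params)
    g_pi = production_uptake_rate(g_circ, g_alpha, G, n, PX, X, T, params)
    X = np.asarray(X, dtype=float)
    PX = np.asarray(PX, dtype=float)
    Xr = X * (1.0 - PX)
    g_mu, mu, pi = growth_partition(g_circ, g_pi, g_alpha, params, Xr, X)
    return {
        "gamma_circ": g_circ,
        "gamma_alpha": g_alpha,
        "gamma_pi": g_pi,
        "gamma_mu": g_mu,
        "mu": mu,
        "pi": pi,
    }


def ode_rhs(state, f, Gf, mu, pi, gamma):
    """Right-hand side of the state ODEs.

    ``f`` is the total volumetric feed (L/h); ``gamma`` is uptake per *total*
    biomass, gamma = gamma_circ * Xr/X.
    """
    X, P, G, V = state.X, state.P, state.G, state.V
    if V <= 0:
        raise SimulationError("volume became non-positive")
    dil = f / V
    return (
        mu * X - dil * X,
        pi * X - dil * P,
        -gamma * X + dil * (Gf - G),
        f,
    )


def generations(X, V, X0, V0, removed_fraction=1.0):
    """Number of generations (biomass doublings) since t=0.

    ``removed_fraction`` is the cumulative product of (1 - v/V) over past
    sampling events; it corrects the total-biomass ratio for biomass removed
    by sampling so n never drops at an event.  Without events this is
    n = log2(X*V / (X0*V0)).
    """
    ratio = np.asarray(X, dtype=float) * np.asarray(V, dtype=float) / (
        X0 * V0 * removed_fraction
    )
    return np.log2(np.maximum(ratio, 1.0))


# --------------------------------------------------------------------------
# forward simulator
# --------------------------------------------------------------------------

def _rhs_factory(params, controls: ControlProfile, base: BaseFeedParams | None,
                 X0, V0, removed_fraction, warn_state):
    Gf = controls.Gf

    def rhs(t, y):
        X, P, G, V = y
        if V <= 0:
            raise SimulationError(f"volume non-positive at t={t:.3f} h")
        Xc = max(X, 1e-12)
        Pc = min(max(P, 0.0), Xc)
        if P > X * (1 + 1e-6) and not warn_state["PX"]:
            logger.warning("P exceeded X during integration (numerical overshoot)")
            warn_state["PX"] = True
        Gc = max(G, 0.0)
        Xr = max(Xc - Pc, 1e-12)
        PX = Pc / Xc
        n = generations(Xc, V, X0, V0, removed_fraction)
        T = float(controls.temperature(t))
        r = evaluate_rates(params, Gc, n, PX, Xc, T)
        gamma = float(r["gamma_circ"]) * Xr / Xc
        f_sub = float(controls.feed(t)) / Gf  # volumetric substrate feed, L/h
        f_base = float(base_feed(Xc, V, r["mu"], base)) if base is not None else 0.0
        f = f_sub + f_base
        dil = f / V
        # only the substrate feed carries substrate; the base feed merely dilutes
        return [
            float(r["mu"]) * Xc - dil * X,
            float(r["pi"]) * Xc - dil * P,
            -gamma * Xc + (f_sub * Gf - f * Gc) / V,
            f,
        ]

    return rhs


def simulate(
    params: KineticParameterSet,
    controls: ControlProfile,
    events: list[SamplingEvent] | None,
    x0: ProcessState,
    grid: np.ndarray | None = None,
    base: BaseFeedParams | None = None,
    rtol: float = 1e-7,
    atol: tuple = (1e-7, 1e-8, 1e-8, 1e-9),
    method: str = "LSODA",
) -> pd.DataFrame:
    """Integrate the process ODEs piecewise between sampling events.

    At each event the volume drops by ``volume_removed`` while the
    concentrations X, P, G are unchanged.  Returns a tidy trajectory frame
    with states, controls and all derived rates.  The substrate equation is
    stiff, hence the implicit-capable default integrator and the tighter
    absolute tolerance on G.
    """
    params.validate()
    x0.validate()
    events = sorted(events or [], key=lambda e: e.t_sample)
    tend = controls.tend
    for e in events:
        if not (0.0 < e.t_sample < tend):
            raise ValueError("sampling events must lie strictly inside (0, tend)")
    if grid is None:
        grid = np.linspace(0.0, tend, 241)
    grid = np.asarray(grid, dtype=float)

    boundaries = [0.0] + [e.t_sample for e in events] + [tend]
    warn_state = {"PX": False}
    removed_fraction = 1.0
    y = np.array([x0.X, x0.P, x0.G, x0.V], dtype=float)
    rows_t, rows_y, rows_frac = [], [], []
    for i in range(len(boundaries) - 1):
        t0, t1 = boundaries[i], boundaries[i + 1]
        seg_grid = grid[(grid >= t0 - 1e-12) & (grid <= t1 + 1e-12)]
        t_eval = np.unique(np.concatenate([[t0], seg_grid, [t1]]))
        rhs = _rhs_factory(params, controls, base, x0.X, x0.V,
                           removed_fraction, warn_state)
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, t_eval=t_eval,
            rtol=rtol, atol=list(atol), max_step=(t1 - t0),
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{t0}, {t1}] h: {sol.message}"
            )
        rows_t.append(sol.t)
        rows_y.append(sol.y.T)
        rows_frac.append(np.full_like(sol.t, removed_fraction))
        y = sol.y[:, -1].copy()
        if i < len(events):
            ev = events[i]
            if ev.volume_removed >= y[3]:
                raise SimulationError(
                    f"sampling at t={ev.t_sample} h would empty the reactor"
                )
            removed_fraction *= 1.0 - ev.volume_removed / y[3]
            y[3] -= ev.volume_removed

    t_all = np.concatenate(rows_t)
    y_all = np.vstack(rows_y)
    X, P, G, V = (y_all[:, j] for j in range(4))
    G = np.maximum(G, 0.0)
    P = np.minimum(np.maximum(P, 0.0), X)
    if np.any(X < -1e-8) or np.any(V <= 0):
        raise SimulationError("negative states beyond tolerance in trajectory")

    rem = np.concatenate(rows_frac)
    n = generations(X, V, x0.X, x0.V, rem)
    PX = np.divide(P, X, out=np.zeros_like(P), where=X > 0)
    T = controls.temperature(t_all)
    r = evaluate_rates(params, G, n, PX, np.maximum(X, 1e-12), T)
    f_sub = controls.feed(t_all)  # g/h
    f_base = (base_feed(X, V, r["mu"], base) if base is not None
              else np.zeros_like(t_all))
    out = pd.DataFrame(
        {
            "t": t_all, "X": X, "P": P, "G": G, "V": V,
            "f_substrate": f_sub, "f_base": f_base, "T": T,
            "n": n, "Xr": X - P,
            "gamma_circ": r["gamma_circ"], "gamma_pi": r["gamma_pi"],
            "gamma_alpha": r["gamma_alpha"], "gamma_mu": r["gamma_mu"],
            "mu": r["mu"], "pi": r["pi"],
        }
    )
    # keep both the pre- and post-event rows at event times
    return out.reset_index(drop=True)
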