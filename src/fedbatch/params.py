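"""Parameter containers for the fed-batch kinetic model.

The model describes three cell-specific substrate fluxes (all in g substrate
per g residual biomass per hour):

* ``uptake`` (gamma_circ)   -- total substrate uptake, a Michaelis-Menten term
  in the substrate concentration G with optional non-competitive inhibition by
  G, the number of generations n, the product load P/X and the biomass X.
* ``production`` (gamma_pi) -- uptake channelled to product, Michaelis-Menten
  in the surplus uptake (gamma_circ - gamma_alpha) with the same optional
  inhibitions.
* ``maintenance`` (gamma_alpha) -- a baseline demand multiplied by optional
  linear activation terms in gamma_circ, G, n, P/X and X.

Each rate's scale is either a 4-parameter temperature law (transition-state
rate with a logistic high-temperature inactivation) or a single constant.
Counting the temperature laws as active, each rate has 9 parameters
(4 + saturation + 4 modifiers for uptake/production, 4 + 5 activations for
maintenance): 27 fittable parameters, plus the two externally supplied yields
Y_XrG and Y_PG, for 29 in total.

A per-term boolean mask marks which terms are currently part of the model;
inactive inhibition/activation terms contribute a factor of exactly 1 and an
inactive temperature law collapses to the single constant ``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    BOLTZMANN_KB,
    GAS_CONSTANT_R,
    PLANCK_H,
    SECONDS_PER_HOUR,
    celsius_to_kelvin,
)

__all__ = [
    "TemperatureLawParams",
    "RateLaw",
    "KineticParameterSet",
    "MODIFIERS",
    "temperature_factor",
]

#: modifier (inhibition/activation) covariates per rate kind, in canonical order
MODIFIERS = {
    "uptake": ("G", "n", "PX", "X"),
    "production": ("G", "n", "PX", "X"),
    "maintenance": ("gamma_uptake", "G", "n", "PX", "X"),
}


@dataclass
class TemperatureLawParams:
    """Transition-state temperature law with logistic inactivation.

    value(T) = E0 * (kB*T_K/h) * exp(-dG_cat/(R*T_K))
               / (1 + exp[(dH_eq/R) * (1/T_eq - 1/T_K)])

    ``E0`` is a hypothetical enzyme abundance that absorbs the kB*T/h
    magnitude; its absolute scale is not physically interpretable.  ``dG_cat``
    (J/mol) is the activation energy, ``T_eq`` (K) the half-inactivation
    temperature and ``dH_eq`` (J/mol) sets how abruptly the rate collapses
    above ``T_eq``.
    """

    E0: float
    dG_cat: float  # J/mol
    T_eq: float  # K
    dH_eq: float  # J/mol

    def validate(self) -> None:
        vals = (self.E0, self.dG_cat, self.T_eq, self.dH_eq)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite temperature-law parameter: {vals}")
        if self.E0 <= 0 or self.T_eq <= 0 or self.dH_eq <= 0:
            raise ValueError(
                "temperature-law parameters must satisfy E0>0, T_eq>0, dH_eq>0"
            )

    def value(self, T_celsius):
        return temperature_factor(T_celsius, self)

    @classmethod
    def from_reference(
        cls, rate_at_ref: float, dG_cat: float, T_eq: float, dH_eq: float,
        T_ref_celsius: float = 31.0,
    ) -> "TemperatureLawParams":
        """Build a law from its *value* at a reference temperature.

        Much better conditioned than specifying E0 directly, whose magnitude
        is astronomically small once kB*T/h and the Boltzmann factor are
        absorbed.
        """
        p = cls(E0=1.0, dG_cat=dG_cat, T_eq=T_eq, dH_eq=dH_eq)
        base = float(temperature_factor(T_ref_celsius, p))
        return cls(E0=float(rate_at_ref) / base, dG_cat=float(dG_cat),
                   T_eq=float(T_eq), dH_eq=float(dH_eq))


def temperature_factor(T_celsius, params):
    """Evaluate the temperature law (or a constant) at ``T_celsius``.

    ``params`` is a :class:`TemperatureLawParams` or a plain number (the
    no-temperature-effect simplification, where the whole law is one
    constant).  Temperatures are interface-level degrees Celsius; the kelvin
    conversion is internal.  Vectorized over ``T_celsius``.
    """
    if not isinstance(params, TemperatureLawParams):
        c = float(params)
        if not math.isfinite(c):
            raise ValueError("non-finite constant rate parameter")
        return c * np.ones_like(np.asarray(T_celsius, dtype=float))
    params.validate()
    T = np.asarray(T_celsius, dtype=float)
    if np.any(T < 0.0) or np.any(T > 60.0):
        raise ValueError("temperature outside the plausible 0-60 degC range")
    TK = celsius_to_kelvin(T)
    prefactor = params.E0 * BOLTZMANN_KB * TK / PLANCK_H * SECONDS_PER_HOUR
    arrhenius = np.exp(-params.dG_cat / (GAS_CONSTANT_R * TK))
    inact = 1.0 + np.exp(
        params.dH_eq / GAS_CONSTANT_R * (1.0 / params.T_eq - 1.0 / TK)
    )
    return prefactor * arrhenius / inact


@dataclass
class RateLaw:
    """One of the three rate equations, with its activity mask.

    ``mask`` keys: ``"temp"`` (temperature law active vs constant), ``"Km"``
    (saturation term; uptake and production only) and one key per modifier in
    :data:`MODIFIERS`.  ``removable`` marks which terms the elimination
    algorithm may drop; the uptake saturation constant is non-removable
    because dropping it would let simulated substrate go negative.
    """

    kind: str
    c: float = 0.1  # constant scale, used when the temperature law is inactive
    temp: TemperatureLawParams | None = None
    Km: float | None = None
    K: dict = field(default_factory=dict)  # modifier constants
    mask: dict = field(default_factory=dict)
    removable: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in MODIFIERS:
            raise ValueError(f"unknown rate kind {self.kind!r}")
        has_km = self.kind in ("uptake", "production")
        terms = (("temp",) + (("Km",) if has_km else ()) + MODIFIERS[self.kind])
        for t in terms:
            self.mask.setdefault(t, False)
        self.mask = {t: bool(self.mask[t]) for t in terms}
        # the saturation constants are structural: dropping the uptake Km
        # lets simulated substrate go negative, and dropping the production
        # Km leaves a discontinuous all-or-nothing rate at zero surplus
        default_removable = {t: True for t in terms}
        if self.kind in ("uptake", "production"):
            default_removable["Km"] = False
        for t, v in default_removable.items():
            self.removable.setdefault(t, v)
        if self.kind == "uptake":
            self.mask["Km"] = True  # always present

    # --- structure ---------------------------------------------------------
    @property
    def term_names(self):
        return tuple(self.mask.keys())

    def n_parameters(self, *, full: bool = False) -> int:
        """Number of fitted parameters (4 per active temperature law, 1 for
        the constant scale otherwise, 1 per other active term).  With
        ``full=True``, count as if every term were active."""
        n = 0
        for t in self.term_names:
            active = True if full else self.mask[t]
            if t == "temp":
                n += 4 if active else 1
            elif active:
                n += 1
        return n

    def scale(self, T_celsius):
        """gamma_max (or gamma_min for maintenance) at temperature T."""
        if self.mask["temp"]:
            if self.temp is None:
                raise ValueError(f"{self.kind}: temperature law active but unset")
            return temperature_factor(T_celsius, self.temp)
        return temperature_factor(T_celsius, self.c)

    def modifier_factor(self, covariates: dict):
        """Product over active modifier terms.

        Inhibitions (uptake, production): 1/(1 + i/K_i).
        Activations (maintenance):        1 + i/K_i.
        Inactive terms contribute exactly 1 (the K -> infinity limit).
        """
        out = 1.0
        inhibit = self.kind != "maintenance"
        for name in MODIFIERS[self.kind]:
            if not self.mask[name]:
                continue
            K = self.K.get(name)
            if K is None or K <= 0:
                raise ValueError(f"{self.kind}: active term {name} needs K > 0")
            x = np.asarray(covariates[name], dtype=float)
            out = out / (1.0 + x / K) if inhibit else out * (1.0 + x / K)
        return out

    def validate(self) -> None:
        if self.mask["temp"] and self.temp is not None:
            self.temp.validate()
        if not self.mask["temp"] and (not math.isfinite(self.c) or self.c < 0):
            raise ValueError(f"{self.kind}: constant scale must be finite and >= 0")
        if self.mask.get("Km") and (self.Km is None or self.Km <= 0):
            raise ValueError(f"{self.kind}: active Km must be > 0")
        for name in MODIFIERS[self.kind]:
            if self.mask[name] and (self.K.get(name) is None or self.K[name] <= 0):
                raise ValueError(f"{self.kind}: active K_{name} must be > 0")


@dataclass
class KineticParameterSet:
    """All parameters of the process model: three rate laws plus yields.

    The yields ``Y_XrG`` (residual biomass per substrate, g/g) and ``Y_PG``
    (product per substrate, g/g) come from outside (e.g. a genome-scale
    model) and are never fitted.
    """

    uptake: RateLaw
    maintenance: RateLaw
    production: RateLaw
    Y_XrG: float = 0.55
    Y_PG: float = 0.9

    def __post_init__(self):
        expected = {"uptake", "maintenance", "production"}
        got = {self.uptake.kind, self.maintenance.kind, self.production.kind}
        if got != expected:
            raise ValueError(f"rate kinds must be {expected}, got {got}")

    @property
    def rates(self):
        return {
            "uptake": self.uptake,
            "maintenance": self.maintenance,
            "production": self.production,
        }

    def n_parameters(self, *, full: bool = True, include_yields: bool = True) -> int:
        n = sum(r.n_parameters(full=full) for r in self.rates.values())
        return n + (2 if include_yields else 0)

    @property
    def n_fittable(self) -> int:
        """Fittable parameters in the general model (yields excluded)."""
        return self.n_parameters(full=True, include_yields=False)

    @property
    def n_active(self) -> int:
        """Currently active fitted parameters under the mask."""
        return self.n_parameters(full=False, include_yields=False)

    def validate(self) -> None:
        if not (0 < self.Y_XrG) or not (0 < self.Y_PG):
            raise ValueError("yields must be positive")
        for r in self.rates.values():
            r.validate()

    def copy(self) -> "KineticParameterSet":
        def _copy_rate(r: RateLaw) -> RateLaw:
            return replace(
                r,
                temp=None if r.temp is None else replace(r.temp),
                K=dict(r.K),
                mask=dict(r.mask),
                removable=dict(r.removable),
            )

        return KineticParameterSet(
            uptake=_copy_rate(self.uptake),
            maintenance=_copy_rate(self.maintenance),
            production=_copy_rate(self.production),
            Y_XrG=self.Y_XrG,
            Y_PG=self.Y_PG,
        )

    # --- flat config round-trip --------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {"yields": {"Y_XrG": float(self.Y_XrG),
                                "Y_PG": float(self.Y_PG)}}
        for kind, r in self.rates.items():
            d: dict = {"c": float(r.c)}
            if r.temp is not None:
                d["temp"] = {
                    "E0": float(r.temp.E0),
                    "dG_cat": float(r.temp.dG_cat),
                    "T_eq": float(r.temp.T_eq),
                    "dH_eq": float(r.temp.dH_eq),
                }
            if r.Km is not None:
                d["Km"] = float(r.Km)
            d["K"] = {k: float(v) for k, v in r.K.items()}
            d["mask"] = dict(r.mask)
            d["removable"] = dict(r.removable)
            out[kind] = d
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameterSet":
        rates = {}
        for kind in ("uptake", "maintenance", "production"):
            rd = d[kind]
            temp = None
            if "temp" in rd and rd["temp"] is not None:
                temp = TemperatureLawParams(**rd["temp"])
            rates[kind] = RateLaw(
                kind=kind,
                c=float(rd.get("c", 0.0)),
                temp=temp,
                Km=rd.get("Km"),
                K={k: float(v) for k, v in rd.get("K", {}).items()},
                mask=dict(rd.get("mask", {})),
                removable=dict(rd.get("removable", {})),
            )
        y = d.get("yields", {})
        return cls(
            uptake=rates["uptake"],
            maintenance=rates["maintenance"],
            production=rates["production"],
            Y_XrG=float(y.get("Y_XrG", 0.55)),
            Y_PG=float(y.get("Y_PG", 0.9)),
        )
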