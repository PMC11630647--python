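"""Containers for experimental (or emulated) fermentation run data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process_model import BaseFeedParams, SamplingEvent

__all__ = ["ProcessRecord", "RateObservations"]


@dataclass
class ProcessRecord:
    """One fed-batch run: offline measurements, online controls, metadata.

    Offline measurements (every sampling interval): biomass ``X_meas``,
    product ``P_meas`` and substrate ``G_meas`` in g/L.  Substrate values
    below the limit of quantification are stored as NaN (censored).  Online
    channels: substrate feed ``f_online`` (g/h) and temperature ``T_online``
    (degC) on the dense ``t_online`` grid.
    """

    run_id: str
    sample_times: np.ndarray  # h
    X_meas: np.ndarray  # g/L
    P_meas: np.ndarray  # g/L
    G_meas: np.ndarray  # g/L, NaN where censored
    t_online: np.ndarray  # h
    f_online: np.ndarray  # g/h substrate mass feed
    T_online: np.ndarray  # degC
    V0: float  # L
    X0: float  # g/L
    Gf: float  # g/L
    sampling_events: list = field(default_factory=list)
    design_point: tuple = (np.nan, np.nan)  # (mu_f 1/h, T_set degC)
    base_params: BaseFeedParams | None = None
    G_loq: float = 0.1  # g/L

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.X_meas = np.asarray(self.X_meas, dtype=float)
        self.P_meas = np.asarray(self.P_meas, dtype=float)
        self.G_meas = np.asarray(self.G_meas, dtype=float)
        self.t_online = np.asarray(self.t_online, dtype=float)
        self.f_online = np.asarray(self.f_online, dtype=float)
        self.T_online = np.asarray(self.T_online, dtype=float)

    def validate(self) -> None:
        if len(self.sample_times) < 4:
            raise ValueError("at least 4 sample points required for smoothing")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.X0 <= 0 or self.V0 <= 0 or self.Gf <= 0:
            raise ValueError("X0, V0, Gf must be positive")
        for arr, name in ((self.X_meas, "X"), (self.P_meas, "P")):
            if len(arr) != len(self.sample_times):
                raise ValueError(f"{name} series length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"negative {name} measurement")
        if np.any(self.P_meas > self.X_meas * (1 + 1e-6)):
            raise ValueError("product measurement exceeds biomass (P > X)")

    @property
    def tend(self) -> float:
        return float(self.sample_times[-1])

    def feed(self, t):
        return np.interp(t, self.t_online, self.f_online)

    def temperature(self, t):
        return np.interp(t, self.t_online, self.T_online)

    @property
    def uptake_quantifiable(self) -> bool:
        """True when enough substrate measurements are above the LOQ to fit
        uptake kinetics from this run."""
        return int(np.sum(np.isfinite(self.G_meas))) >= 4

    def offline_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.sample_times, "X": self.X_meas, "P": self.P_meas,
             "G": self.G_meas}
        )

    def online_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t_online, "f": self.f_online, "T": self.T_online}
        )


@dataclass
class RateObservations:
    """Per-run, per-timepoint observed specific rates with covariates.

    ``data`` columns: run_id, t, gamma_circ_hat, gamma_alpha_hat,
    gamma_pi_hat, gamma_mu_hat, G, n, PX, X, T, surplus, weight,
    valid_uptake.  Additivity gamma_circ = gamma_alpha + gamma_pi + gamma_mu
    holds exactly by construction.
    """

    data: pd.DataFrame
    Y_XrG: float
    Y_PG: float

    REQUIRED = (
        "run_id", "t", "gamma_circ_hat", "gamma_alpha_hat", "gamma_pi_hat",
        "gamma_mu_hat", "G", "n", "PX", "X", "T", "surplus", "weight",
        "valid_uptake",
    )

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"rate observations missing columns: {sorted(missing)}")

    def __len__(self):
        return len(self.data)

    @staticmethod
    def concat(parts: list["RateObservations"]) -> "RateObservations":
        if not parts:
            raise ValueError("no rate observations to concatenate")
        y = {(p.Y_XrG, p.Y_PG) for p in parts}
        if len(y) != 1:
            raise ValueError("inconsistent yields across observation sets")
        return RateObservations(
            data=pd.concat([p.data for p in parts], ignore_index=True),
            Y_XrG=parts[0].Y_XrG,
            Y_PG=parts[0].Y_PG,
        )
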