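"""Response-surface baseline: quadratic model of endpoint yield.

The classical alternative to kinetic modeling: fit a full second-degree
polynomial

    y = c + c_f*mu_f + c_T*T + c_fT*mu_f*T + c_f2*mu_f^2 + c_T2*T^2

to the endpoint target (final product-to-biomass yield by default) of a
central-composite-designed set of runs by ordinary least squares, then locate
the constrained optimum of the fitted quadratic.  Fitted on the natural
variable scale; a coded-units option is available for textbook CCD
comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm_api

__all__ = ["RSMModel", "fit_rsm", "rsm_optimum", "endpoint_table"]

_TERMS = ("const", "mu_f", "T", "mu_f:T", "mu_f^2", "T^2")


@dataclass
class RSMModel:
    coefficients: pd.Series  # indexed by _TERMS
    p_values: pd.Series
    R2: float
    R2_adj: float
    coding: tuple | None  # (center, halfwidth) per factor when coded
    n_points: int

    def predict(self, mu_f, T):
        mu_f = np.asarray(mu_f, dtype=float)
        T = np.asarray(T, dtype=float)
        if self.coding is not None:
            (c_mu, h_mu), (c_T, h_T) = self.coding
            mu_f = (mu_f - c_mu) / h_mu
            T = (T - c_T) / h_T
        b = self.coefficients
        return (b["const"] + b["mu_f"] * mu_f + b["T"] * T
                + b["mu_f:T"] * mu_f * T + b["mu_f^2"] * mu_f**2
                + b["T^2"] * T**2)


def _design_matrix(mu_f, T):
    return np.column_stack([
        np.ones_like(mu_f), mu_f, T, mu_f * T, mu_f**2, T**2,
    ])


def fit_rsm(endpoints, coded: bool = False) -> RSMModel:
    """Ordinary least squares on the six-term quadratic basis.

    ``endpoints``: iterable of (mu_f, T, y) or a DataFrame with columns
    mu_f, T, y.  Raises a descriptive error when the design does not span
    the quadratic basis (rank deficiency).
    """
    if isinstance(endpoints, pd.DataFrame):
        df = endpoints[["mu_f", "T", "y"]].astype(float)
    else:
        df = pd.DataFrame(list(endpoints), columns=["mu_f", "T", "y"])
    if len(df) < 6:
        raise ValueError("need at least 6 design points for the quadratic fit")
    mu_f, T = df["mu_f"].to_numpy(), df["T"].to_numpy()
    coding = None
    if coded:
        coding = tuple(
            (0.5 * (v.max() + v.min()), max(0.5 * (v.max() - v.min()), 1e-12))
            for v in (mu_f, T)
        )
        (c_mu, h_mu), (c_T, h_T) = coding
        mu_f = (mu_f - c_mu) / h_mu
        T = (T - c_T) / h_T
    Xd = _design_matrix(mu_f, T)
    rank = np.linalg.matrix_rank(Xd)
    if rank < 6:
        # name the deficient directions via the smallest singular vectors
        _, s, vt = np.linalg.svd(Xd)
        bad = [
            ", ".join(f"{v:+.2f}*{t}" for v, t in zip(vt[i], _TERMS)
                      if abs(v) > 0.3)
            for i in range(rank, 6)
        ]
        raise ValueError(
            "rank-deficient quadratic design; unidentifiable directions: "
            + "; ".join(bad)
        )
    fit = sm_api.OLS(df["y"].to_numpy(), Xd).fit()
    coef = pd.Series(fit.params, index=_TERMS)
    pvals = pd.Series(fit.pvalues, index=_TERMS)
    return RSMModel(
        coefficients=coef, p_values=pvals, R2=float(fit.rsquared),
        R2_adj=float(fit.rsquared_adj), coding=coding, n_points=len(df),
    )


def rsm_optimum(model: RSMModel, bounds) -> dict:
    """Constrained maximum of the fitted quadratic.

    ``bounds``: ((mu_f_lo, mu_f_hi), (T_lo, T_hi)) on the natural scale.
    Classifies the stationary point (max / min / saddle) by the eigenvalues
    of the quadratic form; if the stationary point is an interior maximum it
    is returned, otherwise the maximum is found on the box boundary.
    """
    b = model.coefficients
    H = np.array([[2 * b["mu_f^2"], b["mu_f:T"]],
                  [b["mu_f:T"], 2 * b["T^2"]]])
    g = np.array([b["mu_f"], b["T"]])
    eig = np.linalg.eigvalsh(H)
    if np.all(eig < 0):
        kind = "maximum"
    elif np.all(eig > 0):
        kind = "minimum"
    else:
        kind = "saddle"
    stationary = None
    if abs(np.linalg.det(H)) > 1e-14 * max(1.0, np.abs(H).max() ** 2):
        stationary = np.linalg.solve(H, -g)

    (lo1, hi1), (lo2, hi2) = bounds
    if model.coding is not None:
        (c_mu, h_mu), (c_T, h_T) = model.coding
        lo1, hi1 = (lo1 - c_mu) / h_mu, (hi1 - c_mu) / h_mu
        lo2, hi2 = (lo2 - c_T) / h_T, (hi2 - c_T) / h_T

    def q(u):
        return (b["const"] + g @ u + 0.5 * u @ H @ u)

    candidates = []
    if (stationary is not None and kind == "maximum"
            and lo1 <= stationary[0] <= hi1 and lo2 <= stationary[1] <= hi2):
        candidates.append(stationary)
    # boundary: 1-D quadratics on each edge
    for x1 in (lo1, hi1):
        a2 = 0.5 * H[1, 1]
        a1 = g[1] + H[0, 1] * x1
        pts = [lo2, hi2]
        if abs(a2) > 1e-300:
            x2s = -a1 / (2 * a2)
            if lo2 < x2s < hi2:
                pts.append(x2s)
        candidates += [np.array([x1, p]) for p in pts]
    for x2 in (lo2, hi2):
        a2 = 0.5 * H[0, 0]
        a1 = g[0] + H[0, 1] * x2
        pts = [lo1, hi1]
        if abs(a2) > 1e-300:
            x1s = -a1 / (2 * a2)
            if lo1 < x1s < hi1:
                pts.append(x1s)
        candidates += [np.array([p, x2]) for p in pts]
    best = max(candidates, key=q)
    y_best = float(q(best))
    mu_best, T_best = float(best[0]), float(best[1])
    if model.coding is not None:
        (c_mu, h_mu), (c_T, h_T) = model.coding
        mu_best = mu_best * h_mu + c_mu
        T_best = T_best * h_T + c_T
    interior = (stationary is not None and kind == "maximum"
                and np.allclose(best, stationary))
    stat_nat = None
    if stationary is not None:
        s_mu, s_T = float(stationary[0]), float(stationary[1])
        if model.coding is not None:
            (c_mu, h_mu), (c_T, h_T) = model.coding
            s_mu, s_T = s_mu * h_mu + c_mu, s_T * h_T + c_T
        stat_nat = (s_mu, s_T)
    return {
        "mu_f": mu_best, "T": T_best, "y": y_best,
        "stationary_kind": kind, "interior": bool(interior),
        "stationary_point": stat_nat,
    }


def endpoint_table(records, target: str = "YPX") -> pd.DataFrame:
    """Endpoint targets from process records (final sample).

    ``target``: YPX (default), P or X.
    """
    rows = []
    for r in records:
        if target == "YPX":
            y = float(r.P_meas[-1] / r.X_meas[-1])
        elif target == "P":
            y = float(r.P_meas[-1])
        elif target == "X":
            y = float(r.X_meas[-1])
        else:
            raise ValueError(f"unknown endpoint target {target!r}")
        rows.append({"run_id": r.run_id, "mu_f": r.design_point[0],
                     "T": r.design_point[1], "y": y})
    return pd.DataFrame(rows)
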