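"""Least-squares fitting of the constitutive models to bulk measurements.

A measurement table holds values of the dielectric (difference) constant
or the viscosity on a grid of applied field E0 and salt concentration
c0, one row per (E0, c0, component, quantity).  The fitters recover the
constitutive parameters:

* Gavish--Promislow decrement (eps_ms, a_c; alpha reported through
  a_c = 3 alpha/(eps_w - eps_ms)) from zero-field dielectric data,
* Booth saturation (eps_n, a_E) from zero-salt dielectric-difference data,
* viscosity polynomial (a_c1, a_c2) from zero-field viscosity data,
* viscosity field law (a_E1, a_E2) per tensor component, p0 held fixed,

and `compare_combination_models` ranks the multiplicative vs additive
coupling ansatz by residual sum of squares with the marginal parameters
frozen, which is how the two ansatze are judged against data.

Weighted least squares is used whenever the table carries a stderr
column; fits are unweighted otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

from .constitutive import (
    Combination,
    Component,
    DielectricModel,
    ViscosityModel,
    eps_combined,
    eps_field_diff,
    eps_salt,
    eta_combined,
    eta_field,
)

__all__ = [
    "TABLE_COLUMNS",
    "MeasurementTable",
    "FitResult",
    "fit_gavish_promislow",
    "fit_booth",
    "fit_eta_conc",
    "fit_eta_field",
    "compare_combination_models",
]

TABLE_COLUMNS = ("E0_V_per_nm", "c0_M", "component", "quantity", "value", "stderr")


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or does not converge."""


@dataclass
class MeasurementTable:
    """Tabulated bulk measurements with unit-suffixed columns.

    ``component`` is one of parallel/perpendicular/isotropic and
    ``quantity`` one of eps_diff/eps_differential/eta.  ``stderr`` may be
    NaN (unweighted fit).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in TABLE_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table lacks columns {missing}")
        if "stderr" not in df.columns:
            df["stderr"] = np.nan
        if len(df) == 0:
            raise ValueError("measurement table is empty")
        if (df["E0_V_per_nm"] < 0).any() or (df["c0_M"] < 0).any():
            raise ValueError("E0 and c0 must be non-negative")
        keys = df[["E0_V_per_nm", "c0_M", "component", "quantity"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (E0, c0, component, quantity) rows")
        self.data = df.reset_index(drop=True)

    def select(self, quantity: str, component: str | None = None,
               E0: float | None = None, c0: float | None = None) -> pd.DataFrame:
        df = self.data[self.data["quantity"] == quantity]
        if component is not None:
            df = df[df["component"] == component]
        if E0 is not None:
            df = df[np.isclose(df["E0_V_per_nm"], E0)]
        if c0 is not None:
            df = df[np.isclose(df["c0_M"], c0)]
        return df

    @property
    def has_stderr(self) -> bool:
        return bool(np.isfinite(self.data["stderr"]).all())


@dataclass
class FitResult:
    """Parameter estimates with covariance and fit diagnostics."""

    params: dict[str, float]
    cov: np.ndarray          # ordered like params
    rss: float
    n_points: int
    model_tag: str
    fixed: dict[str, float] = field(default_factory=dict)
    at_boundary: bool = False

    def stderr(self, name: str) -> float:
        i = list(self.params).index(name)
        return float(np.sqrt(self.cov[i, i]))

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.params)
        if self.cov.shape != (k, k):
            raise ValueError("covariance shape does not match parameters")
        if self.n_points < k:
            raise ValueError("fewer points than free parameters")


def _weights(df: pd.DataFrame) -> np.ndarray:
    se = df["stderr"].to_numpy(dtype=float)
    if np.isfinite(se).all() and (se > 0).all():
        return 1.0 / se
    return np.ones(len(df))


def _wls_linear(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                names: Iterable[str], tag: str,
                fixed: dict[str, float]) -> FitResult:
    """Exact (weighted) linear least squares with covariance from s^2 (X'X)^-1."""
    names = list(names)
    Xw = X * w[:, None]
    yw = y * w
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise FitError("rank-deficient design: not enough distinct abscissae "
                       "for the requested parameters")
    beta, res, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    dof = max(len(y) - X.shape[1], 1)
    s2 = rss / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    return FitResult(params=dict(zip(names, map(float, beta))), cov=cov,
                     rss=rss, n_points=len(y), model_tag=tag, fixed=fixed)


def _multistart_nls(residual, starts, bounds, names, tag, fixed,
                    n_points) -> FitResult:
    """scipy least_squares from several deterministic starts; best RSS wins."""
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(residual, x0, bounds=bounds,
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                         max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("nonlinear fit did not converge from any start")
    r = best.fun
    rss = float(r @ r)
    J = best.jac
    dof = max(n_points - len(best.x), 1)
    s2 = rss / dof
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)
    # flag solutions pinned at a bound, and degenerate fits whose sensitivity
    # matrix is effectively rank-deficient (e.g. a flat table drives the
    # saturation-scale parameter toward its zero bound with eps_n unidentified)
    at_bound = bool(np.any(np.isclose(best.x, bounds[0])
                           | np.isclose(best.x, bounds[1]))
                    or np.linalg.cond(JtJ) > 1e10)
    return FitResult(params=dict(zip(names, map(float, best.x))), cov=cov,
                     rss=rss, n_points=n_points, model_tag=tag, fixed=fixed,
                     at_boundary=at_bound)


def fit_gavish_promislow(table: MeasurementTable,
                         eps_w_fixed: float = 71.0) -> FitResult:
    """Fit (eps_ms, a_c) of the salt decrement to zero-field dielectric data.

    eps_w is held fixed.  The derived excess polarizability
    alpha = a_c (eps_w - eps_ms)/3 is reported alongside.
    """
    df = table.select("eps_diff", E0=0.0)
    if df["c0_M"].nunique() < 4:
        raise FitError("need >= 4 distinct concentrations at E0 = 0")
    c = df["c0_M"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    w = _weights(df)

    def residual(x):
        eps_ms, a_c = x
        m = DielectricModel.from_a_c(a_c, eps_w=eps_w_fixed,
                                     eps_ms=min(eps_ms, eps_w_fixed - 1e-9))
        return w * (np.asarray(eps_salt(c, m)) - y)

    starts = [(27.9, -0.8), (10.0, -0.1), (40.0, -2.0), (2.0, -0.5), (60.0, -5.0)]
    bounds = ([1.0, -np.inf], [eps_w_fixed - 1e-6, 0.0])
    res = _multistart_nls(residual, starts, bounds,
                          ["eps_ms", "a_c"], "gavish_promislow",
                          {"eps_w": eps_w_fixed}, len(y))
    a_c = res.params["a_c"]
    res.params["alpha"] = a_c * (eps_w_fixed - res.params["eps_ms"]) / 3.0
    # pad covariance with the derived parameter (delta method on eps_ms, a_c)
    g = np.array([[1.0, 0.0],
                  [0.0, 1.0],
                  [-a_c / 3.0, (eps_w_fixed - res.params["eps_ms"]) / 3.0]])
    res.cov = g @ res.cov @ g.T
    return res


def fit_booth(table: MeasurementTable, eps_w_fixed: float = 71.0) -> FitResult:
    """Fit (eps_n, a_E) of the field-saturation law to zero-salt data."""
    df = table.select("eps_diff", c0=0.0)
    if df["E0_V_per_nm"].nunique() < 4:
        raise FitError("need >= 4 distinct field strengths at c0 = 0")
    E = df["E0_V_per_nm"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    w = _weights(df)

    def residual(x):
        eps_n, a_E = x
        m = DielectricModel(eps_w=eps_w_fixed, eps_ms=27.9, alpha=0.0,
                            eps_n=eps_n, a_E=a_E)
        return w * (np.asarray(eps_field_diff(E, m)) - y)

    starts = [(4.0, 10.0), (1.5, 1.0), (10.0, 30.0), (2.0, 5.0), (20.0, 2.0)]
    bounds = ([1.0, 1e-8], [eps_w_fixed, np.inf])
    res = _multistart_nls(residual, starts, bounds, ["eps_n", "a_E"],
                          "booth", {"eps_w": eps_w_fixed}, len(y))
    # a_E * E_max << 1 means the saturation scale collapsed below the data
    # resolution (flat table): a_E diverged toward its zero bound
    if res.params["a_E"] * float(np.max(E)) < 1e-2:
        res.at_boundary = True
    return res


def fit_eta_conc(table: MeasurementTable, eta_w_fixed: float | None = 0.648
                 ) -> FitResult:
    """Fit the quadratic salt polynomial to zero-field viscosity data.

    With ``eta_w_fixed`` set (default), only (a_c1, a_c2) are free; pass
    None to co-fit eta_w as well.  Exact linear least squares.
    """
    df = table.select("eta", E0=0.0)
    n_free = 2 if eta_w_fixed is not None else 3
    if df["c0_M"].nunique() < max(3, n_free):
        raise FitError(f"need >= {max(3, n_free)} distinct concentrations")
    c = df["c0_M"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    w = _weights(df)
    if eta_w_fixed is None:
        X = np.column_stack([np.ones_like(c), c, c**2])
        return _wls_linear(X, y, w, ["eta_w", "a_c1", "a_c2"],
                           "eta_conc", {})
    X = np.column_stack([c, c**2])
    return _wls_linear(X, y - eta_w_fixed, w, ["a_c1", "a_c2"],
                       "eta_conc", {"eta_w": eta_w_fixed})


def fit_eta_field(table: MeasurementTable, component: Component | str,
                  eta_w_fixed: float = 0.648, p0: float = 0.049) -> FitResult:
    """Fit (a_E1, a_E2) of the field law for one viscosity component.

    eta_w and the water dipole moment p0 are held fixed; the model is
    then linear in (a_E1, a_E2) and solved exactly.
    """
    component = Component(component)
    df = table.select("eta", component=component.value, c0=0.0)
    if df["E0_V_per_nm"].nunique() < 4:
        raise FitError("need >= 4 distinct field strengths at c0 = 0")
    E = df["E0_V_per_nm"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    w = _weights(df)
    probe = ViscosityModel(eta_w=eta_w_fixed, p0=p0,
                           a_E1_par=1.0, a_E2_par=0.0,
                           a_E1_perp=1.0, a_E2_perp=0.0)
    basis1 = np.asarray(eta_field(E, component, probe)) - eta_w_fixed
    X = np.column_stack([basis1, E**2])
    return _wls_linear(X, y - eta_w_fixed, w, ["a_E1", "a_E2"],
                       "eta_field_" + component.value,
                       {"eta_w": eta_w_fixed, "p0": p0})


def _frozen_models_from_axes(table: MeasurementTable, kind: str,
                             eps_w: float, eta_w: float):
    """Fit the marginal laws on the table's axes and freeze them."""
    if kind == "dielectric":
        gp = fit_gavish_promislow(table, eps_w_fixed=eps_w)
        booth = fit_booth(table, eps_w_fixed=eps_w)
        return DielectricModel.from_a_c(
            gp.params["a_c"], eps_w=eps_w, eps_ms=gp.params["eps_ms"],
            eps_n=booth.params["eps_n"], a_E=booth.params["a_E"])
    conc = fit_eta_conc(table, eta_w_fixed=eta_w)
    perp = fit_eta_field(table, Component.PERPENDICULAR, eta_w_fixed=eta_w)
    return ViscosityModel(eta_w=eta_w, a_c1=conc.params["a_c1"],
                          a_c2=conc.params["a_c2"],
                          a_E1_perp=perp.params["a_E1"],
                          a_E2_perp=perp.params["a_E2"])


def compare_combination_models(table: MeasurementTable, kind: str,
                               eps_w: float = 71.0, eta_w: float = 0.648
                               ) -> pd.DataFrame:
    """Rank the multiplicative vs additive coupling ansatz by RSS.

    ``kind`` is "dielectric" or "viscosity".  Marginal parameters are
    fitted on the axes (E0 = 0 row, c0 = 0 column) and frozen; the two
    ansatze are then scored on the full grid.  Ties rank multiplicative
    first.  Returns a DataFrame with columns mode, rss, rank.
    """
    if kind not in ("dielectric", "viscosity"):
        raise ValueError("kind must be 'dielectric' or 'viscosity'")
    quantity = "eps_diff" if kind == "dielectric" else "eta"
    if kind == "viscosity":
        df = table.select(quantity, component=Component.PERPENDICULAR.value)
    else:
        df = table.select(quantity)
    if df["E0_V_per_nm"].nunique() < 2 or df["c0_M"].nunique() < 2:
        raise FitError("combination comparison needs a non-degenerate "
                       "(E0, c0) grid on both axes")
    base = _frozen_models_from_axes(table, kind, eps_w, eta_w)
    E = df["E0_V_per_nm"].to_numpy(dtype=float)
    c = df["c0_M"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    w = _weights(df)
    rows = []
    for mode in (Combination.MULTIPLICATIVE, Combination.ADDITIVE):
        model = replace(base, combination=mode)
        if kind == "dielectric":
            pred = np.asarray(eps_combined(E, c, model))
        else:
            pred = np.asarray(eta_combined(E, c, Component.PERPENDICULAR, model))
        rows.append({"mode": mode.value,
                     "rss": float(np.sum((w * (pred - y)) ** 2))})
    out = pd.DataFrame(rows)
    # stable sort: ties keep the multiplicative-first input order
    out = out.sort_values("rss", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
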