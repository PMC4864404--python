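"""Adjusted-growth poverty model: system estimation and impact schedules.

The model is a two-equation simultaneous system per country j:

* poverty equation (P):
  ``gamma(H)_j = beta0 + beta1 * (1 -/+ s_j/100) * g_j [+ theta*s_j] + Gamma'Z_j + eps_j``
* growth-index equation (G):
  ``g_j = delta0 + delta1 * gamma(mu)_j + Lambda'W_j + nu_j``

where s is one of the spatial shares (d1, d2: minus sign; i1, i2: plus
sign), g is the endogenous growth index and the errors (eps, nu) may be
correlated across equations. The total derivative of poverty growth with
respect to income growth,

    d gamma(H) / d gamma(mu) = beta1 * delta1 * (1 -/+ s/100),

is the *marginal impact* reported in the impact schedules.

Estimators: per-equation OLS and 2SLS, and the stacked-system SUR and
3SLS (feasible GLS with the cross-equation residual covariance; 3SLS
additionally projects on the instrument space). No small-sample
degrees-of-freedom correction is applied, and Wald tests use the
asymptotic chi-square reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "SystemFit",
    "GrowthPovertySystem",
    "adjusted_growth",
    "marginal_impact",
    "evaluation_points",
    "impact_table",
    "fit_ols",
    "fit_2sls",
    "fit_system_3sls",
    "test_restrictions",
]

DAL_SHARES = ("d1", "d2")
IAL_SHARES = ("i1", "i2")
_POLARITY_SIGN = {"dal": -1.0, "ial": 1.0}


def _polarity_of(share_variable: str) -> str:
    if share_variable in DAL_SHARES:
        return "dal"
    if share_variable in IAL_SHARES:
        return "ial"
    raise ValueError(f"unknown share variable {share_variable!r}")


def adjusted_growth(share: float, growth: float, polarity: str) -> float:
    """Income growth scaled by the spatial-distribution factor.

    ``(1 - share/100) * growth`` for DAL polarity (a larger degrading
    share blunts growth) and ``(1 + share/100) * growth`` for IAL.
    """
    share = np.asarray(share, dtype=float)
    if np.any(share < 0) or np.any(share > 100):
        raise ValueError("share must lie in [0, 100] percent")
    sign = _POLARITY_SIGN[polarity]
    out = (1.0 + sign * share / 100.0) * growth
    return float(out) if np.isscalar(growth) and out.ndim == 0 else out


def marginal_impact(
    beta1: float, delta1: float, share: float, polarity: str, growth: float
) -> float:
    """Total effect of income growth on poverty growth at a given share level.

    ``beta1 * delta1 * (1 -/+ share/100) * growth`` in %/yr; negative
    values mean poverty is falling.
    """
    return beta1 * delta1 * adjusted_growth(share, growth, polarity)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def evaluation_points(mean: float, sd: float, multiplier: float = 1.0) -> tuple[float, float, float]:
    """Display evaluation points (mean - m*sd, mean, mean + m*sd).

    Clipped at zero and rounded half-up to 0.1, matching how share levels
    are reported; remote-IAL schedules conventionally use m = 0.5.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    pts = (mean - multiplier * sd, mean, mean + multiplier * sd)
    return tuple(_round_half_up(max(p, 0.0), 1) for p in pts)


@dataclass
class ModelSpec:
    """Which share variable, estimator and terms a single fit uses."""

    share_variable: str = "d1"
    estimator: str = "3sls"  # ols | 2sls | sur | 3sls
    include_controls: bool = True
    include_direct_term: bool = False
    instrument_names: list[str] | None = None

    @property
    def polarity(self) -> str:
        return _polarity_of(self.share_variable)


@dataclass
class SystemFit:
    """Coefficients, standard errors and residual covariance of one fit."""

    estimator: str
    share_variable: str
    names_P: list[str]
    params_P: np.ndarray
    se_P: np.ndarray
    names_G: list[str]
    params_G: np.ndarray
    se_G: np.ndarray
    sigma: np.ndarray  # 2x2 residual covariance
    cov_P: np.ndarray
    cov_G: np.ndarray
    n_obs: int
    cov_full: np.ndarray | None = None

    def _coef(self, eq: str, name: str) -> tuple[float, float]:
        names = self.names_P if eq == "P" else self.names_G
        params = self.params_P if eq == "P" else self.params_G
        ses = self.se_P if eq == "P" else self.se_G
        i = names.index(name)
        return float(params[i]), float(ses[i])

    @property
    def beta0(self) -> float:
        return self._coef("P", "const")[0]

    @property
    def beta1(self) -> float:
        return self._coef("P", "adjusted_growth")[0]

    @property
    def beta1_se(self) -> float:
        return self._coef("P", "adjusted_growth")[1]

    @property
    def delta0(self) -> float:
        return self._coef("G", "const")[0]

    @property
    def delta1(self) -> float:
        return self._coef("G", "gamma_mu")[0]

    @property
    def delta1_se(self) -> float:
        return self._coef("G", "gamma_mu")[1]

    @property
    def theta_direct(self) -> float | None:
        if "share_direct" not in self.names_P:
            return None
        return self._coef("P", "share_direct")[0]

    def tstats(self) -> dict[str, float]:
        out = {}
        for nm, p, s in zip(self.names_P, self.params_P, self.se_P):
            out[f"P:{nm}"] = float(p / s) if s > 0 else np.nan
        for nm, p, s in zip(self.names_G, self.params_G, self.se_G):
            out[f"G:{nm}"] = float(p / s) if s > 0 else np.nan
        return out

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "share_variable": self.share_variable,
            "n_obs": self.n_obs,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta1_se": self.beta1_se,
            "delta0": self.delta0,
            "delta1": self.delta1,
            "delta1_se": self.delta1_se,
            "theta_direct": self.theta_direct,
            "params_P": dict(zip(self.names_P, map(float, self.params_P))),
            "se_P": dict(zip(self.names_P, map(float, self.se_P))),
            "params_G": dict(zip(self.names_G, map(float, self.params_G))),
            "se_G": dict(zip(self.names_G, map(float, self.se_G))),
            "sigma": self.sigma.tolist(),
            "tstats": self.tstats(),
        }


class SingularityError(np.linalg.LinAlgError):
    """The design (or restriction) matrix is rank-deficient."""


class IdentificationError(ValueError):
    """Fewer instruments than endogenous regressors."""


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name columns with (near-)zero QR pivots
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in np.where(diag <= tol)[0]]
        raise SingularityError(f"design matrix is rank-deficient; collinear columns: {bad}")


def _project(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Projection of the columns of M onto the column space of Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return Z @ coef


class GrowthPovertySystem(BaseEstimator):
    """Two-equation growth-poverty system estimator (scikit-learn style).

    Parameters
    ----------
    share : str
        Which spatial share modifies growth: ``d1``, ``d2`` (DAL, minus
        polarity) or ``i1``, ``i2`` (IAL, plus polarity).
    estimator : str
        ``"ols"``, ``"2sls"``, ``"sur"`` or ``"3sls"``.
    include_controls : bool
        Add the panel's ``Z*`` columns to the poverty equation and ``W*``
        columns to the growth equation.
    include_direct : bool
        Add the share itself as a direct regressor in the poverty
        equation (the direct-channel term tested by the restriction test).
    instruments : list of str, optional
        Extra instrument column names. Defaults to the panel's ``W*``
        columns plus share-interaction terms built from exogenous
        variables.

    After :meth:`fit`, the fitted system is available as ``result_``
    (a :class:`SystemFit`) and the headline coefficients as ``beta0_``,
    ``beta1_``, ``delta0_``, ``delta1_`` and ``theta_direct_``.
    """

    def __init__(
        self,
        share: str = "d1",
        estimator: str = "3sls",
        include_controls: bool = True,
        include_direct: bool = False,
        instruments: list[str] | None = None,
    ):
        self.share = share
        self.estimator = estimator
        self.include_controls = include_controls
        self.include_direct = include_direct
        self.instruments = instruments

    # ------------------------------------------------------------------
    def _design(self, panel: pd.DataFrame):
        polarity = _polarity_of(self.share)
        sign = _POLARITY_SIGN[polarity]
        needed = ["gamma_H", "gamma_mu", "g", self.share]
        w_cols = sorted(c for c in panel.columns if c.startswith("W"))
        z_cols = sorted(c for c in panel.columns if c.startswith("Z"))
        # W/Z columns are kept even without controls: they serve as instruments
        extra = list(self.instruments or [])
        cols = [c for c in dict.fromkeys(needed + w_cols + z_cols + extra) if c in panel.columns]
        missing = [c for c in needed if c not in panel.columns]
        if missing:
            raise ValueError(f"panel lacks required columns: {missing}")
        data = panel[cols].apply(pd.to_numeric, errors="coerce").dropna()
        n = len(data)
        s = data[self.share].to_numpy(float)
        g = data["g"].to_numpy(float)
        gm = data["gamma_mu"].to_numpy(float)
        factor = 1.0 + sign * s / 100.0
        const = np.ones(n)

        names_P = ["const", "adjusted_growth"]
        X_P = [const, factor * g]
        if self.include_direct:
            names_P.append("share_direct")
            X_P.append(s)
        names_G = ["const", "gamma_mu"]
        X_G = [const, gm]
        if self.include_controls:
            for c in z_cols:
                names_P.append(c)
                X_P.append(data[c].to_numpy(float))
            for c in w_cols:
                names_G.append(c)
                X_G.append(data[c].to_numpy(float))

        # instrument set: all exogenous variables plus interaction terms
        # predicting the endogenous adjusted-growth regressor
        inst_names = ["const", "gamma_mu", self.share, f"factor_x_gamma_mu"]
        Zi = [const, gm, s, factor * gm]
        for c in w_cols:
            inst_names += [c, f"factor_x_{c}"]
            Zi += [data[c].to_numpy(float), factor * data[c].to_numpy(float)]
        for c in z_cols:
            inst_names.append(c)
            Zi.append(data[c].to_numpy(float))
        if self.instruments:
            for c in self.instruments:
                if c not in inst_names and c in data.columns:
                    inst_names.append(c)
                    Zi.append(data[c].to_numpy(float))

        y_P = data["gamma_H"].to_numpy(float)
        y_G = g
        return (
            y_P,
            np.column_stack(X_P),
            names_P,
            y_G,
            np.column_stack(X_G),
            names_G,
            np.column_stack(Zi),
            inst_names,
            n,
        )

    # ------------------------------------------------------------------
    def fit(self, panel: pd.DataFrame, y=None) -> "GrowthPovertySystem":
        if self.estimator not in ("ols", "2sls", "sur", "3sls"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        y_P, X_P, names_P, y_G, X_G, names_G, Z, inst_names, n = self._design(panel)
        if n < max(X_P.shape[1], X_G.shape[1]) + 2:
            raise ValueError(f"too few complete records (n={n}) for the design")
        _check_rank(X_P, names_P)
        _check_rank(X_G, names_G)
        if self.estimator in ("2sls", "3sls"):
            if Z.shape[1] < X_P.shape[1]:
                raise IdentificationError(
                    "order condition fails: fewer instruments than poverty-equation regressors"
                )
            # redundant (collinear) instruments are harmless: only the
            # projection onto their span enters the estimator

        if self.estimator == "ols":
            bP, covP, eP = _ols_eq(y_P, X_P)
            bG, covG, eG = _ols_eq(y_G, X_G)
            sigma = _sigma(eP, eG)
            cov_full = None
        elif self.estimator == "2sls":
            bP, covP, eP = _iv_eq(y_P, X_P, Z)
            bG, covG, eG = _iv_eq(y_G, X_G, Z)
            sigma = _sigma(eP, eG)
            cov_full = None
        else:
            proj = self.estimator == "3sls"
            # first pass for the residual covariance
            if proj:
                _, _, eP = _iv_eq(y_P, X_P, Z)
                _, _, eG = _iv_eq(y_G, X_G, Z)
            else:
                _, _, eP = _ols_eq(y_P, X_P)
                _, _, eG = _ols_eq(y_G, X_G)
            sigma = _sigma(eP, eG)
            if np.linalg.matrix_rank(sigma) < 2:
                raise np.linalg.LinAlgError(
                    "singular residual covariance; consider per-equation 2SLS or SUR"
                )
            b, cov_full = _system_gls(
                [y_P, y_G], [X_P, X_G], sigma, Z if proj else None
            )
            k1 = X_P.shape[1]
            bP, bG = b[:k1], b[k1:]
            covP = cov_full[:k1, :k1]
            covG = cov_full[k1:, k1:]
            eP = y_P - X_P @ bP
            eG = y_G - X_G @ bG

        self.result_ = SystemFit(
            estimator=self.estimator,
            share_variable=self.share,
            names_P=names_P,
            params_P=bP,
            se_P=np.sqrt(np.diag(covP)),
            names_G=names_G,
            params_G=bG,
            se_G=np.sqrt(np.diag(covG)),
            sigma=sigma,
            cov_P=covP,
            cov_G=covG,
            n_obs=n,
            cov_full=cov_full,
        )
        r = self.result_
        self.beta0_, self.beta1_ = r.beta0, r.beta1
        self.delta0_, self.delta1_ = r.delta0, r.delta1
        self.theta_direct_ = r.theta_direct
        self.n_obs_ = n
        return self

    # ------------------------------------------------------------------
    def marginal_impacts(self, shares, growth: float) -> np.ndarray:
        """Impact schedule at the fitted beta1 and delta1."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        pol = _polarity_of(self.share)
        return np.array([marginal_impact(self.beta1_, self.delta1_, s, pol, growth) for s in np.atleast_1d(shares)])


def _ols_eq(y, X):
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ b
    s2 = float(e @ e) / len(y)
    cov = s2 * np.linalg.inv(X.T @ X)
    return b, cov, e


def _iv_eq(y, X, Z):
    Xh = _project(Z, X)
    XtX = Xh.T @ X
    try:
        b = np.linalg.solve(XtX, Xh.T @ y)
    except np.linalg.LinAlgError as exc:
        raise IdentificationError(f"projected design is singular: {exc}") from exc
    e = y - X @ b
    s2 = float(e @ e) / len(y)
    cov = s2 * np.linalg.inv(Xh.T @ Xh)
    return b, cov, e


def _sigma(eP, eG):
    E = np.column_stack([eP, eG])
    return E.T @ E / len(eP)


def _system_gls(ys, Xs, sigma, Z=None):
    """Stacked feasible GLS; with Z, regressors are instrument-projected (3SLS)."""
    S = np.linalg.inv(sigma)
    Xt = [(_project(Z, X) if Z is not None else X) for X in Xs]
    ks = [X.shape[1] for X in Xs]
    K = sum(ks)
    A = np.zeros((K, K))
    c = np.zeros(K)
    off = np.cumsum([0] + ks)
    for i in range(len(Xs)):
        for j in range(len(Xs)):
            blk = S[i, j] * (Xt[i].T @ Xs[j])
            A[off[i] : off[i + 1], off[j] : off[j + 1]] = blk
            c[off[i] : off[i + 1]] += S[i, j] * (Xt[i].T @ ys[j])
    # covariance bread uses the projected cross-products (symmetric form)
    B = np.zeros((K, K))
    for i in range(len(Xs)):
        for j in range(len(Xs)):
            B[off[i] : off[i + 1], off[j] : off[j + 1]] = S[i, j] * (Xt[i].T @ Xt[j])
    b = np.linalg.solve(A, c)
    cov = np.linalg.inv(B)
    return b, cov


# ---------------------------------------------------------------------------
# thin functional wrappers


def _fit(panel, estimator, **kw) -> SystemFit:
    est = GrowthPovertySystem(estimator=estimator, **kw)
    est.fit(panel)
    return est.result_


def fit_ols(panel: pd.DataFrame, **kw) -> SystemFit:
    """Per-equation ordinary least squares."""
    return _fit(panel, "ols", **kw)


def fit_2sls(panel: pd.DataFrame, **kw) -> SystemFit:
    """Per-equation two-stage least squares."""
    return _fit(panel, "2sls", **kw)


def fit_system_3sls(panel: pd.DataFrame, **kw) -> SystemFit:
    """Full-system three-stage least squares (SUR via ``estimator='sur'``)."""
    return _fit(panel, "3sls", **kw)


# ---------------------------------------------------------------------------
# restriction tests


def wald_test(fit: SystemFit, eq: str, names: list[str]) -> tuple[float, float]:
    """Wald chi-square test that the named coefficients of one equation are zero."""
    all_names = fit.names_P if eq == "P" else fit.names_G
    params = fit.params_P if eq == "P" else fit.params_G
    cov = fit.cov_P if eq == "P" else fit.cov_G
    idx = [all_names.index(n) for n in names]
    R = np.zeros((len(idx), len(all_names)))
    for r, i in enumerate(idx):
        R[r, i] = 1.0
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("restriction matrix is rank-deficient")
    rb = R @ params
    V = R @ cov @ R.T
    try:
        stat = float(rb @ np.linalg.solve(V, rb))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"restriction covariance is singular: {exc}") from exc
    p = float(stats.chi2.sf(stat, df=len(idx)))
    return stat, p


def test_restrictions(fit: SystemFit, panel: pd.DataFrame) -> dict:
    """Direct vs indirect channel: Wald tests on the fitted poverty equation.

    Tests H0: theta_direct = 0 (the share has no direct influence on
    poverty growth) and H0: beta1 = 0 (the share-adjusted growth channel
    is absent), and states which channel the data support.
    """
    if "share_direct" not in fit.names_P:
        raise ValueError("fit must include the direct share term (include_direct=True)")
    s = pd.to_numeric(panel[fit.share_variable], errors="coerce").dropna()
    if float(s.std()) == 0.0:
        raise ValueError(f"share column {fit.share_variable!r} has zero variance")
    w_dir, p_dir = wald_test(fit, "P", ["share_direct"])
    w_ind, p_ind = wald_test(fit, "P", ["adjusted_growth"])
    direct = p_dir < 0.05
    indirect = p_ind < 0.05
    if indirect and not direct:
        channel = "indirect-only"
    elif direct and not indirect:
        channel = "direct-only"
    elif direct and indirect:
        channel = "both"
    else:
        channel = "neither"
    return {
        "wald_direct": w_dir,
        "p_direct": p_dir,
        "wald_indirect": w_ind,
        "p_indirect": p_ind,
        "supported_channel": channel,
    }


# ---------------------------------------------------------------------------
# impact schedules


def impact_table(
    fits: dict[str, dict[str, tuple[float, float]]],
    moments: dict[str, tuple[float, float]],
    growth: float,
) -> pd.DataFrame:
    """Impact schedule for each share variable at low/mean/high evaluation points.

    ``fits[share]`` maps column labels (e.g. ``"no_controls"``,
    ``"controls"``) to (beta1, delta1) pairs; ``moments[share]`` is the
    sample (mean, sd) of that share. Remote-IAL (``i2``) uses half-SD
    evaluation points. Missing share variables become absent rows, and
    each row carries a formatted "low% to high%" range over the columns.
    """
    rows = []
    for share in ("d1", "d2", "i1", "i2"):
        if share not in fits or share not in moments:
            rows.append({"share_variable": share, "present": False})
            continue
        mean, sd = moments[share]
        mult = 0.5 if share == "i2" else 1.0
        pts = evaluation_points(mean, sd, mult)
        pol = _polarity_of(share)
        for label, point in zip(("low", "mean", "high"), pts):
            row = {"share_variable": share, "present": True, "point": label, "share_pct": point}
            impacts = []
            for col, (b1, d1) in fits[share].items():
                imp = marginal_impact(b1, d1, point, pol, growth)
                row[f"impact_{col}"] = imp
                impacts.append(imp)
            if impacts:
                lo = min(impacts, key=abs)
                hi = max(impacts, key=abs)
                row["range"] = f"{lo:.2f}% to {hi:.2f}%"
            rows.append(row)
    return pd.DataFrame(rows)
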