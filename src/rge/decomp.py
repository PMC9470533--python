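"""Within/between decomposition of polygenic-score effects in sibling pairs.

Implements the five random-intercept models that split the association
between a polygenic score (PRS) and a phenotype into within-family,
between-family and between-region components:

  model 1:  Y = a0 + b * PRS                       + fam intercept
  model 2:  Y = a0 + bW (PRS - m_j) + bB m_j       + fam intercept
  model 3:  Y = a0 + bW (PRS - m_k) + bB m_k       + fam + region intercepts
  model 4:  Y = a0 + bW (PRS - m_j - m_k) + bBF (m_j - m_k) + bBR m_k
                                                   + fam + region intercepts
  model 5:  with w = PRS - m_j:
            Y = a0 + bW (w - wbar_k) + bB wbar_k   + fam + region intercepts

where m_j / m_k are family / region mean scores and wbar_k is the region mean
of the within-family deviation. Sex and age enter every model as fixed
covariates. Family and region intercepts are crossed (siblings may live in
different regions) and are fitted by profiled REML over the two variance
ratios with a derivative-free optimizer.

Note the model-4 within column subtracts both the family and the region mean
from the raw score, so the three PRS columns obey the exact identity
``c1 + c2 + 2*c3 = PRS`` (not a textbook three-level centering; kept as
specified, with the algebra documented rather than "corrected").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DesignSpec",
    "ModelFit",
    "group_center",
    "build_design",
    "fit_lmm",
    "r2_marginal_conditional",
    "sib_difference_oracle",
    "decompose_trait",
    "MODEL_RANDOM_FACTORS",
]

MODEL_RANDOM_FACTORS = {1: ("family",), 2: ("family",), 3: ("family", "region"),
                        4: ("family", "region"), 5: ("family", "region")}


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class DesignSpec:
    model_id: int
    response: str
    fixed_cols: list[str]
    random_factors: tuple[str, ...]


@dataclass
class ModelFit:
    """REML fit of one decomposition model."""

    spec: DesignSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series          # one-sided by default (direction of the estimate)
    vc: dict                    # {"family": s2, "region": s2, "resid": s2}
    loglik: float               # -0.5 * REML criterion (up to a constant)
    n: int
    converged: bool = True
    singular: bool = False
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse,
             "t": self.tvalues, "p": self.pvalues}
        )


# ---------------------------------------------------------------------------
# Group centering and design construction
# ---------------------------------------------------------------------------

def group_center(values, groups):
    """Split values into within-group deviations and group means (broadcast).

    Returns ``(deviations, means)`` with ``deviations + means == values``
    exactly and deviations summing to zero within every group.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(g) != len(v):
        raise ValueError("values and groups must have equal length")
    if g.dtype == object and any(x is None or x == "" for x in g):
        raise ValueError("empty group label")
    if g.dtype.kind == "U" and (g == "").any():
        raise ValueError("empty group label")
    if g.dtype.kind == "f" and np.isnan(g.astype(float)).any():
        raise ValueError("empty group label")
    codes, idx = np.unique(g, return_inverse=True)
    sums = np.bincount(idx, weights=v)
    counts = np.bincount(idx)
    means = (sums / counts)[idx]
    return v - means, means


def build_design(
    model_id: int,
    cohort: pd.DataFrame,
    *,
    response: str = "pheno",
    prs_col: str = "PRS",
    family_col: str = "FID",
    region_col: str = "region_current",
    covariates: tuple[str, ...] = ("sex", "age"),
) -> tuple[DesignSpec, pd.DataFrame]:
    """Numeric fixed-effect design for models 1-5 (intercept added by the fitter)."""
    if model_id not in MODEL_RANDOM_FACTORS:
        raise ValueError(f"unknown model id {model_id!r}")
    prs = cohort[prs_col].to_numpy(dtype=float)
    fam = cohort[family_col].to_numpy()
    X = pd.DataFrame(index=cohort.index)

    if model_id == 1:
        X["PRS"] = prs
    elif model_id == 2:
        dev, mj = group_center(prs, fam)
        X["PRS_w"], X["PRS_bf"] = dev, mj
    else:
        reg = cohort[region_col].to_numpy()
        if model_id == 3:
            dev, mk = group_center(prs, reg)
            X["PRS_w"], X["PRS_br"] = dev, mk
        elif model_id == 4:
            _, mj = group_center(prs, fam)
            _, mk = group_center(prs, reg)
            X["PRS_w"] = prs - mj - mk
            X["PRS_bf"] = mj - mk
            X["PRS_br"] = mk
        else:  # model 5
            w, mj = group_center(prs, fam)
            wdev, wbar_k = group_center(w, reg)
            counts = pd.Series(reg).value_counts()
            if (counts == 1).any():
                warnings.warn(
                    "regions with a single individual make the region mean equal "
                    "the individual deviation", UserWarning,
                )
            X["PRS_wr"], X["PRS_br"] = wdev, wbar_k

    for c in covariates:
        X[c] = cohort[c].to_numpy(dtype=float)
    spec = DesignSpec(model_id, response, list(X.columns), MODEL_RANDOM_FACTORS[model_id])
    return spec, X


def _factor_frames(cohort, spec, family_col="FID", region_col="region_current"):
    factors = {}
    if "family" in spec.random_factors:
        factors["family"] = cohort[family_col].to_numpy()
    if "region" in spec.random_factors:
        factors["region"] = cohort[region_col].to_numpy()
    return factors


# ---------------------------------------------------------------------------
# Profiled REML for 0-2 crossed intercept factors
# ---------------------------------------------------------------------------

class _LmmWork:
    """Precomputed sufficient statistics for the profiled REML criterion.

    With V = s2e (I + sum_f lam_f Z_f Z_f'), all quantities needed by the REML
    criterion reduce to the group sums Z'X, Z'y, the group sizes, the
    cross-factor incidence counts, and the OLS blocks X'X, X'y, y'y. Solves
    with M = Z'Z + diag(1/lam) use a Schur complement on the (small) second
    factor, so each evaluation is O(n + q1*K + K^3).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, factors: dict):
        n, p = X.shape
        self.n, self.p = n, p
        self.X, self.y = X, y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.names = list(factors)
        self.codes = []
        self.sizes = []
        self.ZtX = []
        self.Zty = []
        for name in self.names:
            _, idx = np.unique(factors[name], return_inverse=True)
            q = idx.max() + 1
            if q < 2:
                raise ValueError(f"random factor {name!r} needs >= 2 levels")
            self.codes.append(idx)
            self.sizes.append(np.bincount(idx).astype(float))
            ztx = np.zeros((q, p))
            np.add.at(ztx, idx, X)
            self.ZtX.append(ztx)
            self.Zty.append(np.bincount(idx, weights=y))
        if len(self.names) == 2:
            i, j = self.codes
            q1, q2 = len(self.sizes[0]), len(self.sizes[1])
            C = np.zeros((q1, q2))
            np.add.at(C, (i, j), 1.0)
            self.C = C
        else:
            self.C = None

    # -- solve M^{-1} U and logdet(M) for given variance ratios -------------
    def _msolve(self, lam, U1, U2=None):
        if len(self.names) == 1:
            D1 = self.sizes[0] + 1.0 / lam[0]
            logdet = float(np.sum(np.log(D1)))
            return U1 / D1[:, None], None, logdet
        D1 = self.sizes[0] + 1.0 / lam[0]
        D2 = self.sizes[1] + 1.0 / lam[1]
        CinvD = self.C / D1[:, None]
        S = np.diag(D2) - self.C.T @ CinvD
        cho = np.linalg.cholesky(S)
        logdet = float(np.sum(np.log(D1)) + 2.0 * np.sum(np.log(np.diag(cho))))
        rhs2 = U2 - CinvD.T @ U1
        X2 = np.linalg.solve(S, rhs2)
        X1 = (U1 - self.C @ X2) / D1[:, None]
        return X1, X2, logdet

    def _absorbed(self, lam):
        """X'AX, X'Ay, y'Ay and logdets for A = I - Z M^{-1} Z'."""
        if not self.names:
            return self.XtX, self.Xty, self.yty, 0.0
        U1 = np.column_stack([self.ZtX[0], self.Zty[0]])
        if len(self.names) == 2:
            U2 = np.column_stack([self.ZtX[1], self.Zty[1]])
        else:
            U2 = None
        S1, S2, logdetM = self._msolve(lam, U1, U2)
        quad = U1.T @ S1
        if S2 is not None:
            quad = quad + U2.T @ S2
        p = self.p
        XtAX = self.XtX - quad[:p, :p]
        XtAy = self.Xty - quad[:p, p]
        ytAy = self.yty - quad[p, p]
        logdet_bal = logdetM + sum(
            len(self.sizes[f]) * np.log(lam[f]) for f in range(len(self.names))
        )
        return XtAX, XtAy, ytAy, logdet_bal

    def neg2reml(self, lam):
        XtAX, XtAy, ytAy, logdet = self._absorbed(lam)
        try:
            beta = np.linalg.solve(XtAX, XtAy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytAy - XtAy @ beta
        df = self.n - self.p
        if rss <= 0:
            return np.inf
        s2e = rss / df
        sign, logdet_xtax = np.linalg.slogdet(XtAX)
        if sign <= 0:
            return np.inf
        return df * np.log(s2e) + logdet + logdet_xtax + df

    def gls(self, lam):
        """Fixed effects, their covariance and s2e at given variance ratios."""
        XtAX, XtAy, ytAy, _ = self._absorbed(lam)
        beta = np.linalg.solve(XtAX, XtAy)
        rss = ytAy - XtAy @ beta
        s2e = max(rss, 0.0) / (self.n - self.p)
        cov = s2e * np.linalg.inv(XtAX)
        return beta, cov, s2e


_LAM_FLOOR = 1e-8


def fit_lmm(
    design,
    y,
    factors: dict | None = None,
    *,
    two_sided: bool = False,
    start: dict | None = None,
    xtol: float = 1e-8,
    spec: DesignSpec | None = None,
) -> ModelFit:
    """Profiled-REML fit of a linear model with 0-2 crossed intercept factors.

    ``design`` is the fixed-effect matrix WITHOUT intercept (one is added);
    ``factors`` maps factor name to a label array. P-values are one-sided in
    the direction of the estimate (the convention of the sibling analyses);
    pass ``two_sided=True`` for two-sided.
    """
    if isinstance(design, pd.DataFrame):
        names = ["intercept"] + list(design.columns)
        Xmat = design.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(design, dtype=float)
        names = ["intercept"] + [f"x{i}" for i in range(Xmat.shape[1])]
    X = np.column_stack([np.ones(len(Xmat)), Xmat])
    yv = np.asarray(y, dtype=float)
    factors = factors or {}

    work = _LmmWork(X, yv, factors)
    k = len(work.names)
    converged = True
    if k == 0:
        lam_hat = []
    else:
        start_lam = [0.5] * k if start is None else [start.get(nm, 0.5) for nm in work.names]
        theta0 = np.log(np.maximum(start_lam, 1e-4))

        def obj(theta):
            lam = np.exp(np.clip(theta, -25.0, 12.0))
            return work.neg2reml(lam)

        res = optimize.minimize(
            obj, theta0, method="Nelder-Mead",
            options={"xatol": xtol, "fatol": xtol, "maxiter": 600 * k},
        )
        converged = bool(res.success)
        lam_hat = list(np.exp(np.clip(res.x, -25.0, 12.0)))
        if not converged:
            warnings.warn("REML optimizer did not converge", ConvergenceWarning)

    beta, cov, s2e = work.gls(lam_hat)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    if two_sided:
        pv = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pv = stats.norm.sf(np.abs(t))

    vc = {"resid": float(s2e)}
    singular = False
    for nm, lam in zip(work.names, lam_hat):
        vc[nm] = float(lam * s2e)
        if lam <= _LAM_FLOOR * 10:
            vc[nm] = 0.0
            singular = True
    loglik = -0.5 * work.neg2reml(lam_hat) if k else -0.5 * work.neg2reml([])

    the_spec = spec or DesignSpec(0, "y", names[1:], tuple(work.names))
    idx = pd.Index(names)
    fit = ModelFit(
        spec=the_spec,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(t, index=idx),
        pvalues=pd.Series(pv, index=idx),
        vc=vc,
        loglik=float(loglik),
        n=work.n,
        converged=converged,
        singular=singular,
    )
    fit._work = work          # reused by the bootstrap (same sufficient stats)
    fit._lam = lam_hat
    return fit


def r2_marginal_conditional(fit: ModelFit, design, y) -> tuple[float, float]:
    """Marginal and conditional R^2 of a mixed model.

    R2m = var(fixed predictor) / (var(fixed) + s2_family + s2_region + s2_resid);
    R2c replaces the numerator with var(fixed) + random-intercept variances.
    """
    if isinstance(design, pd.DataFrame):
        Xmat = design.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(design, dtype=float)
    X = np.column_stack([np.ones(len(Xmat)), Xmat])
    eta = X @ fit.params.to_numpy()
    var_fixed = float(np.var(eta))
    s2f = fit.vc.get("family", 0.0)
    s2r = fit.vc.get("region", 0.0)
    s2e = fit.vc["resid"]
    denom = var_fixed + s2f + s2r + s2e
    if denom <= 0:
        raise ValueError("zero total variance")
    r2m = var_fixed / denom
    r2c = (var_fixed + s2f + s2r) / denom
    fit.r2_marginal, fit.r2_conditional = r2m, r2c
    return r2m, r2c


# ---------------------------------------------------------------------------
# Independent oracle and the high-level entry point
# ---------------------------------------------------------------------------

def sib_difference_oracle(
    cohort: pd.DataFrame,
    *,
    response: str = "pheno",
    prs_col: str = "PRS",
    family_col: str = "FID",
    covariates: tuple[str, ...] = ("sex", "age"),
) -> tuple[float, float]:
    """Within-family slope from sib differences: OLS of (Y1-Y2) on (PRS1-PRS2).

    Covariate differences are included; no intercept beyond them. Families
    missing either phenotype are dropped. Returns (slope, se). Estimates the
    same estimand as the model-2 within coefficient in balanced pairs.
    """
    df = cohort.dropna(subset=[response]).copy()
    counts = df.groupby(family_col)[response].transform("size")
    df = df[counts == 2].sort_values([family_col, "IID"])
    a = df.iloc[0::2].reset_index(drop=True)
    b = df.iloc[1::2].reset_index(drop=True)
    dy = a[response].to_numpy() - b[response].to_numpy()
    dx = np.column_stack(
        [a[prs_col].to_numpy() - b[prs_col].to_numpy()]
        + [a[c].to_numpy(dtype=float) - b[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.allclose(dx[:, 0], 0.0):
        raise ValueError("sib PRS differences are all zero; slope undefined")
    import statsmodels.api as sm

    res = sm.OLS(dy, dx).fit()
    return float(res.params[0]), float(res.bse[0])


def decompose_trait(
    cohort: pd.DataFrame,
    trait: str,
    model_ids=(1, 2, 3, 4, 5),
    *,
    prs_col: str = "PRS",
    region_col: str = "region_current",
    two_sided: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Fit the requested models for one trait; complete-pair analysis.

    Returns ``(fits, table)``: fits keyed by model id, and a tidy long table
    with one row per (model, term) plus fit-summary rows (R2m, R2c, variance
    components).
    """
    df = cohort.dropna(subset=[trait])
    sizes = df.groupby("FID")[trait].transform("size")
    df = df[sizes == 2].reset_index(drop=True)

    fits = {}
    rows = []
    for mid in model_ids:
        spec, X = build_design(
            mid, df, response=trait, prs_col=prs_col, region_col=region_col
        )
        factors = _factor_frames(df, spec, region_col=region_col)
        fit = fit_lmm(X, df[trait].to_numpy(), factors, two_sided=two_sided, spec=spec)
        r2_marginal_conditional(fit, X, df[trait].to_numpy())
        fits[mid] = fit
        for term in fit.params.index:
            rows.append({
                "trait": trait, "model": mid, "term": term,
                "estimate": fit.params[term], "se": fit.bse[term],
                "t": fit.tvalues[term], "p": fit.pvalues[term],
            })
        rows.append({
            "trait": trait, "model": mid, "term": "_fit",
            "estimate": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
            "r2_marginal": fit.r2_marginal, "r2_conditional": fit.r2_conditional,
            "vc_family": fit.vc.get("family", np.nan),
            "vc_region": fit.vc.get("region", np.nan),
            "vc_resid": fit.vc["resid"],
            "converged": fit.converged,
        })
    return fits, pd.DataFrame(rows)
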