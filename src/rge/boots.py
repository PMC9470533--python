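"""Dependent-coefficient bootstrap for the change in the within-family effect.

The within-family PRS coefficient from the family-only decomposition (model 2)
and from the family+region decomposition (model 4) are estimated on the same
rows, so their standard errors are strongly dependent. Resampling sibling
pairs with replacement and re-estimating both models inside each replicate
reproduces that dependence in the bootstrap distribution of the difference;
(diff / sd(diff))^2 is chi-square with 1 df under the null.

Sampling unit: families (sibling pairs), not individuals — resampling
individuals would destroy the within-family contrast. Each resampled copy of
a family is treated as a distinct family; all group means (family and region)
are recomputed inside each replicate, as the model formulas force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decomp import _LmmWork, build_design, fit_lmm, _factor_frames

__all__ = ["DiffTestResult", "bootstrap_within_diff", "bh_fdr"]


@dataclass
class DiffTestResult:
    trait: str
    beta_w2: float
    beta_w4: float
    difference: float
    se: float
    chi2: float
    pvalue: float
    n_boot: int
    n_failed: int
    seed: int
    unreliable: bool = False

    def to_dict(self) -> dict:
        return {
            "trait": self.trait, "beta_w2": self.beta_w2, "beta_w4": self.beta_w4,
            "difference": self.difference, "se": self.se, "chi2": self.chi2,
            "p": self.pvalue, "n_boot": self.n_boot, "n_failed": self.n_failed,
            "unreliable": self.unreliable,
        }


def _within_beta(df, model_id, region_col, lam=None, refit=False):
    """Within coefficient of one model on one (resampled) dataset.

    With ``lam`` given and ``refit=False``, solves the GLS fixed effects at
    those variance ratios (fast bootstrap path); otherwise runs full REML.
    """
    spec, X = build_design(model_id, df, region_col=region_col)
    y = df[spec.response].to_numpy() if spec.response in df else df["pheno"].to_numpy()
    factors = _factor_frames(df, spec, region_col=region_col)
    col = 1 + list(X.columns).index("PRS_w" if model_id != 5 else "PRS_wr")
    if refit or lam is None:
        fit = fit_lmm(X, y, factors, spec=spec)
        name = "PRS_w" if model_id != 5 else "PRS_wr"
        return float(fit.params[name]), fit._lam
    Xmat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    work = _LmmWork(Xmat, y, factors)
    beta, _, _ = work.gls([lam[nm] for nm in work.names])
    return float(beta[col]), None


def _design_arrays(model_id, prs, fam_codes, reg_codes, sex, age):
    """Numpy twin of build_design for the bootstrap inner loop.

    Returns (X without intercept, within-column index offset by the intercept,
    factor dict). fam_codes/reg_codes must be dense 0..q-1.
    """
    fam_mean = np.bincount(fam_codes, weights=prs) / np.bincount(fam_codes)
    mj = fam_mean[fam_codes]
    factors = {"family": fam_codes}
    if model_id == 1:
        cols = [prs]
    elif model_id == 2:
        cols = [prs - mj, mj]
    else:
        reg_mean = np.bincount(reg_codes, weights=prs) / np.bincount(reg_codes)
        mk = reg_mean[reg_codes]
        factors["region"] = reg_codes
        if model_id == 3:
            cols = [prs - mk, mk]
        elif model_id == 4:
            cols = [prs - mj - mk, mj - mk, mk]
        else:
            w = prs - mj
            wbar = (np.bincount(reg_codes, weights=w) / np.bincount(reg_codes))[reg_codes]
            cols = [w - wbar, wbar]
    X = np.column_stack([np.ones(len(prs))] + cols + [sex, age])
    return X, 1, factors


def bootstrap_within_diff(
    cohort: pd.DataFrame,
    trait: str,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    model_pair: tuple[int, int] = (2, 4),
    region_col: str = "region_current",
    refit_variance: bool = False,
    unit: str = "family",
) -> DiffTestResult:
    """Bootstrap test for the difference in the within effect between two models.

    The point estimates come from full REML fits on the original data. Each
    replicate resamples sampling units with replacement to the original size,
    recomputes all group means, and re-estimates both models; by default the
    REML variance ratios are held at the full-sample estimates and only the
    GLS fixed effects are re-solved (``refit_variance=True`` re-profiles them
    per replicate). SE = sd of the per-replicate difference; p from
    chi-square(1) of (diff/SE)^2. Replicates where a fit fails are skipped
    and counted; more than 10% failures flags the result unreliable.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if unit not in ("family", "individual"):
        raise ValueError("unit must be 'family' or 'individual'")
    rng = np.random.default_rng(seed)

    df = cohort.dropna(subset=[trait]).copy()
    sizes = df.groupby("FID")[trait].transform("size")
    df = df[sizes == 2].reset_index(drop=True)
    df = df.rename(columns={trait: "pheno"})

    m_a, m_b = model_pair
    beta_a, lam_a = _within_beta(df, m_a, region_col, refit=True)
    beta_b, lam_b = _within_beta(df, m_b, region_col, refit=True)
    lam_a = dict(zip(["family"] if m_a in (1, 2) else ["family", "region"], lam_a))
    lam_b = dict(zip(["family"] if m_b in (1, 2) else ["family", "region"], lam_b))

    if unit == "family":
        fam_ids = df["FID"].to_numpy()
        fams, first = np.unique(fam_ids, return_index=True)
        F = len(fams)
        # row indices of each family's two rows, in a dense (F, 2) array
        order = np.argsort(fam_ids, kind="stable")
        rows_by_fam = order.reshape(F, 2)
    else:
        F = len(df)

    prs_all = df["PRS"].to_numpy(dtype=float)
    y_all = df["pheno"].to_numpy(dtype=float)
    sex_all = df["sex"].to_numpy(dtype=float)
    age_all = df["age"].to_numpy(dtype=float)
    _, reg_all = np.unique(df[region_col].to_numpy(), return_inverse=True)

    def _fast_beta(rows, new_fam, model_id, lam):
        _, reg_c = np.unique(reg_all[rows], return_inverse=True)
        _, fam_c = np.unique(new_fam, return_inverse=True)
        X, off, factors = _design_arrays(
            model_id, prs_all[rows], fam_c, reg_c, sex_all[rows], age_all[rows]
        )
        work = _LmmWork(X, y_all[rows], factors)
        beta, _, _ = work.gls([lam[nm] for nm in work.names])
        return float(beta[off])

    diffs = np.empty(n_boot)
    rep_a = np.empty(n_boot)
    rep_b = np.empty(n_boot)
    n_failed = 0
    base_cols = df[[region_col, "sex", "age", "PRS", "pheno"]]
    for b in range(n_boot):
        if unit == "family":
            pick = rng.integers(0, F, size=F)
            rows = rows_by_fam[pick].ravel()
            new_fid = np.repeat(np.arange(F), 2)  # each resampled copy is distinct
        else:
            rows = rng.integers(0, len(df), size=len(df))
            new_fid = df["FID"].to_numpy()[rows]
        try:
            if not refit_variance:
                ba = _fast_beta(rows, new_fid, m_a, lam_a)
                bb = _fast_beta(rows, new_fid, m_b, lam_b)
            else:
                boot = base_cols.iloc[rows].reset_index(drop=True)
                boot["FID"] = new_fid
                boot["IID"] = np.arange(len(boot))
                ba, _ = _within_beta(boot, m_a, region_col, refit=True)
                bb, _ = _within_beta(boot, m_b, region_col, refit=True)
            diffs[b] = ba - bb
            rep_a[b], rep_b[b] = ba, bb
        except (np.linalg.LinAlgError, ValueError):
            diffs[b] = rep_a[b] = rep_b[b] = np.nan
            n_failed += 1

    good = diffs[~np.isnan(diffs)]
    se = float(np.std(good, ddof=1))
    diff = beta_a - beta_b
    chi2 = (diff / se) ** 2 if se > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if se > 0 else 1.0
    result = DiffTestResult(
        trait=trait, beta_w2=beta_a, beta_w4=beta_b, difference=diff, se=se,
        chi2=float(chi2), pvalue=p, n_boot=n_boot, n_failed=n_failed, seed=seed,
        unreliable=(n_failed > 0.1 * n_boot),
    )
    result.replicates = {"diff": diffs, "a": rep_a, "b": rep_b}
    return result


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone nondecreasing in p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
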