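"""Association scans with PC covariates and region fixed effects.

A scan regresses the phenotype on each SNP with sex, age, genotype PCs and,
optionally, dummy variables for all but one geographic region (birthplace
and/or current address). Covariates are absorbed once by projection
(Frisch-Waugh-Lovell), so per-SNP statistics equal the full joint OLS at a
fraction of the cost. Also provides the region variance-explained summary,
PGS residualization on PCs, and Moran's I spatial autocorrelation with a
permutation or normal-approximation test.

The GWAS cohort is assumed unrelated (the synthetic generator guarantees it);
no sparse-GRM random effect is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SumStats",
    "compute_pcs",
    "residualize_pgs",
    "make_region_dummies",
    "build_covariates",
    "assoc_scan",
    "region_r2",
    "morans_i",
]

SUMSTATS_COLS = ["SNP", "A1", "A2", "FRQ", "BETA", "SE", "Z", "N"]


@dataclass
class SumStats:
    """Per-SNP association results in summary-statistic convention."""

    table: pd.DataFrame  # columns SUMSTATS_COLS (+ CHISQ)
    n: int

    def to_file(self, path) -> None:
        self.table[SUMSTATS_COLS].to_csv(path, sep="\t", index=False)

    @property
    def z(self) -> np.ndarray:
        return self.table["Z"].to_numpy()

    @property
    def chisq(self) -> np.ndarray:
        return self.table["Z"].to_numpy() ** 2


def compute_pcs(genotypes: np.ndarray, n_pcs: int) -> np.ndarray:
    """Principal components of the column-standardized dosage matrix.

    Monomorphic SNPs are dropped with a warning. Scores have unit variance
    and a deterministic sign (the largest-magnitude SNP loading of each
    component is positive). ``n_pcs=0`` returns an empty block.
    """
    G = np.asarray(genotypes, dtype=float)
    n = G.shape[0]
    if n_pcs == 0:
        return np.empty((n, 0))
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} monomorphic SNPs", UserWarning)
        G = G[:, keep]
        sd = sd[keep]
    if min(G.shape) < n_pcs:
        raise ValueError("n_pcs exceeds the rank of the genotype matrix")
    Z = (G - G.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    sign = np.sign(Vt[np.arange(n_pcs), np.argmax(np.abs(Vt), axis=1)])
    sign[sign == 0] = 1.0
    scores = U * sign
    return scores / scores.std(axis=0)


def residualize_pgs(pgs: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    """OLS residual of the polygenic score on the PCs plus an intercept."""
    y = np.asarray(pgs, dtype=float)
    P = np.asarray(pcs, dtype=float)
    X = np.column_stack([np.ones(len(y)), P])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("PC block is rank deficient")
    return y - X @ coef


def make_region_dummies(
    labels, min_n: int = 0, prefix: str = "D", ref=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """0/1 dummies for all but one reference region (the most frequent level).

    Individuals in regions with fewer than ``min_n`` members are excluded;
    returns ``(dummies, keep_mask)`` where the dummies are indexed 0..sum(keep).
    """
    lab = pd.Series(np.asarray(labels))
    counts = lab.value_counts()
    small = counts[counts < min_n].index
    keep = ~lab.isin(small).to_numpy()
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} individuals in regions below min_n={min_n}",
            UserWarning,
        )
    lab = lab[keep]
    if ref is None:
        ref = lab.value_counts().idxmax()
    levels = [l for l in sorted(lab.unique()) if l != ref]
    D = pd.DataFrame(
        {f"{prefix}_{l}": (lab == l).astype(float).to_numpy() for l in levels},
        index=np.arange(len(lab)),
    )
    return D, keep


def build_covariates(
    cohort: pd.DataFrame,
    pcs: np.ndarray | None = None,
    regions: str = "none",
    *,
    birth_col: str = "region_birth",
    current_col: str = "region_current",
    min_region_n: int = 100,
    extra_cols: tuple[str, ...] = ("sex", "age"),
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate matrix for a scan condition in {none, birth, current, both}.

    Returns ``(C, keep_mask)``; region dummies drop one reference level per
    factor and individuals in regions below ``min_region_n`` are excluded.
    A condition number above 1e8 raises a multicollinearity warning.
    """
    if regions not in ("none", "birth", "current", "both"):
        raise ValueError(f"unknown region condition {regions!r}")
    n = len(cohort)
    keep = np.ones(n, dtype=bool)
    blocks = [cohort[c].to_numpy(dtype=float)[:, None] for c in extra_cols]
    if pcs is not None and pcs.shape[1] > 0:
        blocks.append(np.asarray(pcs, dtype=float))
    dummy_specs = []
    if regions in ("birth", "both"):
        dummy_specs.append(birth_col)
    if regions in ("current", "both"):
        dummy_specs.append(current_col)
    for col in dummy_specs:
        _, k = make_region_dummies(cohort[col].to_numpy(), min_region_n)
        keep &= k
    sub = cohort[keep]
    blocks = [b[keep] for b in blocks]
    for col in dummy_specs:
        D, k2 = make_region_dummies(sub[col].to_numpy(), 0, prefix=col)
        blocks.append(D.to_numpy())
    C = np.column_stack(blocks) if blocks else np.empty((keep.sum(), 0))
    if C.shape[1] > 1:
        s = np.linalg.svd(C - C.mean(axis=0), compute_uv=False)
        if s[-1] <= 0 or s[0] / max(s[-1], 1e-300) > 1e8:
            warnings.warn(
                "covariate block is ill conditioned; estimates may be unstable "
                "(may be caused by multicollinearity)", UserWarning,
            )
    return C, keep


def assoc_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    snp_ids=None,
    a1=None,
    a2=None,
) -> SumStats:
    """Per-SNP OLS with covariates absorbed by projection (FWL).

    Both the phenotype and every SNP are residualized on [1, covariates] via
    one QR decomposition; the per-SNP slope, SE (with the joint-model residual
    df) and z then equal the full joint OLS. SNPs collinear with the
    covariates get NaN statistics and a warning.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = G.shape
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    X = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    if float(y_r @ y_r) <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("phenotype has zero residual variance after covariates")
    G_r = G - Q @ (Q.T @ G)

    gtg = np.einsum("ij,ij->j", G_r, G_r)
    gty = G_r.T @ y_r
    df = n - X.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gty / gtg
        rss = (y_r @ y_r) - beta * gty
        se = np.sqrt(rss / df / gtg)
        z = beta / se
    bad = gtg <= 1e-10 * n
    if bad.any():
        warnings.warn(f"{int(bad.sum())} SNPs collinear with covariates", UserWarning)
        beta[bad] = np.nan
        se[bad] = np.nan
        z[bad] = np.nan

    tab = pd.DataFrame({
        "SNP": snp_ids if snp_ids is not None else [f"snp{i}" for i in range(m)],
        "A1": a1 if a1 is not None else ["A"] * m,
        "A2": a2 if a2 is not None else ["G"] * m,
        "FRQ": G.mean(axis=0) / 2.0,
        "BETA": beta, "SE": se, "Z": z, "N": n,
    })
    tab["CHISQ"] = tab["Z"] ** 2
    return SumStats(table=tab, n=n)


def region_r2(
    phenotype: np.ndarray,
    region_labels,
    base_covariates: np.ndarray | None = None,
) -> dict:
    """Incremental variance explained by region dummies over base covariates.

    Returns raw and adjusted incremental R^2. A single region explains 0 by
    definition.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    lab = np.asarray(region_labels)
    if len(np.unique(lab)) < 2:
        return {"r2": 0.0, "adj_r2": 0.0}
    C = np.empty((n, 0)) if base_covariates is None else np.asarray(base_covariates, dtype=float)
    D, _ = make_region_dummies(lab, 0)

    def _fit(Xb):
        X = np.column_stack([np.ones(n), Xb])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        r2 = 1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - X.shape[1])
        return r2, adj

    r2_base, adj_base = _fit(C)
    r2_full, adj_full = _fit(np.column_stack([C, D.to_numpy()]) if C.size else D.to_numpy())
    return {"r2": r2_full - r2_base, "adj_r2": adj_full - adj_base}


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    *,
    alternative: str = "greater",
    method: str = "permutation",
) -> tuple[float, float]:
    """Moran's I spatial autocorrelation with a permutation or normal test.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    values and S0 the total weight. The permutation p-value shuffles values
    over units; the normal approximation uses the randomization moments.
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 spatial units")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    S0 = W.sum()

    def _I(v):
        z = v - v.mean()
        return (n / S0) * float(z @ W @ z) / float(z @ z)

    I_obs = _I(x)
    if method == "normal":
        EI = -1.0 / (n - 1)
        S1 = 0.5 * np.sum((W + W.T) ** 2)
        S2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
        z = x - x.mean()
        b2 = n * np.sum(z**4) / (np.sum(z**2) ** 2)
        A = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2)
        Bq = b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2)
        varI = (A - Bq) / ((n - 1) * (n - 2) * (n - 3) * S0**2) - EI**2
        zscore = (I_obs - EI) / np.sqrt(varI)
        if alternative == "greater":
            p = float(stats.norm.sf(zscore))
        elif alternative == "less":
            p = float(stats.norm.cdf(zscore))
        else:
            p = float(2 * stats.norm.sf(abs(zscore)))
        return I_obs, p

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = _I(rng.permutation(x))
    if alternative == "greater":
        extreme = np.sum(perm >= I_obs)
    elif alternative == "less":
        extreme = np.sum(perm <= I_obs)
    else:
        EI = -1.0 / (n - 1)
        extreme = np.sum(np.abs(perm - EI) >= abs(I_obs - EI))
    p = float((1 + extreme) / (n_perm + 1))
    return I_obs, p
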