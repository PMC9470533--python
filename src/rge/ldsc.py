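"""LD score regression: SNP heritability, genetic correlation, change tests.

h2 comes from the weighted regression of per-SNP chi-square on the LD score
(slope * M / N); the genetic covariance of two traits from the regression of
the product of their z-scores on the LD score (slope * M / sqrt(N1*N2)); and
r_g = gencov / sqrt(h2_1 * h2_2). Standard errors use a delete-one-block
jackknife over contiguous SNP blocks. Because scans with and without region
covariates share the same sample, their h2/r_g estimates are strongly
dependent; the change test therefore differences the delete-one-block
estimates of the two fits (same SNPs, same blocks) before forming the
jackknife SE, and divides the difference by that SE for a Z test.

Regression weights: 1/max(l_j, 1) heteroskedasticity weights, with one update
from a provisional fit (w = 1 / (max(l,1) * E[chi2]^2)); full iterative
weighting is deliberately not re-derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdScores",
    "LdscFit",
    "empirical_ld_scores",
    "assign_blocks",
    "h2_ldsc",
    "rg_ldsc",
    "delta_test",
]


@dataclass
class LdScores:
    snp: np.ndarray          # SNP ids
    l: np.ndarray            # per-SNP LD score
    blocks: np.ndarray       # jackknife block id per SNP

    @property
    def M(self) -> int:
        return len(self.l)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.snp, "L2": self.l, "BLOCK": self.blocks})


@dataclass
class LdscFit:
    """One h2 or r_g estimate with its jackknife machinery.

    ``delete_one`` holds the delete-one-block estimates that make dependent
    change tests possible. h2 may be <= 0 by sampling noise (reported, not
    truncated); r_g is clipped to [-1.25, 1.25] for display only (the raw
    value is kept in ``estimate``).
    """

    kind: str                # "h2" or "rg"
    estimate: float
    intercept: float
    se: float
    delete_one: np.ndarray
    block_ids: np.ndarray
    M: int
    N: float
    N2: float | None = None
    flags: list = field(default_factory=list)

    @property
    def display(self) -> float:
        if self.kind == "rg" and np.isfinite(self.estimate):
            return float(np.clip(self.estimate, -1.25, 1.25))
        return self.estimate

    def z_against_zero(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.nan


def assign_blocks(m: int, n_blocks: int | None = None) -> np.ndarray:
    """Deterministic contiguous jackknife blocks in SNP order."""
    if n_blocks is None:
        n_blocks = min(200, max(2, m // 10))
    edges = (np.arange(m) * n_blocks) // m
    return edges


def empirical_ld_scores(
    reference: np.ndarray,
    block_ids: np.ndarray,
    snp_ids=None,
    n_jackknife_blocks: int | None = None,
) -> LdScores:
    """LD scores from a reference panel: l_j = sum of bias-corrected r^2 over
    the SNPs sharing j's LD block (self term included).

    ``reference`` is haplotypes or dosages (N x M); r^2 is corrected as
    r2 - (1 - r2)/(N - 2). Monomorphic SNPs are dropped.
    """
    R = np.asarray(reference, dtype=float)
    N, m = R.shape
    if N < 3:
        raise ValueError("reference panel too small")
    block_ids = np.asarray(block_ids)
    sd = R.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} monomorphic SNPs", UserWarning)
    R = R[:, keep]
    block_ids = block_ids[keep]
    ids = (np.asarray(snp_ids)[keep] if snp_ids is not None
           else np.array([f"snp{i}" for i in np.flatnonzero(keep)]))

    Z = (R - R.mean(axis=0)) / R.std(axis=0)
    l = np.empty(Z.shape[1])
    for b in np.unique(block_ids):
        cols = np.flatnonzero(block_ids == b)
        corr = (Z[:, cols].T @ Z[:, cols]) / N
        r2 = corr**2
        r2_adj = r2 - (1.0 - r2) / (N - 2)
        l[cols] = r2_adj.sum(axis=1)
    jk = assign_blocks(len(l), n_jackknife_blocks)
    return LdScores(snp=ids, l=l, blocks=jk)


# ---------------------------------------------------------------------------
# Weighted regression with delete-one-block jackknife
# ---------------------------------------------------------------------------

def _wls(y, x, w):
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(len(x)), x]) * sw[:, None]
    coef, _, _, _ = np.linalg.lstsq(X, y * sw, rcond=None)
    return coef[0], coef[1]


def _ldsc_weights(l, pred):
    base = 1.0 / np.maximum(l, 1.0)
    return base / np.maximum(pred, 0.1) ** 2


def _jackknife_regression(y, l, blocks):
    """Two-pass weighted chi2 ~ l regression plus delete-one-block coefs.

    Returns (intercept, slope, per-block (intercept, slope) array).
    """
    w0 = 1.0 / np.maximum(l, 1.0)
    i0, s0 = _wls(y, l, w0)
    pred = np.maximum(i0 + s0 * l, 0.1)
    w = _ldsc_weights(l, pred)
    icept, slope = _wls(y, l, w)
    uniq = np.unique(blocks)
    coefs = np.empty((len(uniq), 2))
    for bi, b in enumerate(uniq):
        m = blocks != b
        coefs[bi] = _wls(y[m], l[m], w[m])
    return icept, slope, coefs, uniq


def _jackknife_se(delete_one: np.ndarray) -> float:
    B = len(delete_one)
    mean = delete_one.mean()
    return float(np.sqrt((B - 1) / B * np.sum((delete_one - mean) ** 2)))


def _check_sumstats(ss: pd.DataFrame) -> pd.DataFrame:
    if "N" not in ss.columns or ss["N"].isna().any():
        raise ValueError("sumstats must carry per-SNP N")
    return ss


def _merge_ld(ss: pd.DataFrame, ld: LdScores) -> pd.DataFrame:
    ldf = ld.to_frame()
    merged = ss.merge(ldf, on="SNP", how="inner")
    if len(merged) < len(ldf):
        warnings.warn(
            f"{len(ldf) - len(merged)} scored SNPs missing from sumstats", UserWarning
        )
    return merged


def h2_ldsc(sumstats: pd.DataFrame | "object", ldscores: LdScores) -> LdscFit:
    """SNP heritability by LD score regression with block-jackknife SE.

    ``sumstats`` needs columns SNP, Z (or CHISQ) and N. h2 = slope * M / N
    with a free intercept; M is the number of scored SNPs.
    """
    ss = sumstats.table if hasattr(sumstats, "table") else sumstats
    ss = _check_sumstats(ss)
    merged = _merge_ld(ss, ldscores)
    if len(merged) < 200:
        raise ValueError("need at least 200 SNPs for LD score regression")
    l = merged["L2"].to_numpy()
    if np.ptp(l) == 0:
        raise ValueError("constant LD scores: slope unidentifiable")
    chi2 = (merged["CHISQ"] if "CHISQ" in merged else merged["Z"] ** 2).to_numpy()
    N = float(merged["N"].mean())
    M = ldscores.M
    blocks = merged["BLOCK"].to_numpy()

    icept, slope, coefs, uniq = _jackknife_regression(chi2, l, blocks)
    h2 = slope * M / N
    d1 = coefs[:, 1] * M / N
    return LdscFit(
        kind="h2", estimate=float(h2), intercept=float(icept),
        se=_jackknife_se(d1), delete_one=d1, block_ids=uniq, M=M, N=N,
    )


def rg_ldsc(
    sumstats1, sumstats2, ldscores: LdScores
) -> LdscFit:
    """Genetic correlation from the regression of z1*z2 on the LD score.

    The two sumstats are intersected on SNP id with an allele-match check
    (swapped A1/A2 flips the second z; any other mismatch drops the SNP).
    gencov = slope * M / sqrt(N1*N2); r_g = gencov / sqrt(h2_1 * h2_2). The
    jackknife recomputes all three regressions per deleted block, so the
    delete-one r_g values honor the dependence between numerator and
    denominators. Nonpositive h2 in either trait flags r_g undefined.
    """
    ss1 = (sumstats1.table if hasattr(sumstats1, "table") else sumstats1).copy()
    ss2 = (sumstats2.table if hasattr(sumstats2, "table") else sumstats2).copy()
    _check_sumstats(ss1), _check_sumstats(ss2)
    m = ss1.merge(ss2, on="SNP", suffixes=("_1", "_2"))
    if {"A1_1", "A1_2", "A2_1", "A2_2"} <= set(m.columns):
        same = (m["A1_1"] == m["A1_2"]) & (m["A2_1"] == m["A2_2"])
        flipped = (m["A1_1"] == m["A2_2"]) & (m["A2_1"] == m["A1_2"])
        bad = ~(same | flipped)
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} allele-mismatched SNPs", UserWarning)
        m = m[~bad].copy()
        m.loc[flipped[~bad], "Z_2"] *= -1.0
    merged = _merge_ld(m, ldscores)
    l = merged["L2"].to_numpy()
    if np.ptp(l) == 0:
        raise ValueError("constant LD scores: slope unidentifiable")
    blocks = merged["BLOCK"].to_numpy()
    M = ldscores.M
    z1, z2 = merged["Z_1"].to_numpy(), merged["Z_2"].to_numpy()
    N1, N2 = float(merged["N_1"].mean()), float(merged["N_2"].mean())

    def _all_three(mask):
        i1, s1 = _two_pass(z1[mask] ** 2, l[mask])
        i2, s2 = _two_pass(z2[mask] ** 2, l[mask])
        ig, sg = _two_pass(z1[mask] * z2[mask], l[mask])
        h1 = s1 * M / N1
        h2 = s2 * M / N2
        gencov = sg * M / np.sqrt(N1 * N2)
        denom = h1 * h2
        rg = gencov / np.sqrt(denom) if denom > 0 else np.nan
        return rg, gencov, h1, h2, ig

    def _two_pass(y, lv):
        i0, s0 = _wls(y, lv, 1.0 / np.maximum(lv, 1.0))
        pred = np.maximum(np.abs(i0 + s0 * lv), 0.1)
        return _wls(y, lv, _ldsc_weights(lv, pred))

    full = np.ones(len(l), dtype=bool)
    rg, gencov, h1, h2v, icept_g = _all_three(full)
    uniq = np.unique(blocks)
    d1 = np.empty(len(uniq))
    for bi, b in enumerate(uniq):
        d1[bi] = _all_three(blocks != b)[0]
    flags = []
    if not np.isfinite(rg):
        flags.append("nonpositive h2: r_g undefined")
    good = d1[np.isfinite(d1)]
    se = _jackknife_se(good) if len(good) > 1 else np.nan
    return LdscFit(
        kind="rg", estimate=float(rg), intercept=float(icept_g), se=se,
        delete_one=d1, block_ids=uniq, M=M, N=N1, N2=N2, flags=flags,
    )


def delta_test(fitA: LdscFit, fitB: LdscFit) -> tuple[float, float, float, float]:
    """Dependence-aware test for a change in h2 or r_g between two fits.

    Both fits must come from the same SNP set and block assignment; the
    per-block delete-one differences give the SE of the difference, honoring
    the dependence induced by the shared sample. Returns (delta, se, Z, p)
    with a two-sided normal p.
    """
    if fitA.kind != fitB.kind:
        raise ValueError("cannot difference fits of different kinds")
    if fitA.M != fitB.M or not np.array_equal(fitA.block_ids, fitB.block_ids):
        raise ValueError("fits use different SNPs/blocks; refusing to intersect")
    delta = fitA.estimate - fitB.estimate
    d = fitA.delete_one - fitB.delete_one
    d = d[np.isfinite(d)]
    se = _jackknife_se(d) if len(d) > 1 else np.nan
    if se == 0:
        return delta, 0.0, 0.0, 1.0
    z = delta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(delta), float(se), float(z), p
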