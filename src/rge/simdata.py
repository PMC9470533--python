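"""Synthetic cohorts with controllable gene-environment correlation (rGE).

Generates sibling-pair pedigrees, block-LD genotypes, geographic regions with
an SES gradient, passive rGE (parents sort into birth regions by their genetic
value), active rGE (individuals migrate by their own within-family genetic
deviation), and polygenic phenotypes with region and family environments.
Every generative parameter has an analytic ground truth used by the test
suite: sibling polygenic scores correlate 0.5, block-exchangeable LD gives
closed-form LD scores, and the phenotype variance fractions are the config
fields themselves.

The generative commitments: additive SNP effects; rank-based sorting into
equally sized regions via a standardized latent SES score; Gaussian noise
everywhere; exactly two siblings per family; polygenic-score weight error as
independent Gaussian noise on the true effects (closed-form attenuation).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "RegionLayout",
    "GenotypeSet",
    "ParentPop",
    "TraitSpec",
    "simulate_regions",
    "simulate_parents",
    "transmit_genotypes",
    "migrate",
    "simulate_phenotype",
    "simulate_trait_effects",
    "true_ld_scores",
    "simulate_sibling_cohort",
    "simulate_unrelated_cohort",
    "DEFAULT_TRAITS",
]

# Small fixed covariate effects added to every phenotype (standardized scale).
SEX_EFFECT = 0.10
AGE_EFFECT = 0.05
AGE_RANGE = (40.0, 70.0)  # adult cohort


class InvalidConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Generative parameters for one synthetic study.

    Variance fractions (``h2_direct``, ``var_region``, ``var_family``) are on
    the scale of a unit-variance phenotype and must sum to at most 1.
    ``ld_block_r`` is either a single haplotype correlation shared by all LD
    blocks or a ``(lo, hi)`` pair from which a per-block correlation is drawn
    uniformly (varying LD scores, as LD score regression requires).
    """

    n_families: int = 20_000
    n_regions: int = 100
    n_snps: int = 1_000
    ld_block_size: int = 10
    ld_block_r: float | tuple[float, float] = (0.1, 0.7)
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_direct: float = 0.3
    w_passive: float = 0.5
    w_active: float = 0.5
    var_region: float = 0.2
    var_family: float = 0.2
    delta_nurture: float = 0.1
    pgs_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 2:
            raise InvalidConfigError("n_regions must be >= 2")
        if self.n_families < 1:
            raise InvalidConfigError("n_families must be >= 1")
        if self.n_snps % self.ld_block_size != 0:
            raise InvalidConfigError(
                f"ld_block_size ({self.ld_block_size}) must divide n_snps ({self.n_snps})"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie in (0, 0.5]")
        for r in self._block_r_bounds():
            if not (0.0 <= r < 1.0):
                raise InvalidConfigError("ld_block_r must lie in [0, 1)")
        for name in ("h2_direct", "var_region", "var_family", "pgs_noise"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.h2_direct + self.var_region + self.var_family > 1.0 + 1e-12:
            raise InvalidConfigError(
                "h2_direct + var_region + var_family must be <= 1"
            )

    def _block_r_bounds(self) -> tuple[float, float]:
        if np.isscalar(self.ld_block_r):
            r = float(self.ld_block_r)  # type: ignore[arg-type]
            return (r, r)
        lo, hi = self.ld_block_r  # type: ignore[misc]
        return (float(lo), float(hi))

    def draw_block_r(self, rng: np.random.Generator) -> np.ndarray:
        """Per-block haplotype correlation (length n_snps / ld_block_size)."""
        n_blocks = self.n_snps // self.ld_block_size
        lo, hi = self._block_r_bounds()
        if lo == hi:
            return np.full(n_blocks, lo)
        return rng.uniform(lo, hi, size=n_blocks)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RegionLayout:
    """K regions on a near-square grid with standardized SES and rook adjacency."""

    region_id: np.ndarray      # (K,) ints 0..K-1
    ses: np.ndarray            # (K,) mean 0, variance 1 (ddof=0)
    x: np.ndarray              # (K,) grid column
    y: np.ndarray              # (K,) grid row
    weights: np.ndarray        # (K, K) symmetric 0/1 rook adjacency, zero diagonal

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.region_id, "ses": self.ses, "x": self.x, "y": self.y}
        )


@dataclass
class GenotypeSet:
    """Dosages plus the haplotypes and effect sizes behind them.

    ``dosages`` is individuals x M with values {0,1,2}; ``haplotypes`` is
    individuals x 2 x M with values {0,1} (kept so Mendelian transmission can
    pass whole haplotype blocks to offspring, preserving LD).
    """

    dosages: np.ndarray        # (n, M) int8
    haplotypes: np.ndarray     # (n, 2, M) uint8
    freqs: np.ndarray          # (M,) allele frequency of the counted allele
    beta: np.ndarray           # (M,) true additive effects
    block_r: np.ndarray        # (n_blocks,) haplotype correlation per LD block
    block_size: int
    role: str = "parent"       # "parent" or "sibling"

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def score(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Polygenic score with mean-centered dosages (true weights by default)."""
        w = self.beta if weights is None else weights
        return (self.dosages - 2.0 * self.freqs) @ w


@dataclass
class ParentPop:
    """Parent generation: couples 2f, 2f+1 form family f."""

    genotypes: GenotypeSet
    score_true: np.ndarray         # (2F,) true genetic value
    beta_hat: np.ndarray           # (M,) noisy PGS weights shared with offspring
    midparent: np.ndarray          # (F,) standardized midparent true score
    birth_region: np.ndarray       # (F,) couple's region id

    @property
    def n_families(self) -> int:
        return len(self.birth_region)


@dataclass
class TraitSpec:
    """A named synthetic phenotype.

    ``effect_corr`` is the correlation between this trait's causal effects and
    the focal (PGS) trait's effects; ``region_load`` is the signed coefficient
    on region SES (variance contributed = region_load**2); ``nurture`` is the
    effect of the standardized midparent focal score on the phenotype.
    """

    name: str
    h2: float = 0.3
    effect_corr: float = 0.0
    region_load: float = 0.0
    family_var: float = 0.0
    nurture: float = 0.0


# Qualitative classes of the real-trait menu: SES-like (all rGE channels),
# adiposity-like (region environment, negative genetic overlap with the focal
# SES score), blood-cell-like (no rGE).
DEFAULT_TRAITS = [
    TraitSpec("ses", h2=0.3, effect_corr=1.0, region_load=0.45, family_var=0.15, nurture=0.1),
    TraitSpec("adiposity", h2=0.3, effect_corr=-0.3, region_load=-0.35, family_var=0.1),
    TraitSpec("bloodcell", h2=0.3, effect_corr=0.0, region_load=0.0, family_var=0.05),
]


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def simulate_regions(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    ses_gradient: float = 0.6,
) -> RegionLayout:
    """Lay K regions on a near-square grid with standardized SES.

    SES mixes a smooth spatial gradient (weight ``ses_gradient``) with white
    noise, so regional SES is spatially autocorrelated as in real geography,
    then is standardized to mean 0 and variance 1 (ddof=0) exactly.
    """
    K = config.n_regions
    if K < 2:
        raise InvalidConfigError("need at least 2 regions")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    nrow = int(np.floor(np.sqrt(K)))
    ncol = int(np.ceil(K / nrow))
    cells = np.arange(K)
    y, x = np.divmod(cells, ncol)

    W = np.zeros((K, K))
    coord = {(int(yy), int(xx)): k for k, (yy, xx) in enumerate(zip(y, x))}
    for k in range(K):
        for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nb = coord.get((int(y[k]) + dy, int(x[k]) + dx))
            if nb is not None:
                W[k, nb] = 1.0

    g = float(np.clip(ses_gradient, 0.0, 1.0))
    grad = (x - x.mean()) + (y - y.mean())
    sd = grad.std()
    grad = grad / sd if sd > 0 else grad
    raw = g * grad + np.sqrt(max(0.0, 1.0 - g * g)) * rng.standard_normal(K)
    ses = (raw - raw.mean()) / raw.std()
    return RegionLayout(region_id=cells, ses=ses, x=x.astype(float), y=y.astype(float), weights=W)


def _rank_to_regions(latent: np.ndarray, layout: RegionLayout) -> np.ndarray:
    """Monotone map from a latent SES-rank score to region ids of equal size.

    Units with the highest latent score land in the region with the highest
    SES; region populations differ by at most one unit.
    """
    n = len(latent)
    K = layout.n_regions
    order = np.argsort(latent, kind="stable")
    ses_order = np.argsort(layout.ses, kind="stable")  # regions, ascending SES
    bins = (np.arange(n) * K) // n
    out = np.empty(n, dtype=np.int64)
    out[order] = layout.region_id[ses_order][bins]
    return out


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _draw_haplotypes(
    n_hap: int, p: np.ndarray, block_r: np.ndarray, block_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Block-exchangeable haplotypes via a copying model.

    Within a block all SNPs share one allele frequency. Each haplotype draws a
    block-level template allele A ~ Bern(p); each SNP copies A with
    probability sqrt(r) and otherwise draws fresh, giving pairwise allele
    correlation exactly r within the block and 0 across blocks.
    """
    M = len(p)
    n_blocks = M // block_size
    phi = np.sqrt(block_r)  # copy probability per SNP
    p_block = p.reshape(n_blocks, block_size)[:, 0]

    template = (rng.random((n_hap, n_blocks)) < p_block).astype(np.uint8)
    template = np.repeat(template, block_size, axis=1)
    copy = rng.random((n_hap, M)) < np.repeat(phi, block_size)
    fresh = (rng.random((n_hap, M)) < p).astype(np.uint8)
    return np.where(copy, template, fresh).astype(np.uint8)


def simulate_parents(
    config: SimConfig,
    layout: RegionLayout,
    rng: np.random.Generator | None = None,
) -> ParentPop:
    """Parent couples with HWE genotypes and passive-rGE birth regions.

    Couples are sorted into birth regions by a standardized latent
    ``w_passive * z(midparent score) + sqrt(1-w_passive^2) * noise``, mapped
    monotonically to region ids ordered by SES — the passive channel.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidConfigError("maf_range must lie in (0, 0.5]")

    F = config.n_families
    M = config.n_snps
    B = config.ld_block_size
    n_blocks = M // B
    block_r = config.draw_block_r(rng)
    p = np.repeat(rng.uniform(lo, hi, size=n_blocks), B)

    hap = _draw_haplotypes(2 * 2 * F, p, block_r, B, rng).reshape(2 * F, 2, M)
    dos = hap.sum(axis=1).astype(np.int8)

    var_sum = np.sum(2.0 * p * (1.0 - p))
    beta = rng.standard_normal(M) * np.sqrt(config.h2_direct / var_sum)
    beta_hat = beta + rng.standard_normal(M) * np.sqrt(config.pgs_noise / var_sum)

    geno = GenotypeSet(dos, hap, p, beta, block_r, B, role="parent")
    score_true = geno.score()

    mid = 0.5 * (score_true[0::2] + score_true[1::2])
    mid_sd = mid.std()
    mid_std = (mid - mid.mean()) / mid_sd if mid_sd > 0 else np.zeros_like(mid)
    w = config.w_passive
    latent = w * mid_std + np.sqrt(max(0.0, 1.0 - w * w)) * rng.standard_normal(F)
    birth_region = _rank_to_regions(latent, layout)

    return ParentPop(geno, score_true, beta_hat, mid_std, birth_region)


def transmit_genotypes(
    parents: ParentPop,
    rng: np.random.Generator | None = None,
    n_children: int = 2,
) -> GenotypeSet:
    """Mendelian transmission: each child receives one haplotype per parent per
    LD block (no recombination within blocks, free recombination between)."""
    rng = np.random.default_rng(0) if rng is None else rng
    geno = parents.genotypes
    n_parents, _, M = geno.haplotypes.shape
    if n_parents % 2 != 0:
        raise ValueError("parents must come in couples (even count)")
    F = n_parents // 2
    B = geno.block_size
    n_blocks = M // B

    # choice[f, c, s, b]: which haplotype of parent s family f passes to child c in block b
    choice = rng.integers(0, 2, size=(F, n_children, 2, n_blocks))
    choice_m = np.repeat(choice, B, axis=3)  # expand blocks to SNPs

    hap_par = geno.haplotypes.reshape(F, 2, 2, M)  # (family, parent, hap, M)
    child_hap = np.empty((F, n_children, 2, M), dtype=np.uint8)
    for s in range(2):  # parent side
        src = hap_par[:, s]                       # (F, 2, M)
        sel = choice_m[:, :, s, :]                # (F, C, M)
        child_hap[:, :, s, :] = np.take_along_axis(
            src[:, None, :, :].repeat(n_children, axis=1).reshape(F * n_children, 2, M),
            sel.reshape(F * n_children, 1, M),
            axis=1,
        ).reshape(F, n_children, M)

    child_hap = child_hap.reshape(F * n_children, 2, M)
    dos = child_hap.sum(axis=1).astype(np.int8)
    return GenotypeSet(
        dos, child_hap, geno.freqs, geno.beta, geno.block_r, B, role="sibling"
    )


# ---------------------------------------------------------------------------
# Migration and phenotypes
# ---------------------------------------------------------------------------

def migrate(
    cohort: pd.DataFrame,
    layout: RegionLayout,
    config: SimConfig,
    score_true: np.ndarray,
    midparent_std: np.ndarray,
    rng: np.random.Generator | None = None,
    persistence: float | None = None,
) -> pd.DataFrame:
    """Assign current regions through migration.

    The latent current-SES rank is ``a * z(midparent) + w_active * z(own score
    - family mean) + noise`` with ``a`` defaulting to ``w_passive`` (birth
    sorting persists at the passive strength). With ``w_active = 0`` current
    sorting reproduces the passive channel only.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    a = config.w_passive if persistence is None else persistence
    fam = cohort["FID"].to_numpy()
    fam_mean = pd.Series(score_true).groupby(fam).transform("mean").to_numpy()
    dev = score_true - fam_mean
    sd = dev.std()
    dev_std = dev / sd if sd > 0 else dev
    mid_i = midparent_std  # already per-individual

    wa = config.w_active
    noise_var = max(0.0, 1.0 - a * a - wa * wa)
    latent = a * mid_i + wa * dev_std + np.sqrt(noise_var) * rng.standard_normal(len(dev))
    out = cohort.copy()
    out["region_current"] = _rank_to_regions(latent, layout)
    return out


def simulate_trait_effects(
    config: SimConfig,
    beta_focal: np.ndarray,
    freqs: np.ndarray,
    spec: TraitSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Causal effects for a secondary trait with a given effect correlation to
    the focal trait, scaled so the genetic value has variance ``spec.h2``."""
    var_sum = np.sum(2.0 * freqs * (1.0 - freqs))
    rho = spec.effect_corr
    b_focal_unit = beta_focal / np.sqrt(config.h2_direct / var_sum) if config.h2_direct > 0 else rng.standard_normal(len(beta_focal))
    indep = rng.standard_normal(len(beta_focal))
    b = rho * b_focal_unit + np.sqrt(max(0.0, 1.0 - rho * rho)) * indep
    return b * np.sqrt(spec.h2 / var_sum)


def simulate_phenotype(
    cohort: pd.DataFrame,
    layout: RegionLayout,
    config: SimConfig,
    genetic_value: np.ndarray,
    midparent_std: np.ndarray,
    rng: np.random.Generator | None = None,
    *,
    region_basis: str = "region_current",
    region_load: float | None = None,
    family_var: float | None = None,
    nurture: float | None = None,
    name: str = "pheno",
) -> pd.DataFrame:
    """Add a phenotype column: genetics + nurture + region SES + family
    environment + residual, residual scaled so total variance is ~1, plus
    small fixed sex/age effects.
    """
    if config.h2_direct + config.var_region + config.var_family > 1.0 + 1e-12:
        raise InvalidConfigError("variance fractions sum to more than 1")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    load = np.sqrt(config.var_region) if region_load is None else region_load
    fvar = config.var_family if family_var is None else family_var
    nur = config.delta_nurture if nurture is None else nurture

    fam_codes, fam_idx = np.unique(cohort["FID"].to_numpy(), return_inverse=True)
    fam_env = rng.standard_normal(len(fam_codes)) * np.sqrt(fvar)
    ses_i = layout.ses[cohort[region_basis].to_numpy()]

    signal = genetic_value + nur * midparent_std + load * ses_i + fam_env[fam_idx]
    resid_var = max(0.0, 1.0 - float(np.var(signal)))
    yv = signal + rng.standard_normal(len(signal)) * np.sqrt(resid_var)

    age = cohort["age"].to_numpy()
    age_z = (age - age.mean()) / age.std() if age.std() > 0 else np.zeros_like(age)
    yv = yv + SEX_EFFECT * (cohort["sex"].to_numpy() - 0.5) + AGE_EFFECT * age_z

    out = cohort.copy()
    out[name] = yv
    return out


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def true_ld_scores(source: SimConfig | GenotypeSet) -> np.ndarray:
    """Closed-form LD scores for the block-exchangeable model.

    l_j = 1 + (B-1) * r_b^2 for every SNP j in block b. For a SimConfig with a
    scalar ld_block_r this is a single value for all SNPs; for a GenotypeSet
    it uses the realized per-block correlations.
    """
    if isinstance(source, GenotypeSet):
        B = source.block_size
        return np.repeat(1.0 + (B - 1) * source.block_r**2, B)
    B = source.ld_block_size
    lo, hi = source._block_r_bounds()
    if lo != hi:
        raise ValueError(
            "ld_block_r is a range; pass the realized GenotypeSet for per-block scores"
        )
    return np.full(source.n_snps, 1.0 + (B - 1) * lo**2)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _base_cohort(
    n: int, fam_ids: np.ndarray, birth_region: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "FID": fam_ids,
            "IID": np.arange(n),
            "region_birth": birth_region,
            "sex": rng.integers(0, 2, size=n),
            "age": np.round(rng.uniform(*AGE_RANGE, size=n), 1),
        }
    )


def simulate_sibling_cohort(
    config: SimConfig,
    layout: RegionLayout | None = None,
    traits: list[TraitSpec] | None = None,
    rng: np.random.Generator | None = None,
    keep_genotypes: bool = False,
):
    """Full sibling-pair cohort: genotypes, regions, PGS and phenotypes.

    Returns ``(cohort, layout, extras)`` where ``cohort`` has one row per
    sibling (two per family) with columns FID, IID, region_birth,
    region_current, sex, age, PRS and one phenotype column per trait, and
    ``extras`` carries ground truth (true scores, effects, genotypes if
    requested).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if layout is None:
        layout = simulate_regions(config, rng)
    traits = DEFAULT_TRAITS if traits is None else traits

    parents = simulate_parents(config, layout, rng)
    sibs = transmit_genotypes(parents, rng)
    F = parents.n_families
    n = 2 * F

    fam_ids = np.repeat(np.arange(F), 2)
    birth = parents.birth_region[fam_ids]
    cohort = _base_cohort(n, fam_ids, birth, rng)

    score_true = sibs.score()
    prs = sibs.score(parents.beta_hat)
    sd = prs.std()
    cohort["PRS"] = (prs - prs.mean()) / sd if sd > 0 else prs
    mid_i = parents.midparent[fam_ids]

    cohort = migrate(cohort, layout, config, score_true, mid_i, rng)

    extras = {
        "score_true": score_true,
        "beta_hat": parents.beta_hat,
        "beta": sibs.beta,
        "freqs": sibs.freqs,
        "midparent_std": parents.midparent,
        "trait_specs": {t.name: t for t in traits},
        "trait_effects": {},
    }
    if keep_genotypes:
        extras["genotypes"] = sibs

    for t in traits:
        b_t = simulate_trait_effects(config, sibs.beta, sibs.freqs, t, rng)
        g_t = (sibs.dosages - 2.0 * sibs.freqs) @ b_t
        extras["trait_effects"][t.name] = b_t
        cohort = simulate_phenotype(
            cohort, layout, config, g_t, mid_i, rng,
            region_load=t.region_load, family_var=t.family_var,
            nurture=t.nurture, name=f"pheno_{t.name}",
        )
    return cohort, layout, extras


def simulate_unrelated_cohort(
    config: SimConfig,
    layout: RegionLayout | None = None,
    traits: list[TraitSpec] | None = None,
    rng: np.random.Generator | None = None,
):
    """Unrelated GWAS cohort: one offspring per family, genotypes retained.

    Keeps the first sibling of each simulated pair so that birth regions carry
    passive rGE and current regions carry active rGE, while no two retained
    individuals are related (OLS association models are correctly specified).
    """
    cohort, layout, extras = simulate_sibling_cohort(
        config, layout, traits, rng, keep_genotypes=True
    )
    keep = np.arange(0, len(cohort), 2)
    sub = cohort.iloc[keep].reset_index(drop=True)
    geno: GenotypeSet = extras["genotypes"]
    extras = dict(extras)
    extras["genotypes"] = GenotypeSet(
        geno.dosages[keep], geno.haplotypes[keep], geno.freqs, geno.beta,
        geno.block_r, geno.block_size, role="unrelated",
    )
    extras["score_true"] = extras["score_true"][keep]
    return sub, layout, extras
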