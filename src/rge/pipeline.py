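"""End-to-end orchestration of the two analysis tracks.

Track 1 (siblings): fit decomposition models 1-5 per trait on a sibling-pair
cohort, bootstrap the model-2-vs-4 within-effect contrast, BH-correct across
traits, and summarize the between-family vs between-region (model 4) and
within- vs between-region (model 5) comparisons.

Track 2 (GWAS): on an unrelated cohort sharing the same region layout and SNP
effects, run association scans under the four region-control conditions
(none, birth, current, both), estimate h2 per trait and r_g of every trait
with the designated SES trait, and test each corrected condition against the
uncorrected one with the dependence-aware block-jackknife delta test.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boots, decomp, gwas, io, ldsc, simdata

__all__ = ["RunConfig", "run_sibling_track", "run_gwas_track", "run_all"]

log = logging.getLogger("rge")

CONDITIONS = ("none", "birth", "current", "both")


@dataclass
class RunConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    traits: list = field(default_factory=lambda: list(simdata.DEFAULT_TRAITS))
    models: tuple = (1, 2, 3, 4, 5)
    region_conditions: tuple = CONDITIONS
    ses_trait: str = "ses"
    n_boot: int = 1000
    n_pcs: int = 10
    min_region_n: int = 100
    fdr_alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.load_yaml_config(path)
        kw = {}
        if "simulate" in raw:
            kw["sim"] = io.sim_config_from_dict(raw["simulate"])
        if "traits" in raw:
            kw["traits"] = io.trait_specs_from_list(raw["traits"])
        for key in ("n_boot", "n_pcs", "min_region_n", "fdr_alpha", "seed",
                    "out_dir", "ses_trait"):
            if key in raw:
                kw[key] = raw[key]
        if "models" in raw:
            kw["models"] = tuple(raw["models"])
        if "region_conditions" in raw:
            kw["region_conditions"] = tuple(raw["region_conditions"])
        return cls(**kw)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _write(df: pd.DataFrame, out_dir, name):
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / name, sep="\t", index=False)


def run_sibling_track(
    config: RunConfig,
    cohort: pd.DataFrame | None = None,
    layout=None,
    out_dir=None,
) -> dict:
    """Decomposition report: model fits, bootstrap contrasts, comparisons."""
    t0 = time.time()
    if cohort is None:
        try:
            cohort, layout, _ = simdata.simulate_sibling_cohort(
                config.sim, traits=config.traits,
                rng=np.random.default_rng(config.seed),
            )
        except Exception as e:  # pragma: no cover - stage tagging
            raise StageError("simulate", e)
    trait_cols = [c for c in cohort.columns if c.startswith("pheno_")]

    tables, contrasts = [], []
    for col in trait_cols:
        try:
            fits, table = decomp.decompose_trait(cohort, col, config.models)
        except Exception as e:
            raise StageError(f"decompose:{col}", e)
        tables.append(table)
        if {2, 4} <= set(config.models):
            try:
                res = boots.bootstrap_within_diff(
                    cohort, col, n_boot=config.n_boot, seed=config.seed,
                )
            except Exception as e:
                raise StageError(f"bootstrap:{col}", e)
            contrasts.append(res.to_dict())
        # model 4: between-family vs between-region; model 5: within vs between region
    model_table = pd.concat(tables, ignore_index=True)
    contrast_table = pd.DataFrame(contrasts)
    if len(contrast_table):
        contrast_table["q"] = boots.bh_fdr(contrast_table["p"].to_numpy())

    def _pick(model, term, col):
        t = model_table
        sel = t[(t.model == model) & (t.term == term)]
        return sel.set_index("trait")[col]

    comparisons = pd.DataFrame({
        "m4_between_family": _pick(4, "PRS_bf", "estimate"),
        "m4_between_region": _pick(4, "PRS_br", "estimate"),
        "m5_within_region": _pick(5, "PRS_wr", "estimate"),
        "m5_between_region": _pick(5, "PRS_br", "estimate"),
    }) if {4, 5} <= set(config.models) else pd.DataFrame()

    _write(model_table, out_dir, "sibling_models.tsv")
    if len(contrast_table):
        _write(contrast_table, out_dir, "sibling_contrasts.tsv")
    if len(comparisons):
        _write(comparisons.reset_index(), out_dir, "sibling_comparisons.tsv")
    log.info("sibling track done in %.1fs", time.time() - t0)
    return {"models": model_table, "contrasts": contrast_table,
            "comparisons": comparisons, "cohort": cohort}


def _residual_variance_ratio(y, C_full, C_base) -> float:
    """var(y | full covariates) / var(y | base covariates) on the same rows."""

    def _rss(C):
        X = np.column_stack([np.ones(len(y)), C])
        Q, _ = np.linalg.qr(X)
        r = y - Q @ (Q.T @ y)
        return float(r @ r)

    return _rss(C_full) / _rss(C_base)


def run_gwas_track(
    config: RunConfig,
    cohort: pd.DataFrame | None = None,
    layout=None,
    extras: dict | None = None,
    out_dir=None,
) -> dict:
    """h2/r_g contrast report across region-control conditions."""
    t0 = time.time()
    if cohort is None:
        try:
            cohort, layout, extras = simdata.simulate_unrelated_cohort(
                config.sim, traits=config.traits,
                rng=np.random.default_rng(config.seed + 1),
            )
        except Exception as e:  # pragma: no cover
            raise StageError("simulate", e)
    geno: simdata.GenotypeSet = extras["genotypes"]
    G = geno.dosages.astype(float)
    try:
        pcs = gwas.compute_pcs(G, config.n_pcs)
    except Exception as e:
        raise StageError("pcs", e)

    lds = ldsc.empirical_ld_scores(
        G, np.repeat(np.arange(geno.n_snps // geno.block_size), geno.block_size)
    )

    trait_cols = [c for c in cohort.columns if c.startswith("pheno_")]
    ses_col = f"pheno_{config.ses_trait}"
    scans: dict[tuple, gwas.SumStats] = {}
    h2_fits: dict[tuple, ldsc.LdscFit] = {}
    rg_fits: dict[tuple, ldsc.LdscFit] = {}
    C_base, _ = gwas.build_covariates(cohort, pcs, "none")
    for cond in config.region_conditions:
        try:
            C, keep = gwas.build_covariates(
                cohort, pcs, cond, min_region_n=config.min_region_n
            )
        except Exception as e:
            raise StageError(f"covariates:{cond}", e)
        for col in trait_cols:
            y = cohort.loc[keep, col].to_numpy()
            try:
                ss = gwas.assoc_scan(G[keep], y, C)
            except Exception as e:
                raise StageError(f"scan:{cond}:{col}", e)
            scans[(cond, col)] = ss
            fit = ldsc.h2_ldsc(ss, lds)
            # express h2 on the original phenotype-variance scale: a scan on a
            # region-residualized trait otherwise measures h2 against the
            # smaller residual variance, mechanically inflating it
            scale = _residual_variance_ratio(y, C, C_base[keep])
            fit.estimate *= scale
            fit.se *= scale
            fit.delete_one = fit.delete_one * scale
            h2_fits[(cond, col)] = fit
        if ses_col in trait_cols:
            for col in trait_cols:
                if col == ses_col:
                    continue
                rg_fits[(cond, col)] = ldsc.rg_ldsc(
                    scans[(cond, col)], scans[(cond, ses_col)], lds
                )

    rows = []
    base = "none" if "none" in config.region_conditions else config.region_conditions[0]
    for cond in config.region_conditions:
        for col in trait_cols:
            fit = h2_fits[(cond, col)]
            row = {"trait": col.removeprefix("pheno_"), "condition": cond,
                   "h2": fit.estimate, "h2_se": fit.se, "intercept": fit.intercept}
            if (cond, col) in rg_fits:
                rg = rg_fits[(cond, col)]
                row.update({"rg_ses": rg.estimate, "rg_se": rg.se})
            if cond != base:
                d, se, z, p = ldsc.delta_test(h2_fits[(base, col)], fit)
                row.update({"h2_delta": d, "h2_delta_se": se, "h2_delta_z": z,
                            "h2_delta_p": p})
                if (cond, col) in rg_fits:
                    d, se, z, p = ldsc.delta_test(rg_fits[(base, col)], rg_fits[(cond, col)])
                    row.update({"rg_delta": d, "rg_delta_se": se,
                                "rg_delta_z": z, "rg_delta_p": p})
            rows.append(row)
    report = pd.DataFrame(rows)
    if "h2_delta_p" in report:
        mask = report["h2_delta_p"].notna()
        q = np.full(len(report), np.nan)
        if mask.any():
            q[mask.to_numpy()] = boots.bh_fdr(report.loc[mask, "h2_delta_p"].to_numpy())
        report["h2_delta_q"] = q
    _write(report, out_dir, "gwas_ldsc_report.tsv")
    log.info("gwas track done in %.1fs", time.time() - t0)
    return {"report": report, "scans": scans, "h2": h2_fits, "rg": rg_fits,
            "ldscores": lds, "cohort": cohort, "pcs": pcs}


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Both tracks on two cohorts sharing the region layout and SNP effects."""
    out_dir = out_dir or config.out_dir
    rng = np.random.default_rng(config.seed)
    layout = simdata.simulate_regions(config.sim, rng)
    sib_cohort, _, _ = simdata.simulate_sibling_cohort(
        config.sim, layout, config.traits, rng
    )
    gwas_cohort, _, gextras = simdata.simulate_unrelated_cohort(
        config.sim, layout, config.traits, np.random.default_rng(config.seed + 1)
    )
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": config.seed,
            "config_hash": io.config_hash({"sim": vars(config.sim),
                                           "n_boot": config.n_boot,
                                           "n_pcs": config.n_pcs}),
            "versions": _versions(),
        }
        (Path(out_dir) / "run_log.json").write_text(json.dumps(meta, indent=2))
    sib = run_sibling_track(config, sib_cohort, layout, out_dir=out_dir)
    gw = run_gwas_track(config, gwas_cohort, layout, gextras, out_dir=out_dir)
    return {"sibling": sib, "gwas": gw, "layout": layout}


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {"rge": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}
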