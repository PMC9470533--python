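"""Readers and writers for the pipeline's plain-text formats.

Phenotype/covariate tables are tab-delimited (FID, IID, region_birth,
region_current, sex, age, PRS, pheno_*). Genotypes travel as an uncompressed
VCF (GT field, one sample per individual) or as a plain 0/1/2 matrix with a
SNP map file (SNP, CHR, BP, A1, A2, MAF). Summary statistics follow the
whitespace-delimited SNP/A1/A2/FRQ/BETA/SE/Z/N convention. Configs are YAML.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simdata import GenotypeSet, RegionLayout, SimConfig, TraitSpec

__all__ = [
    "write_cohort", "read_cohort",
    "write_region_layout", "read_region_layout",
    "write_genotype_matrix", "read_genotype_matrix",
    "write_vcf", "read_vcf",
    "write_sumstats", "read_sumstats",
    "load_yaml_config", "dump_yaml_config", "config_hash",
]


class ParseError(ValueError):
    pass


# -- cohort tables ----------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("FID", "IID"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def write_region_layout(layout: RegionLayout, path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def read_region_layout(path) -> RegionLayout:
    df = pd.read_csv(path, sep="\t")
    for col in ("region", "ses", "x", "y"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    K = len(df)
    # adjacency is reconstructed from grid coordinates (rook neighbors)
    W = np.zeros((K, K))
    coords = {(int(r.y), int(r.x)): i for i, r in df.iterrows()}
    for i, r in df.iterrows():
        for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            j = coords.get((int(r.y) + dy, int(r.x) + dx))
            if j is not None:
                W[i, j] = 1.0
    return RegionLayout(
        region_id=df["region"].to_numpy(), ses=df["ses"].to_numpy(),
        x=df["x"].to_numpy(float), y=df["y"].to_numpy(float), weights=W,
    )


# -- genotypes --------------------------------------------------------------

def _snp_map(geno: GenotypeSet) -> pd.DataFrame:
    m = geno.n_snps
    return pd.DataFrame({
        "SNP": [f"snp{i}" for i in range(m)],
        "CHR": np.ones(m, dtype=int),
        "BP": np.arange(1, m + 1) * 1000,
        "A1": ["A"] * m, "A2": ["G"] * m,
        "MAF": np.minimum(geno.freqs, 1 - geno.freqs),
    })


def write_genotype_matrix(geno: GenotypeSet, prefix) -> None:
    """Plain 0/1/2 matrix (one row per individual) plus a SNP map TSV."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".geno.txt"), geno.dosages, fmt="%d")
    _snp_map(geno).to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)


def read_genotype_matrix(prefix) -> tuple[np.ndarray, pd.DataFrame]:
    prefix = Path(prefix)
    dosages = np.loadtxt(prefix.with_suffix(".geno.txt"), dtype=np.int8)
    snps = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    if dosages.ndim == 1:
        dosages = dosages[None, :]
    if dosages.shape[1] != len(snps):
        raise ParseError("genotype matrix and SNP map disagree on SNP count")
    return dosages, snps


def write_vcf(geno: GenotypeSet, sample_ids, path) -> None:
    """Minimal uncompressed VCF 4.2 with GT fields from the stored haplotypes."""
    snps = _snp_map(geno)
    hap = geno.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rge-simulator\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in sample_ids) + "\n")
        for j in range(geno.n_snps):
            gts = "\t".join(f"{hap[i, 0, j]}|{hap[i, 1, j]}" for i in range(len(sample_ids)))
            fh.write(f"1\t{(j + 1) * 1000}\tsnp{j}\tG\tA\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Read dosages of the ALT allele from a VCF.

    Multiallelic records are skipped with a count (returned third). Uses
    cyvcf2 when available, else a plain-text fallback parser.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    rows, meta, skipped = [], [], 0
    if VCF is not None:
        vcf = VCF(str(path))
        for var in vcf:
            if len(var.ALT) != 1:
                skipped += 1
                continue
            gt = np.array(var.genotypes)[:, :2].sum(axis=1)
            rows.append(gt)
            meta.append((var.ID, var.CHROM, var.POS, var.ALT[0], var.REF))
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 10:
                    raise ParseError(f"{path}:{ln}: truncated VCF record")
                if "," in parts[4]:
                    skipped += 1
                    continue
                gts = [sum(int(a) for a in g.replace("|", "/").split("/"))
                       for g in parts[9:]]
                rows.append(np.array(gts))
                meta.append((parts[2], parts[0], int(parts[1]), parts[4], parts[3]))
    if skipped:
        import warnings
        warnings.warn(f"skipped {skipped} multiallelic VCF records", UserWarning)
    dosages = np.array(rows, dtype=np.int8).T  # individuals x SNPs
    snps = pd.DataFrame(meta, columns=["SNP", "CHR", "BP", "A1", "A2"])
    return dosages, snps, skipped


# -- summary statistics -----------------------------------------------------

def write_sumstats(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("SNP", "A1", "A2", "FRQ", "BETA", "SE", "Z", "N") if c in table]
    table[cols].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("SNP", "Z", "N"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required sumstats column {col!r}")
    return df


# -- config -----------------------------------------------------------------

_SIM_FIELDS = {f.name for f in __import__("dataclasses").fields(SimConfig)}


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return raw


def sim_config_from_dict(d: dict) -> SimConfig:
    unknown = set(d) - _SIM_FIELDS
    if unknown:
        raise ParseError(f"unknown simulate field(s): {sorted(unknown)}")
    for key in ("n_families", "n_snps"):
        if key not in d:
            raise ParseError(f"config missing required field {key!r}")
    d = dict(d)
    for key in ("ld_block_r", "maf_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimConfig(**d)


def trait_specs_from_list(items: list) -> list[TraitSpec]:
    specs = []
    for it in items:
        if "name" not in it:
            raise ParseError("trait entry missing required field 'name'")
        specs.append(TraitSpec(**it))
    return specs


def dump_yaml_config(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def config_hash(obj: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(obj, sort_keys=True).encode()
    ).hexdigest()[:16]
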