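"""File formats, configuration and the per-gene analysis pipeline.

Score files are per-trait TSVs with columns GENE, CHR, POS, REF, ALT, MAF,
N and either (U, V) — score and its variance — or (BETA, SE). The LD source
is a dense per-gene correlation matrix TSV keyed by 'chrom:pos:ref:alt'
identifiers, a reference genotype table (samples x variants, entries
0/1/2), or a VCF. The genetic-correlation matrix C and the overlap
covariance zeta are K x K TSVs with a trait-name header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gene_tests import mtar_gene_test
from .kernels import DEFAULT_GRID
from .sumstats import (EffectSummary, LDMatrix, ScoreStats,
                       ld_from_reference, reconstruct_uv, variant_ids)
from .trait_cov import TraitCovariance, zeta_empirical

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "bonferroni_threshold",
    "read_score_file",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_ld_matrix",
    "read_genotype_table",
    "ld_from_vcf",
    "read_inputs",
    "run_pipeline",
    "write_results",
]

SCORE_COLS = ["GENE", "CHR", "POS", "REF", "ALT", "MAF", "N"]

RESULT_COLUMNS = ["GENE", "M_VARIANTS", "P_MTAR_O", "P_CMTAR", "P_IMTAR",
                  "P_CCTP", "P_MINP"]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


@dataclass
class AnalysisConfig:
    """Everything the per-gene pipeline needs."""

    traits: list[str]
    score_files: list[str]
    ld_source: str
    ld_kind: str = "matrix"  # matrix | matrix_dir | genotypes | vcf
    c_matrix: str | None = None
    zeta: str = "none"       # none | auto | path to a K x K TSV
    zscore_files: list[str] | None = None  # genome-wide Z TSVs for auto zeta
    maf_cap: float = 0.05
    min_variants: int = 2
    grid: tuple = DEFAULT_GRID
    weight_scheme: str = "beta_1_25"
    output: str | None = None
    log_level: str = "WARNING"
    seed: int | None = None  # simulation subcommand only

    def __post_init__(self) -> None:
        if len(self.traits) != len(self.score_files):
            raise ValueError("one score file per trait is required")
        if len(self.traits) < 1:
            raise ValueError("need at least one trait")
        for g in np.concatenate(self.grid):
            if not 0.0 <= float(g) <= 1.0:
                raise ValueError("grid values must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "grid" in raw:
            raw["grid"] = tuple(tuple(float(v) for v in axis)
                                for axis in raw["grid"])
        return cls(**raw)


def read_score_file(path, trait: str) -> pd.DataFrame:
    """Read one trait's score TSV; returns a frame with a `format` attr."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if {"U", "V"}.issubset(df.columns):
        fmt = "uv"
    elif {"BETA", "SE"}.issubset(df.columns):
        fmt = "beta_se"
    else:
        raise ValueError(f"{path}: need either (U, V) or (BETA, SE) columns")
    bad = df[SCORE_COLS].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed row at line {row}")
    df = df.copy()
    df.attrs["format"] = fmt
    df.attrs["trait"] = trait
    return df


def _gene_summary(rows: pd.DataFrame, trait: str, gene: str):
    variants = pd.DataFrame({
        "chrom": rows["CHR"].astype(str).to_numpy(),
        "pos": rows["POS"].astype(int).to_numpy(),
        "ref": rows["REF"].astype(str).to_numpy(),
        "alt": rows["ALT"].astype(str).to_numpy(),
    })
    n = int(rows["N"].max())
    maf = rows["MAF"].to_numpy(float)
    if rows.attrs.get("format") == "beta_se" or "BETA" in rows.columns and \
            "U" not in rows.columns:
        return EffectSummary(trait=trait, gene=gene, variants=variants,
                             beta=rows["BETA"].to_numpy(float),
                             se=rows["SE"].to_numpy(float), maf=maf,
                             n_samples=n)
    u = rows["U"].to_numpy(float)
    v = rows["V"].to_numpy(float)
    return ScoreStats(trait=trait, gene=gene, variants=variants, U=u,
                      V=np.diag(v), maf=maf, n_samples=n)


def read_trait_matrix(path, traits: list[str] | None = None) -> np.ndarray:
    """K x K TSV with trait-name header and index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if traits is not None:
        missing = [t for t in traits if t not in df.columns]
        if missing:
            raise ValueError(f"{path}: traits {missing} absent from matrix")
        df = df.loc[traits, traits]
    return df.to_numpy(float)


def write_trait_matrix(mat: np.ndarray, traits: list[str], path) -> None:
    pd.DataFrame(mat, index=traits, columns=traits).to_csv(path, sep="\t")


def _parse_variant_ids(ids) -> pd.DataFrame:
    parts = [str(v).split(":") for v in ids]
    if any(len(p) != 4 for p in parts):
        raise ValueError("variant ids must be 'chrom:pos:ref:alt'")
    return pd.DataFrame({
        "chrom": [p[0] for p in parts],
        "pos": [int(p[1]) for p in parts],
        "ref": [p[2] for p in parts],
        "alt": [p[3] for p in parts],
    })


def read_ld_matrix(path) -> LDMatrix:
    """Dense LD TSV keyed by 'chrom:pos:ref:alt' on both axes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: LD matrix rows and columns must match")
    return LDMatrix(variants=_parse_variant_ids(df.columns),
                    R=df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    ids = list(variant_ids(ld.variants))
    pd.DataFrame(ld.R, index=ids, columns=ids).to_csv(path, sep="\t")


def read_genotype_table(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Reference genotypes: TSV of 0/1/2, one column per variant id."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float), _parse_variant_ids(df.columns)


def ld_from_vcf(path, region: str | None = None) -> LDMatrix:
    """LD matrix from the biallelic variants of a (possibly regional) VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, genos = [], []
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1:
            continue
        g = np.asarray(rec.gt_types, dtype=float)
        g[g == 2] = np.nan  # UNKNOWN in cyvcf2 coding
        g[g == 3] = 2.0     # HOM_ALT
        if np.any(np.isnan(g)):
            g[np.isnan(g)] = np.nanmean(g)
        rows.append((str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
        genos.append(g)
    if not rows:
        raise ValueError(f"{path}: no biallelic variants found")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return ld_from_reference(np.column_stack(genos), variants)


def _gene_ld(config: AnalysisConfig, gene: str,
             wanted_ids: pd.Index) -> LDMatrix:
    kind = config.ld_kind
    if kind == "matrix":
        return read_ld_matrix(config.ld_source)
    if kind == "matrix_dir":
        return read_ld_matrix(Path(config.ld_source) / f"{gene}.tsv")
    if kind == "genotypes":
        geno, variants = _GENO_CACHE.setdefault(
            config.ld_source, read_genotype_table(config.ld_source))
        ids = variant_ids(variants)
        mask = ids.isin(wanted_ids)
        return ld_from_reference(geno[:, mask],
                                 variants.loc[mask.nonzero()[0]]
                                 .reset_index(drop=True))
    if kind == "vcf":
        return ld_from_vcf(config.ld_source)
    raise ValueError(f"unknown ld_kind {config.ld_kind!r}")


_GENO_CACHE: dict = {}


def _resolve_zeta(config: AnalysisConfig) -> TraitCovariance:
    if config.zeta == "none":
        return TraitCovariance.identity(config.traits)
    if config.zeta == "auto":
        if not config.zscore_files:
            raise ValueError("zeta: auto requires zscore_files")
        tables = {t: pd.read_csv(p, sep="\t")
                  for t, p in zip(config.traits, config.zscore_files)}
        return zeta_empirical(tables)
    zeta = read_trait_matrix(config.zeta, config.traits)
    return TraitCovariance(traits=list(config.traits), zeta=zeta,
                           provenance="file")


def read_inputs(config: AnalysisConfig):
    """Yield per-gene harmonised bundles.

    Each bundle is (gene, [ScoreStats per trait], LDMatrix, C, zeta).
    Genes with fewer than ``min_variants`` rare variants after harmonisation
    are skipped and counted (analysis is restricted to genes that contain at
    least two rare variants).
    """
    tables = {}
    for t, p in zip(config.traits, config.score_files):
        tables[t] = read_score_file(p, t)
    c_mat = (read_trait_matrix(config.c_matrix, config.traits)
             if config.c_matrix else np.eye(len(config.traits)))
    zeta = _resolve_zeta(config)
    genes: list[str] = []
    for t in config.traits:
        for g in tables[t]["GENE"].unique():
            if g not in genes:
                genes.append(g)
    n_skipped = 0
    for gene in genes:
        per_trait = []
        for t in config.traits:
            rows = tables[t][tables[t]["GENE"] == gene]
            rows = rows[rows["MAF"] <= config.maf_cap]
            if rows.shape[0] == 0:
                continue
            rows.attrs["format"] = tables[t].attrs["format"]
            per_trait.append(_gene_summary(rows, t, gene))
        if not per_trait:
            n_skipped += 1
            continue
        wanted = pd.Index(np.unique(np.concatenate(
            [s.ids.to_numpy() for s in per_trait])))
        try:
            ld_full = _gene_ld(config, gene, wanted)
        except FileNotFoundError:
            log.warning("gene %s: no LD source found; skipped", gene)
            n_skipped += 1
            continue
        stats = [reconstruct_uv(s, ld_full) for s in per_trait]
        stats = [s for s in stats if s.n_variants > 0]
        if not stats:
            n_skipped += 1
            continue
        union = pd.Index(np.unique(np.concatenate(
            [s.ids.to_numpy() for s in stats])))
        if union.size < config.min_variants:
            n_skipped += 1
            log.info("gene %s skipped: %d rare variant(s) after "
                     "harmonisation", gene, union.size)
            continue
        keep = np.flatnonzero(ld_full.ids.isin(union))
        ld = LDMatrix(
            variants=ld_full.variants.iloc[keep].reset_index(drop=True),
            R=ld_full.R[np.ix_(keep, keep)])
        yield gene, stats, ld, c_mat, zeta
    log.info("%d gene(s) skipped", n_skipped)


def run_pipeline(config: AnalysisConfig) -> pd.DataFrame:
    """Run the full battery gene by gene; one row per gene.

    Per-gene failures are isolated: the row carries NA P-values and the
    reason in the NOTE column.
    """
    rows = []
    traits = config.traits
    for gene, stats, ld, c_mat, zeta in read_inputs(config):
        row = {"GENE": gene, "M_VARIANTS": ld.R.shape[0], "NOTE": ""}
        try:
            present = [s.trait for s in stats]
            c_sub = c_mat[np.ix_([traits.index(t) for t in present],
                                 [traits.index(t) for t in present])]
            z_sub = zeta.zeta[np.ix_([traits.index(t) for t in present],
                                     [traits.index(t) for t in present])]
            res = mtar_gene_test(stats, ld, z_sub, C=c_sub,
                                 weight_scheme=config.weight_scheme,
                                 grid=config.grid)
            row.update({
                "P_MTAR_O": res.p_mtar_o, "P_CMTAR": res.p_cmtar,
                "P_IMTAR": res.p_imtar, "P_CCTP": res.p_cctp,
                "P_MINP": res.p_minp,
                "METHODS": ";".join(res.diagnostics["methods"]),
            })
            for t, ps, pb in zip(present, res.p_skat, res.p_burden):
                row[f"P_SKAT_{t}"] = ps
                row[f"P_BURDEN_{t}"] = pb
        except Exception as exc:  # per-gene isolation
            log.warning("gene %s failed: %s", gene, exc)
            row["NOTE"] = str(exc)
        rows.append(row)
    cols = list(RESULT_COLUMNS)
    for t in traits:
        cols += [f"P_SKAT_{t}", f"P_BURDEN_{t}"]
    cols += ["METHODS", "NOTE"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan if c not in ("GENE", "NOTE", "METHODS") else ""
    return df[cols]


def write_results(results: pd.DataFrame, path) -> None:
    """Write the results TSV with P-values in 6-significant-digit
    scientific notation; stable column order."""
    if results is None:
        raise ValueError("results must not be None")
    df = results.copy()
    for c in df.columns:
        if c.startswith("P_"):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.5e}")
    df.to_csv(path, sep="\t", index=False)
    log.info("wrote %d gene rows to %s", df.shape[0], path)
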