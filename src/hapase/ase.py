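"""SNV- and gene-level allele-specific expression testing.

Each sample (animal x tissue) is processed independently: informative
filtering (>= 10 reads), a two-tailed beta-binomial test per heterozygous SNV
against a balanced null, and Benjamini-Hochberg FDR across the sample's SNVs.
Gene-level ASE is the same test applied to phased haplotype-aggregated counts
(haplotype-1 reads out of total gene reads), with BH applied per sample across
genes — a separate testing family from the SNV level.

Also here: expression classification (monoallelic vs biallelic; "balanced"
labels non-significant results in summaries), reference-bias measurement,
allele fold change, subsampling robustness of a significant site, TPM-based
expression classes and tissue enrichment, and the Kruskal-Wallis test of
tissue dependence of read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from statsmodels.stats.multitest import multipletests

from .betabinom import TailMode, bb_rvs, bb_two_tailed_p_vec

__all__ = [
    "TestConfig",
    "filter_informative",
    "snv_ase_test",
    "aggregate_gene_haplotypes",
    "gene_ase_test",
    "classify_expression",
    "reference_bias",
    "allele_fold_change",
    "subsample_robustness",
    "tissue_enrichment",
    "expression_class_tpm",
    "tissue_dependence",
]


@dataclass(frozen=True)
class TestConfig:
    """Global ASE-test parameters.

    min_reads : informative-variant read threshold ("fewer than min_reads" dropped)
    rho       : constant beta-binomial overdispersion used by the tests
    null_alpha: allelic ratio under the balanced null
    fdr_q     : BH significance threshold
    tail_mode : "inclusive" (default) or "literal" two-tailed p
    """

    min_reads: int = 10
    rho: float = 0.001
    null_alpha: float = 0.5
    fdr_q: float = 0.05
    tail_mode: TailMode = "inclusive"

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must lie in (0, 1)")


def filter_informative(
    records: pd.DataFrame, config: TestConfig = TestConfig()
) -> tuple[pd.DataFrame, int]:
    """Keep informative variants (total reads >= min_reads); return drop tally."""
    keep = records["total_count"] >= config.min_reads
    return records[keep].reset_index(drop=True), int((~keep).sum())


def _bh_per_group(df: pd.DataFrame, group_cols: list[str], fdr_q: float) -> pd.Series:
    q = pd.Series(np.nan, index=df.index)
    for _, grp in df.groupby(group_cols, sort=False):
        q.loc[grp.index] = multipletests(grp["p_value"], method="fdr_bh")[1]
    return q


def classify_expression(ref_count: np.ndarray, alt_count: np.ndarray) -> np.ndarray:
    """Monoallelic iff one allele has zero reads; otherwise biallelic."""
    mono = (np.asarray(ref_count) == 0) | (np.asarray(alt_count) == 0)
    return np.where(mono, "monoallelic", "biallelic")


def allele_fold_change(
    ref_count: np.ndarray, alt_count: np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """max/min allele-count ratio; infinite for monoallelic sites at
    pseudocount 0, NaN when both counts are zero."""
    r = np.asarray(ref_count, dtype=float) + pseudocount
    a = np.asarray(alt_count, dtype=float) + pseudocount
    hi = np.maximum(r, a)
    lo = np.minimum(r, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = hi / lo
    return np.where(hi == 0, np.nan, fold)


def snv_ase_test(records: pd.DataFrame, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Two-tailed beta-binomial test per SNV, BH-corrected within each sample.

    ``records`` must already be informative-filtered.  The tested count is the
    reference count; the null is symmetric at ``null_alpha`` = 0.5 so the
    choice of allele is immaterial.
    """
    if records.empty:
        raise ValueError("no records to test")
    out = records.copy().reset_index(drop=True)
    out["p_value"] = bb_two_tailed_p_vec(
        out["ref_count"].to_numpy(),
        out["total_count"].to_numpy(),
        null_alpha=config.null_alpha,
        rho=config.rho,
        mode=config.tail_mode,
    )
    out["q_value"] = _bh_per_group(out, ["animal", "tissue"], config.fdr_q)
    out["is_ase"] = out["q_value"] < config.fdr_q
    out["ref_ratio"] = out["ref_count"] / out["total_count"]
    out["fold_change"] = allele_fold_change(
        out["ref_count"].to_numpy(), out["alt_count"].to_numpy()
    )
    out["expression_class"] = classify_expression(
        out["ref_count"].to_numpy(), out["alt_count"].to_numpy()
    )
    out["higher_allele"] = np.where(out["ref_count"] >= out["alt_count"], "ref", "alt")
    return out


def aggregate_gene_haplotypes(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Aggregate phased SNV counts to per-sample gene haplotype counts.

    For each (animal, tissue, gene): ``x`` sums the reads on haplotype 1
    (the ref count where hap1 carries ref, else the alt count) and ``y`` sums
    total reads.  Records lacking phase (``alt_on_hap1`` NA) or a gene
    assignment are excluded and tallied.  ``single_block`` marks genes whose
    SNVs all share one haplotype block in that animal.
    """
    has_phase = records["alt_on_hap1"].notna() & records["gene_id"].notna()
    n_excluded = int((~has_phase).sum())
    df = records[has_phase].copy()
    alt_on_hap1 = df["alt_on_hap1"].astype(bool)
    df["hap1_count"] = np.where(alt_on_hap1, df["alt_count"], df["ref_count"])

    grouped = df.groupby(["animal", "tissue", "gene_id"], sort=True)
    agg = grouped.agg(
        x=("hap1_count", "sum"),
        y=("total_count", "sum"),
        n_snvs=("snv_id", "nunique"),
        n_blocks=("block_id", "nunique"),
    ).reset_index()
    agg["single_block"] = agg["n_blocks"] <= 1
    agg = agg.drop(columns="n_blocks")
    return agg, n_excluded


def gene_ase_test(
    gene_counts: pd.DataFrame, config: TestConfig = TestConfig()
) -> pd.DataFrame:
    """Beta-binomial ASE test on haplotype-aggregated gene counts.

    BH is applied within each sample across its genes (a separate family from
    the SNV-level tests).  Rows with ``y`` = 0 are excluded.
    """
    if gene_counts.empty:
        raise ValueError("no gene counts to test")
    out = gene_counts[gene_counts["y"] > 0].copy().reset_index(drop=True)
    out["p_value"] = bb_two_tailed_p_vec(
        out["x"].to_numpy(),
        out["y"].to_numpy(),
        null_alpha=config.null_alpha,
        rho=config.rho,
        mode=config.tail_mode,
    )
    out["q_value"] = _bh_per_group(out, ["animal", "tissue"], config.fdr_q)
    out["is_ase"] = out["q_value"] < config.fdr_q
    out["hap1_ratio"] = out["x"] / out["y"]
    out["major_hap"] = np.where(out["hap1_ratio"] > 0.5, 1, 2)
    out["expression_class"] = classify_expression(
        out["x"].to_numpy(), (out["y"] - out["x"]).to_numpy()
    )
    return out


def reference_bias(records: pd.DataFrame) -> dict:
    """Median reference-read fraction, overall and per sample.

    The cohort-wide median is the empirical reference-mapping-bias summary; a
    value of 0.5 indicates no detectable bias.
    """
    if records.empty:
        raise ValueError("no records for reference-bias computation")
    ratio = records["ref_count"] / records["total_count"]
    per_sample = (
        records.assign(ref_ratio=ratio)
        .groupby(["animal", "tissue"])["ref_ratio"]
        .median()
        .reset_index()
    )
    return {"median": float(ratio.median()), "per_sample": per_sample}


def subsample_robustness(
    x: int,
    n: int,
    fractions: list[float],
    iterations: int,
    config: TestConfig = TestConfig(),
    seed: int = 0,
    alpha_sig: float = 0.05,
) -> pd.DataFrame:
    """Significance retention under read subsampling at fixed effect size.

    Each iteration thins the two allele counts independently by binomial
    thinning with the given fraction (expected allelic ratio preserved),
    reruns the two-tailed test, and tallies p < ``alpha_sig``.  Returns the
    proportion of significant iterations per fraction.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    alt = n - x
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"fraction must lie in (0, 1], got {frac}")
        ref_thin = rng.binomial(x, frac, size=iterations)
        alt_thin = rng.binomial(alt, frac, size=iterations)
        tot = ref_thin + alt_thin
        ok = tot > 0
        p = np.ones(iterations)
        if ok.any():
            p[ok] = bb_two_tailed_p_vec(
                ref_thin[ok], tot[ok], config.null_alpha, config.rho, config.tail_mode
            )
        rows.append({"fraction": frac, "proportion_significant": float(np.mean(p < alpha_sig))})
    return pd.DataFrame(rows)


def expression_class_tpm(tpm: float | np.ndarray) -> np.ndarray | str:
    """EBI-atlas-style expression classes from TPM.

    <= 0.5 not-expressed; (0.5, 10] low; (10, 1000] medium; > 1000 high.
    """
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be non-negative")
    out = np.select(
        [arr <= 0.5, arr <= 10, arr <= 1000],
        ["not-expressed", "low", "medium"],
        default="high",
    )
    return out if np.ndim(tpm) else str(out)


def tissue_enrichment(tpm: pd.DataFrame, factor: float = 4.0) -> pd.DataFrame:
    """Genes enriched in a tissue: mean TPM strictly greater than ``factor``
    times the mean TPM across all other tissues' samples.

    ``tpm`` columns are ``animal:tissue`` sample keys.
    """
    tissues = sorted({c.split(":", 1)[1] for c in tpm.columns})
    if len(tissues) < 2:
        raise ValueError("tissue enrichment requires at least two tissues")
    cols_by_tissue = {
        t: [c for c in tpm.columns if c.split(":", 1)[1] == t] for t in tissues
    }
    rows = []
    for t in tissues:
        in_cols = cols_by_tissue[t]
        out_cols = [c for c in tpm.columns if c not in in_cols]
        mean_in = tpm[in_cols].mean(axis=1)
        mean_out = tpm[out_cols].mean(axis=1)
        enriched = mean_in > factor * mean_out
        for gene in tpm.index[enriched]:
            rows.append(
                {
                    "gene_id": gene,
                    "tissue": t,
                    "mean_tpm": float(mean_in[gene]),
                    "mean_tpm_other": float(mean_out[gene]),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "mean_tpm", "mean_tpm_other"])


def tissue_dependence(records: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis test of read-count differences across tissues, per gene.

    Pools observations (total read counts) across animals within each tissue.
    Genes observed in fewer than two tissues are skipped; identical counts in
    every group give H = 0, p = 1.
    """
    rows = []
    for gene, grp in records.dropna(subset=["gene_id"]).groupby("gene_id"):
        groups = [g["total_count"].to_numpy() for _, g in grp.groupby("tissue")]
        if len(groups) < 2 or sum(len(g) for g in groups) < 2:
            continue
        flat = np.concatenate(groups)
        if np.all(flat == flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*groups)
        rows.append({"gene_id": gene, "H": float(h), "p_value": float(p)})
    return pd.DataFrame(rows, columns=["gene_id", "H", "p_value"])
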