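"""End-to-end orchestration: load a cohort, run every stage, summarize, and
score results against simulated truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .ase import (
    TestConfig,
    aggregate_gene_haplotypes,
    allele_fold_change,
    filter_informative,
    gene_ase_test,
    reference_bias,
    snv_ase_test,
    tissue_enrichment,
)
from .switching import (
    call_cross_animal_switching,
    fit_bb_mixture_batch,
    call_tissue_switching,
    canonicalize_haplotypes,
    fit_bb_mixture,
    imprinting_screen,
)

__all__ = ["PipelineConfig", "load_cohort", "run_pipeline", "compare_to_truth"]


@dataclass
class PipelineConfig:
    """Every tunable of the full pipeline, with the study defaults."""

    test: TestConfig = field(default_factory=TestConfig)
    k_max: int = 3
    min_ase_snvs: int = 4
    min_ase_tissues: int = 6
    delta: float = 0.1
    min_animals_per_side: int = 2
    # random restarts per mixture fit in the cohort scan (fit_bb_mixture's
    # own default of 10 is kept for standalone fits)
    mixture_starts: int = 3
    restrict_to_ase_snvs: bool = False
    seed: int = 0


def load_cohort(
    counts_path: str | Path,
    vcf_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read counts (directory of per-sample TSVs), attach gene ids and phase."""
    counts_path = Path(counts_path)
    records = (
        io.read_counts_dir(counts_path)
        if counts_path.is_dir()
        else io.read_allele_counts(counts_path, "sample", "sample")
    )
    if genes_path is not None:
        gene_map = io.read_gene_map(genes_path)
        records = io.map_snvs_to_genes(records, gene_map)
    else:
        records["gene_id"] = None
    if vcf_path is not None:
        phase = {
            animal: io.read_phase(vcf_path, animal)
            for animal in sorted(records["animal"].unique())
        }
        records = io.attach_phase(records, phase)
    else:
        records["alt_on_hap1"] = None
        records["block_id"] = None
    return records


def _mixture_stage(
    records: pd.DataFrame,
    snv_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    gene_counts: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Fit the tissue mixture for every eligible (animal, gene) pair."""
    ase_snvs = (
        snv_results[snv_results["is_ase"]]
        .dropna(subset=["gene_id"])
        .groupby(["animal", "gene_id"])["snv_id"]
        .nunique()
    )
    ase_tissues = (
        gene_results[gene_results["is_ase"]]
        .groupby(["animal", "gene_id"])["tissue"]
        .nunique()
    )
    eligible = sorted(
        set(ase_snvs[ase_snvs >= config.min_ase_snvs].index)
        & set(ase_tissues[ase_tissues >= config.min_ase_tissues].index)
    )
    if config.restrict_to_ase_snvs:
        ase_keys = snv_results.loc[
            snv_results["is_ase"], ["animal", "gene_id", "snv_id"]
        ].drop_duplicates()
        restricted = records.merge(
            ase_keys[["animal", "snv_id"]].drop_duplicates(), on=["animal", "snv_id"]
        )
        counts_src, _ = aggregate_gene_haplotypes(restricted)
    else:
        counts_src = gene_counts

    indexed = counts_src.set_index(["animal", "gene_id"]).sort_index()
    keys: list[tuple[str, str]] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for animal, gene in eligible:
        try:
            sub = indexed.loc[(animal, gene)]
        except KeyError:
            continue
        if isinstance(sub, pd.Series):
            continue  # single tissue: no series to model
        sub = sub[sub["y"] > 0]
        if len(sub) < 2:
            continue
        keys.append((animal, gene))
        xs.append(sub["x"].to_numpy())
        ys.append(sub["y"].to_numpy())
    fits = fit_bb_mixture_batch(
        xs,
        ys,
        k_max=config.k_max,
        n_starts=config.mixture_starts,
        seed=config.seed % (2**31 - 1),
    )
    rows = []
    for (animal, gene), x, fit in zip(keys, xs, fits):
        rows.append(
            {
                "animal": animal,
                "gene_id": gene,
                "n_tissues": len(x),
                "k": fit.k,
                "alphas": list(np.round(fit.alphas, 6)),
                "weights": list(np.round(fit.weights, 6)),
                "phi": fit.phi,
                "loglik": fit.loglik,
                "lrt_trail": ";".join(
                    f"{a}->{b}:stat={s:.4g},df={d},p={p:.4g}"
                    for a, b, s, d, p in fit.lrt_trail
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal",
            "gene_id",
            "n_tissues",
            "k",
            "alphas",
            "weights",
            "phi",
            "loglik",
            "lrt_trail",
        ],
    )


def _summaries(
    filtered: pd.DataFrame,
    snv_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    n_dropped: int,
) -> pd.DataFrame:
    bias = reference_bias(filtered)
    ase_genes = gene_results[gene_results["is_ase"]]
    fold = allele_fold_change(
        ase_genes["x"].to_numpy(), (ase_genes["y"] - ase_genes["x"]).to_numpy()
    )
    gene_class = np.where(
        ~gene_results["is_ase"], "balanced", gene_results["expression_class"]
    )
    cls_counts = pd.Series(gene_class).value_counts()
    rows = [
        ("n_samples", len(filtered.groupby(["animal", "tissue"]))),
        ("n_informative_records", len(filtered)),
        ("n_subthreshold_dropped", n_dropped),
        ("n_snvs_tested", filtered["snv_id"].nunique()),
        ("n_ase_snvs", snv_results.loc[snv_results["is_ase"], "snv_id"].nunique()),
        ("n_genes_assayed", gene_results["gene_id"].nunique()),
        ("n_ase_genes", ase_genes["gene_id"].nunique()),
        ("reference_bias_median", bias["median"]),
        ("frac_ase_gene_samples_fold_ge2", float(np.mean(fold >= 2)) if len(fold) else np.nan),
        ("n_gene_samples_balanced", int(cls_counts.get("balanced", 0))),
        ("n_gene_samples_biallelic", int(cls_counts.get("biallelic", 0))),
        ("n_gene_samples_monoallelic", int(cls_counts.get("monoallelic", 0))),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


def run_pipeline(
    records: pd.DataFrame,
    tpm: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
    known_imprinted: set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run filtering, SNV/gene ASE tests, mixture fitting, switching calls,
    the imprinting screen, and summaries on one cohort's records."""
    filtered, n_dropped = filter_informative(records, config.test)
    snv_results = snv_ase_test(filtered, config.test)
    gene_counts, _ = aggregate_gene_haplotypes(filtered)
    gene_results = gene_ase_test(gene_counts, config.test)

    phase_df = (
        filtered.dropna(subset=["gene_id", "alt_on_hap1"])[
            ["gene_id", "animal", "snv_id", "pos", "alt_on_hap1"]
        ]
        .drop_duplicates(["gene_id", "animal", "snv_id"])
        .reset_index(drop=True)
    )
    canonical = canonicalize_haplotypes(phase_df)

    fits = _mixture_stage(filtered, snv_results, gene_results, gene_counts, config)
    switch_calls = call_tissue_switching(fits, delta=config.delta)
    cross_calls = call_cross_animal_switching(
        gene_results, canonical, config.min_animals_per_side
    )
    imprint = imprinting_screen(
        snv_results,
        gene_results,
        canonical,
        known_imprinted,
        min_ase_snvs=config.min_ase_snvs,
    )
    out: dict[str, pd.DataFrame] = {
        "snv_ase": snv_results,
        "gene_counts": gene_counts,
        "gene_ase": gene_results,
        "canonical_haplotypes": canonical,
        "mixture_fits": fits,
        "switch_calls": switch_calls,
        "cross_animal_calls": cross_calls,
        "imprint_candidates": imprint,
        "summaries": _summaries(filtered, snv_results, gene_results, n_dropped),
    }
    if tpm is not None:
        out["tissue_enrichment"] = tissue_enrichment(tpm)
    return out


def compare_to_truth(
    results: dict[str, pd.DataFrame],
    truth_genes: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, float]:
    """Score pipeline output against the generator's planted classes.

    Imprinting recall is computed over screenable planted genes (those with at
    least ``min_ase_snvs`` simulated SNVs); the screen cannot, by design, see
    genes with fewer phased SNVs.
    """
    cls = truth_genes.set_index("gene_id")["class"]
    planted_ase = set(cls[cls != "balanced"].index)
    detected_ase = set(results["gene_ase"].loc[results["gene_ase"]["is_ase"], "gene_id"])
    gene_ase_recall = (
        len(planted_ase & detected_ase) / len(planted_ase) if planted_ase else np.nan
    )
    balanced = set(cls[cls == "balanced"].index)
    false_ase = len(detected_ase & balanced)

    screenable = set(
        truth_genes.loc[
            (truth_genes["class"] == "monoallelic_imprinted")
            & (truth_genes["n_snvs"] >= config.min_ase_snvs),
            "gene_id",
        ]
    )
    imprint = results["imprint_candidates"]
    candidates = set(imprint["gene_id"])
    imprint_recall = (
        len(screenable & candidates) / len(screenable) if screenable else np.nan
    )
    tier2 = set(imprint.loc[imprint["tier"] == "all-sample-consistent", "gene_id"])
    tier2_false_balanced = len(tier2 & balanced)

    planted_switch = set(cls[cls == "tissue_switching"].index)
    flagged_switch = set(
        results["switch_calls"].loc[results["switch_calls"]["switching"], "gene_id"]
    )
    switch_recall = (
        len(planted_switch & flagged_switch) / len(planted_switch)
        if planted_switch
        else np.nan
    )

    planted_cross = set(cls[cls == "cross_animal_switching"].index)
    flagged_cross = set(
        results["cross_animal_calls"].loc[
            results["cross_animal_calls"]["switching"], "gene_id"
        ]
    )
    cross_recall = (
        len(planted_cross & flagged_cross) / len(planted_cross)
        if planted_cross
        else np.nan
    )

    sc = results["switch_calls"]
    consistent_fraction = float(sc["consistent"].mean()) if len(sc) else np.nan
    return {
        "gene_ase_recall": float(gene_ase_recall),
        "n_false_ase_balanced_genes": float(false_ase),
        "imprint_recall": float(imprint_recall),
        "tier2_false_positives_balanced": float(tier2_false_balanced),
        "tissue_switch_recall": float(switch_recall),
        "cross_animal_switch_recall": float(cross_recall),
        "consistent_fraction": consistent_fraction,
    }
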