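"""Synthetic multi-tissue ASE cohorts with known truth.

The generator emulates the shape of a phased bulk RNA-seq cohort: N animals x
T tissues, genes carrying phased heterozygous SNVs, and beta-binomially
dispersed allele counts.  Gene classes are planted with known parameters:

* ``balanced`` — haplotype ratio 0.5 everywhere;
* ``biallelic_ase`` — one haplotype favored (ratio drawn from the effect
  distribution) consistently across animals and tissues;
* ``monoallelic_imprinted`` — all reads from one haplotype within an animal;
  half of these genes express the same founder haplotype in every animal
  (imprinting-like), half pick the expressed haplotype per animal
  (cis-regulatory-switch-like);
* ``tissue_switching`` — the favored haplotype flips in one designated tissue;
* ``cross_animal_switching`` — half the animals favor the opposite haplotype.

Each gene has two founder haplotypes: haplotype A carries the alternate
allele at every SNV of the gene, haplotype B the reference allele.  Every
heterozygous animal carries both founders, with the local haplotype-1/2
labeling randomized per phase block, so cross-animal canonicalization is
exactly recoverable from shared alleles.  Defaults mirror the cohort the
pipeline is built for: 12 animals, 11 tissues, a median of 12 SNVs per gene,
a median of 48 reads per SNV, and dispersion 0.001.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimTruth", "Cohort", "simulate_cohort", "make_worked_fixture"]

DEFAULT_TISSUES = (
    "cerebellum",
    "heart",
    "hippocampus",
    "ileum",
    "kidney_cortex",
    "liver",
    "lung",
    "muscle",
    "pancreas",
    "spleen",
    "white_adipose",
)

CLASSES = (
    "balanced",
    "biallelic_ase",
    "monoallelic_imprinted",
    "tissue_switching",
    "cross_animal_switching",
)

_GENE_SPAN = 10_000  # genomic stride per gene on the synthetic contig
_GENE_LEN = 5_000


@dataclass
class SimConfig:
    """Cohort-shape and noise parameters of the generator."""

    n_animals: int = 12
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_genes: int = 1000
    # SNVs per gene: floor + negative binomial, median 12 at the defaults
    snv_nb_r: float = 4.0
    snv_nb_p: float = 0.25
    snv_floor: int = 1
    het_prob: float = 0.6
    # read depth per SNV-sample: negative binomial, median 48, floor 0
    depth_nb_r: float = 10.0
    depth_nb_p: float = 1.0 / 6.0
    rho: float = 0.001
    ref_bias: float = 0.5  # mean reference-read fraction shift; 0.5 = no bias
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "balanced": 0.70,
            "biallelic_ase": 0.20,
            "monoallelic_imprinted": 0.05,
            "tissue_switching": 0.03,
            "cross_animal_switching": 0.02,
        }
    )
    effect_low: float = 0.7
    effect_high: float = 0.9
    phase_block_split_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_animals < 2:
            bad.append("n_animals")
        if len(self.tissues) < 2:
            bad.append("tissues")
        if self.n_genes < 1:
            bad.append("n_genes")
        if not (0.0 <= self.het_prob <= 1.0):
            bad.append("het_prob")
        if not (0.0 <= self.rho < 1.0):
            bad.append("rho")
        if not (0.0 < self.ref_bias < 1.0):
            bad.append("ref_bias")
        if set(self.class_proportions) - set(CLASSES) or abs(
            sum(self.class_proportions.values()) - 1.0
        ) > 1e-9:
            bad.append("class_proportions")
        if not (0.0 < self.effect_low <= self.effect_high < 1.0):
            bad.append("effect_low/effect_high")
        if not (0.0 <= self.phase_block_split_prob <= 1.0):
            bad.append("phase_block_split_prob")
        if bad:
            raise ValueError(f"invalid simulation config field(s): {bad}")


@dataclass
class SimTruth:
    """Planted per-gene classes and per-animal haplotype parameters.

    ``genes``: gene_id, class, effect, switch_tissue, n_snvs.
    ``animal_gene``: gene_id, animal, per-block orientation (is founder A on
    local haplotype 1), expressed founder for imprinted genes, het-SNV count.
    """

    genes: pd.DataFrame
    animal_gene: pd.DataFrame


@dataclass
class Cohort:
    """One simulated cohort: counts, phase, gene map, TPM, and the truth."""

    records: pd.DataFrame  # allele-count rows incl. gene_id / phase columns
    phase_by_animal: dict[str, dict[str, tuple[bool, str | None]]]
    gene_map: pd.DataFrame  # 0-based half-open intervals
    tpm: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        """Serialize in the pipeline's input dialects (plus the truth)."""
        outdir = Path(outdir)
        counts_dir = outdir / "counts"
        counts_dir.mkdir(parents=True, exist_ok=True)
        cols = {
            "chrom": "contig",
            "pos": "position",
            "ref_allele": "refAllele",
            "alt_allele": "altAllele",
            "ref_count": "refCount",
            "alt_count": "altCount",
            "total_count": "totalCount",
        }
        for (animal, tissue), grp in self.records.groupby(["animal", "tissue"], sort=True):
            out = grp[list(cols)].rename(columns=cols)
            out.to_csv(counts_dir / f"{animal}__{tissue}.tsv", sep="\t", index=False)
        self._write_vcf(outdir / "phased.vcf")
        bed = self.gene_map.copy()
        bed[["chrom", "start", "end", "gene_id"]].to_csv(
            outdir / "genes.bed", sep="\t", index=False, header=False
        )
        self.tpm.to_csv(outdir / "tpm.tsv", sep="\t")
        self.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.truth.animal_gene.to_csv(
            outdir / "truth_animal_gene.tsv", sep="\t", index=False
        )
        with open(outdir / "sim_config.json", "w") as fh:
            cfg = dataclasses.asdict(self.config)
            cfg["tissues"] = list(cfg["tissues"])
            json.dump(cfg, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def _write_vcf(self, path: Path) -> None:
        animals = sorted(self.phase_by_animal)
        sites = (
            self.records[["chrom", "pos", "snv_id", "ref_allele", "alt_allele"]]
            .drop_duplicates("snv_id")
            .sort_values(["chrom", "pos"])
        )
        max_pos = int(sites["pos"].max()) + _GENE_SPAN if len(sites) else _GENE_SPAN
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID=chr1,length={max_pos}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(animals)
                + "\n"
            )
            for row in sites.itertuples(index=False):
                cells = []
                for animal in animals:
                    entry = self.phase_by_animal[animal].get(row.snv_id)
                    if entry is None:
                        cells.append("0/0:.")
                    else:
                        alt_on_hap1, block = entry
                        gt = "1|0" if alt_on_hap1 else "0|1"
                        cells.append(f"{gt}:{block if block is not None else '.'}")
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.snv_id}\t{row.ref_allele}\t"
                    f"{row.alt_allele}\t.\tPASS\t.\tGT:PS\t" + "\t".join(cells) + "\n"
                )


def _allocate_classes(n_genes: int, proportions: dict[str, float], rng) -> np.ndarray:
    """Exact class counts (largest-remainder rounding), order randomized."""
    names = [c for c in CLASSES if proportions.get(c, 0.0) > 0]
    raw = np.array([proportions[c] * n_genes for c in names])
    counts = np.floor(raw).astype(int)
    rem = n_genes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(names, counts)
    return rng.permutation(labels)


_BASES = np.array(list("ACGT"))


def simulate_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Generate one cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    A = config.n_animals
    T = len(config.tissues)
    G = config.n_genes
    animals = [f"animal{i+1:02d}" for i in range(A)]
    tissues = list(config.tissues)

    classes = _allocate_classes(G, config.class_proportions, rng)
    n_snvs = config.snv_floor + rng.negative_binomial(
        config.snv_nb_r, config.snv_nb_p, size=G
    )
    effects = rng.uniform(config.effect_low, config.effect_high, size=G)
    # which founder the gene over-expresses (coin flip per gene, so the
    # reference allele is favored as often as the alternate cohort-wide)
    favored_a = rng.random(G) < 0.5
    eff_a = np.where(favored_a, effects, 1.0 - effects)  # founder-A fraction
    switch_tissue_idx = rng.integers(0, T, size=G)
    # imprinted genes alternate between cohort-consistent (same founder in
    # every animal) and per-animal expressed founders
    imprint_idx = np.flatnonzero(classes == "monoallelic_imprinted")
    imprint_consistent = np.zeros(G, dtype=bool)
    imprint_consistent[imprint_idx[::2]] = True
    # per-animal expressed founder (A=True) for imprinted genes
    expressed_a = rng.random((G, A)) < 0.5
    expressed_a[imprint_consistent, :] = favored_a[imprint_consistent, None]
    # cross-animal switching: a fixed random half of the animals mirrored
    mirrored = np.zeros((G, A), dtype=bool)
    for g in np.flatnonzero(classes == "cross_animal_switching"):
        picked = rng.choice(A, size=A // 2, replace=False)
        mirrored[g, picked] = True

    # founder-A read fraction per gene x animal x tissue
    theta = np.full((G, A, T), 0.5)
    for g in range(G):
        cls = classes[g]
        e = eff_a[g]
        if cls == "balanced":
            continue
        if cls == "biallelic_ase":
            theta[g, :, :] = e
        elif cls == "tissue_switching":
            theta[g, :, :] = e
            theta[g, :, switch_tissue_idx[g]] = 1.0 - e
        elif cls == "cross_animal_switching":
            theta[g, :, :] = e
            theta[g, mirrored[g], :] = 1.0 - e
        elif cls == "monoallelic_imprinted":
            theta[g, :, :] = np.where(expressed_a[g], 1.0, 0.0)[:, None]

    # reference bias: shift the mean reference fraction on the logit scale
    if config.ref_bias != 0.5:
        bias_logit = math.log(config.ref_bias / (1.0 - config.ref_bias))
        interior = (theta > 0) & (theta < 1)
        ref_frac = 1.0 - theta[interior]
        shifted = 1.0 / (1.0 + np.exp(-(np.log(ref_frac / (1 - ref_frac)) + bias_logit)))
        theta[interior] = 1.0 - shifted

    # SNV positions and alleles
    gene_of_snv = np.repeat(np.arange(G), n_snvs)
    positions = np.concatenate(
        [
            g * _GENE_SPAN + 1 + np.sort(rng.choice(_GENE_LEN, size=k, replace=False))
            for g, k in enumerate(n_snvs)
        ]
    )
    S = len(gene_of_snv)
    ref_idx = rng.integers(0, 4, size=S)
    alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
    ref_alleles = _BASES[ref_idx]
    alt_alleles = _BASES[alt_idx]
    snv_ids = np.array([f"chr1:{p}" for p in positions])
    gene_ids = np.array([f"gene{g:04d}" for g in range(G)])

    # heterozygosity and phase blocks
    het = rng.random((S, A)) < config.het_prob
    split_gene = rng.random(G) < config.phase_block_split_prob
    split_at = np.array(
        [rng.integers(1, k) if (split_gene[g] and k > 1) else 0 for g, k in enumerate(n_snvs)]
    )
    snv_rank = np.concatenate([np.arange(k) for k in n_snvs])
    block_idx = np.where(
        (split_at[gene_of_snv] > 0) & (snv_rank >= split_at[gene_of_snv]), 2, 1
    )
    block_ids = gene_of_snv * 10 + block_idx
    # founder-A on local haplotype 1, chosen per animal x gene x block
    a_on_hap1_block = rng.random((G, A, 2)) < 0.5
    alt_on_hap1 = a_on_hap1_block[gene_of_snv, :, block_idx - 1]  # (S, A)

    # flatten het (snv, animal) pairs, cross with tissues
    snv_i, animal_i = np.nonzero(het)
    M = len(snv_i)
    snv_rep = np.repeat(snv_i, T)
    animal_rep = np.repeat(animal_i, T)
    tissue_rep = np.tile(np.arange(T), M)
    depth = rng.negative_binomial(config.depth_nb_r, config.depth_nb_p, size=M * T)
    th = theta[gene_of_snv[snv_rep], animal_rep, tissue_rep]
    alt_count = np.empty(M * T, dtype=np.int64)
    fixed = (th == 0.0) | (th == 1.0)
    alt_count[fixed] = (depth[fixed] * th[fixed]).astype(np.int64)
    free = ~fixed
    if free.any():
        if config.rho == 0.0:
            alt_count[free] = rng.binomial(depth[free], th[free])
        else:
            c = (1.0 - config.rho) / config.rho
            p = rng.beta(th[free] * c, (1.0 - th[free]) * c)
            alt_count[free] = rng.binomial(depth[free], p)
    ref_count = depth - alt_count

    records = pd.DataFrame(
        {
            "animal": np.array(animals)[animal_rep],
            "tissue": np.array(tissues)[tissue_rep],
            "chrom": "chr1",
            "pos": positions[snv_rep],
            "snv_id": snv_ids[snv_rep],
            "ref_allele": ref_alleles[snv_rep],
            "alt_allele": alt_alleles[snv_rep],
            "ref_count": ref_count,
            "alt_count": alt_count,
            "total_count": depth,
            "gene_id": gene_ids[gene_of_snv[snv_rep]],
            "alt_on_hap1": alt_on_hap1[snv_rep, animal_rep].astype(object),
            "block_id": np.array([str(b) for b in block_ids])[snv_rep],
        }
    )
    records = records.sort_values(["animal", "tissue", "pos"], kind="stable").reset_index(
        drop=True
    )

    phase_by_animal: dict[str, dict[str, tuple[bool, str | None]]] = {
        a: {} for a in animals
    }
    for s, a in zip(snv_i, animal_i):
        phase_by_animal[animals[a]][snv_ids[s]] = (
            bool(alt_on_hap1[s, a]),
            str(block_ids[s]),
        )

    gene_map = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(G) * _GENE_SPAN,
            "end": np.arange(G) * _GENE_SPAN + _GENE_LEN,
            "gene_id": gene_ids,
        }
    )

    # TPM: lognormal gene baseline with mild per-sample noise
    base = rng.lognormal(mean=math.log(20.0), sigma=1.2, size=G)
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(G, A * T))
    sample_keys = [f"{a}:{t}" for a in animals for t in tissues]
    tpm = pd.DataFrame(base[:, None] * noise, index=gene_ids, columns=sample_keys)
    tpm.index.name = "gene_id"

    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "effect": np.where(classes == "balanced", 0.5, eff_a),
            "switch_tissue": np.where(
                classes == "tissue_switching",
                np.array(tissues)[switch_tissue_idx],
                "",
            ),
            "n_snvs": n_snvs,
        }
    )
    ag_rows = []
    for g in range(G):
        snvs_g = np.flatnonzero(gene_of_snv == g)
        for a in range(A):
            n_het = int(het[snvs_g, a].sum())
            if n_het == 0:
                continue
            ag_rows.append(
                {
                    "gene_id": gene_ids[g],
                    "animal": animals[a],
                    "a_on_hap1": bool(a_on_hap1_block[g, a, 0]),
                    "expressed_founder": (
                        ("A" if expressed_a[g, a] else "B")
                        if classes[g] == "monoallelic_imprinted"
                        else ""
                    ),
                    "n_het_snvs": n_het,
                }
            )
    truth_animal_gene = pd.DataFrame(
        ag_rows, columns=["gene_id", "animal", "a_on_hap1", "expressed_founder", "n_het_snvs"]
    )

    return Cohort(
        records=records,
        phase_by_animal=phase_by_animal,
        gene_map=gene_map,
        tpm=tpm,
        truth=SimTruth(genes=truth_genes, animal_gene=truth_animal_gene),
        config=config,
    )


# ---------------------------------------------------------------------------
# worked fixture
# ---------------------------------------------------------------------------

def make_worked_fixture() -> Cohort:
    """Tiny deterministic dataset exercising every pipeline branch.

    2 animals x 3 tissues x 5 genes with hand-chosen counts: a balanced gene,
    a strongly imbalanced gene, a monoallelic gene, a gene whose favored
    haplotype flips in one tissue, and a gene carrying an unphased SNV plus
    exactly four sub-threshold (< 10 reads) observations.
    """
    animals = ["A1", "A2"]
    tissues = ["kidney", "liver", "spleen"]
    gene_ids = [f"g{i}" for i in range(1, 6)]
    # gene g: positions g*10000+1 + offsets
    snv_pos = {
        "g1": [1, 401, 801],
        "g2": [1, 301, 601, 901],
        "g3": [1, 501, 1001, 1501],
        "g4": [1, 201, 401, 601],
        "g5": [1, 701],
    }
    # alt_on_hap1 per animal per gene (single block; g5's 2nd SNV unphased)
    a_on_hap1 = {("A1", g): True for g in gene_ids} | {("A2", g): False for g in gene_ids}
    # per gene/tissue (ref, alt) count template applied to every SNV
    # ref corresponds to founder B (hap carrying ref everywhere)
    tmpl: dict[tuple[str, str], tuple[int, int]] = {}
    for t in tissues:
        tmpl[("g1", t)] = (21, 19)  # balanced
        tmpl[("g2", t)] = (9, 36)  # strong ASE toward alt
        tmpl[("g3", t)] = (0, 37)  # monoallelic alt
        tmpl[("g4", t)] = (8, 40)  # favored alt ...
    tmpl[("g4", "kidney")] = (40, 8)  # ... flipped in kidney
    for t in tissues:
        tmpl[("g5", t)] = (15, 14)
    # four sub-threshold rows: g5 first SNV in A2, all three tissues (+1 extra)
    sub = {("A2", t, "g5", 0): (4, 3) for t in tissues}
    sub[("A1", "spleen", "g5", 1)] = (5, 2)

    rows = []
    for animal in animals:
        for tissue in tissues:
            for g in gene_ids:
                for j, off in enumerate(snv_pos[g]):
                    pos = (gene_ids.index(g) + 1) * 10_000 + off
                    ref, alt = sub.get((animal, tissue, g, j), tmpl[(g, tissue)])
                    # vary counts slightly by SNV index for realism (never
                    # disturbing a monoallelic zero)
                    if (animal, tissue, g, j) not in sub and j % 2 == 1 and ref > 0:
                        ref, alt = ref + 1, alt + 1
                    rows.append(
                        {
                            "animal": animal,
                            "tissue": tissue,
                            "chrom": "chr1",
                            "pos": pos,
                            "snv_id": f"chr1:{pos}",
                            "ref_allele": "A",
                            "alt_allele": "G",
                            "ref_count": ref,
                            "alt_count": alt,
                            "total_count": ref + alt,
                            "gene_id": g,
                        }
                    )
    records = pd.DataFrame(rows)

    phase_by_animal: dict[str, dict[str, tuple[bool, str | None]]] = {
        a: {} for a in animals
    }
    for g in gene_ids:
        for j, off in enumerate(snv_pos[g]):
            pos = (gene_ids.index(g) + 1) * 10_000 + off
            if g == "g5" and j == 1:
                continue  # unphased SNV
            block = str((gene_ids.index(g) + 1) * 10)
            for animal in animals:
                alt_on_h1 = a_on_hap1[(animal, g)]
                phase_by_animal[animal][f"chr1:{pos}"] = (alt_on_h1, block)

    alt_col: list[object] = []
    block_col: list[object] = []
    for rec in records.itertuples(index=False):
        entry = phase_by_animal[rec.animal].get(rec.snv_id)
        alt_col.append(None if entry is None else entry[0])
        block_col.append(None if entry is None else entry[1])
    records["alt_on_hap1"] = alt_col
    records["block_id"] = block_col

    gene_map = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [(i + 1) * 10_000 for i in range(5)],
            "end": [(i + 1) * 10_000 + 5_000 for i in range(5)],
            "gene_id": gene_ids,
        }
    )
    sample_keys = [f"{a}:{t}" for a in animals for t in tissues]
    tpm_vals = {
        "g1": 50.0,
        "g2": 200.0,
        "g3": 5.0,
        "g4": 30.0,
        "g5": 1200.0,
    }
    tpm = pd.DataFrame(
        {k: [tpm_vals[g] for g in gene_ids] for k in sample_keys}, index=gene_ids
    )
    tpm.index.name = "gene_id"

    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": [
                "balanced",
                "biallelic_ase",
                "monoallelic_imprinted",
                "tissue_switching",
                "balanced",
            ],
            "effect": [0.5, 0.8, 1.0, 0.83, 0.5],
            "switch_tissue": ["", "", "", "kidney", ""],
            "n_snvs": [len(snv_pos[g]) for g in gene_ids],
        }
    )
    ag_rows = []
    for g in gene_ids:
        for animal in animals:
            ag_rows.append(
                {
                    "gene_id": g,
                    "animal": animal,
                    "a_on_hap1": a_on_hap1[(animal, g)],
                    "expressed_founder": "A" if g == "g3" else "",
                    "n_het_snvs": len(snv_pos[g]),
                }
            )
    truth_animal_gene = pd.DataFrame(ag_rows)

    return Cohort(
        records=records,
        phase_by_animal=phase_by_animal,
        gene_map=gene_map,
        tpm=tpm,
        truth=SimTruth(genes=truth_genes, animal_gene=truth_animal_gene),
        config=SimConfig(
            n_animals=2,
            tissues=tuple(tissues),
            n_genes=5,
            class_proportions={"balanced": 1.0},
            seed=0,
        ),
    )
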