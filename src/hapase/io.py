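"""Readers and writers for the file formats the pipeline touches.

Formats:

* allele counts — GATK-ASEReadCounter-style TSV (``contig``, ``position``,
  ``refAllele``, ``altAllele``, ``refCount``, ``altCount``, ``totalCount``);
* phased genotypes — VCF 4.x with ``GT`` (``|``-separated when phased) and an
  optional ``PS`` haplotype-block tag, read through pysam;
* SNV-to-gene map — BED (0-based, half-open) or TSV (1-based, inclusive);
* TPM matrix — genes x samples TSV with ``animal:tissue`` column keys.

Coordinate conventions follow the respective format standards.  Result tables
are plain single-header TSV written at full float precision so that a
write/read round trip is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_allele_counts",
    "read_counts_dir",
    "read_phase",
    "read_gene_map",
    "map_snvs_to_genes",
    "read_tpm",
    "write_table",
    "read_table",
]

#: canonical column order of the in-memory allele-count record table
RECORD_COLUMNS = [
    "animal",
    "tissue",
    "chrom",
    "pos",
    "snv_id",
    "ref_allele",
    "alt_allele",
    "ref_count",
    "alt_count",
    "total_count",
]

_REQUIRED_COUNT_COLUMNS = [
    "contig",
    "position",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
]


class FormatError(ValueError):
    """An input file violates its format contract."""


def read_allele_counts(path: str | Path, animal: str, tissue: str) -> pd.DataFrame:
    """Read one sample's ASEReadCounter-style allele-count table.

    ``totalCount`` is recomputed as ``refCount + altCount`` (other-allele reads
    are outside the biallelic analysis); a mismatch is logged.  Rows whose
    ref/alt alleles are not single distinct bases are dropped with a logged
    count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in _REQUIRED_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    ref = df["refAllele"].astype(str)
    alt = df["altAllele"].astype(str)
    is_snv = (ref.str.len() == 1) & (alt.str.len() == 1) & (ref != alt)
    n_dropped = int((~is_snv).sum())
    if n_dropped:
        logger.info("%s: dropped %d non-biallelic-SNV row(s)", path, n_dropped)
    df = df[is_snv].copy()
    total = df["refCount"] + df["altCount"]
    n_mismatch = int((total != df["totalCount"]).sum())
    if n_mismatch:
        logger.warning(
            "%s: %d row(s) had totalCount != refCount + altCount; repaired to the sum",
            path,
            n_mismatch,
        )
    out = pd.DataFrame(
        {
            "animal": animal,
            "tissue": tissue,
            "chrom": df["contig"].astype(str),
            "pos": df["position"].astype(np.int64),
            "ref_allele": ref[is_snv],
            "alt_allele": alt[is_snv],
            "ref_count": df["refCount"].astype(np.int64),
            "alt_count": df["altCount"].astype(np.int64),
            "total_count": total.astype(np.int64),
        }
    )
    out["snv_id"] = out["chrom"] + ":" + out["pos"].astype(str)
    return out[RECORD_COLUMNS].reset_index(drop=True)


def read_counts_dir(path: str | Path) -> pd.DataFrame:
    """Read a directory of per-sample count tables named ``<animal>__<tissue>.tsv``."""
    path = Path(path)
    frames = []
    for f in sorted(path.glob("*.tsv")):
        stem = f.stem
        if "__" not in stem:
            raise FormatError(
                f"{f}: sample file names must be '<animal>__<tissue>.tsv'"
            )
        animal, tissue = stem.split("__", 1)
        frames.append(read_allele_counts(f, animal, tissue))
    if not frames:
        raise FormatError(f"{path}: no *.tsv count files found")
    return pd.concat(frames, ignore_index=True)


def read_phase(
    vcf_path: str | Path, animal: str
) -> dict[str, tuple[bool, str | None]]:
    """Phase of one animal: map ``snv_id -> (alt_on_hap1, block_id)``.

    Only heterozygous, phased, biallelic SNV records are returned.  GT ``0|1``
    means the alternate allele sits on haplotype 2 (``alt_on_hap1 = False``);
    ``1|0`` means haplotype 1.  Unphased heterozygotes and homozygotes are
    excluded (counts logged).  ``block_id`` is the ``PS`` value when present.
    """
    phase: dict[str, tuple[bool, str | None]] = {}
    n_unphased = 0
    n_nonhet = 0
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{vcf_path}: cannot parse VCF ({exc})") from exc
    with vcf:
        if animal not in list(vcf.header.samples):
            raise FormatError(f"{vcf_path}: sample {animal!r} not in VCF header")
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            sample = rec.samples[animal]
            gt = sample.get("GT")
            if gt is None or None in gt or len(gt) != 2:
                continue
            if gt[0] == gt[1]:
                n_nonhet += 1
                continue
            if not sample.phased:
                n_unphased += 1
                continue
            ps = sample.get("PS")
            block_id = str(ps) if ps is not None else None
            snv_id = f"{rec.chrom}:{rec.pos}"
            phase[snv_id] = (gt[0] == 1, block_id)
    if n_unphased:
        logger.info("%s/%s: excluded %d unphased heterozygote(s)", vcf_path, animal, n_unphased)
    if n_nonhet:
        logger.debug("%s/%s: skipped %d homozygous record(s)", vcf_path, animal, n_nonhet)
    return phase


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED or TSV into 0-based half-open form.

    BED: ``chrom  start  end  gene_id`` (0-based half-open, no header).
    TSV: header ``gene_id  chrom  start  end`` (1-based inclusive).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "gene_id": str},
        )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(df.columns):
            raise FormatError(f"{path}: gene TSV must have columns {sorted(need)}")
        df = df[["chrom", "start", "end", "gene_id"]].copy()
        # 1-based inclusive -> 0-based half-open
        df["start"] = df["start"] - 1
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise FormatError(
            f"{path}: interval with start > end for gene {bad['gene_id']!r}"
        )
    return df.reset_index(drop=True)


def map_snvs_to_genes(sites: pd.DataFrame, gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Assign ``gene_id`` to sites by interval overlap.

    ``gene_intervals`` is 0-based half-open (see :func:`read_gene_map`).  A
    site inside several overlapping genes is duplicated, one row per gene,
    flagged ``ambiguous``; intergenic sites keep ``gene_id`` = NaN.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in gene_intervals.groupby("chrom"):
        tree = IntervalTree()
        for _, row in grp.iterrows():
            if row["end"] > row["start"]:
                tree.addi(int(row["start"]), int(row["end"]), str(row["gene_id"]))
        trees[str(chrom)] = tree

    gene_col: list[str | None] = []
    ambiguous: list[bool] = []
    idx: list[int] = []
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        tree = trees.get(str(chrom))
        # 1-based pos -> 0-based point query
        hits = sorted(iv.data for iv in tree[int(pos) - 1]) if tree is not None else []
        if not hits:
            idx.append(i)
            gene_col.append(None)
            ambiguous.append(False)
        else:
            for g in hits:
                idx.append(i)
                gene_col.append(g)
                ambiguous.append(len(hits) > 1)
    out = sites.iloc[idx].copy().reset_index(drop=True)
    out["gene_id"] = gene_col
    out["ambiguous"] = ambiguous
    return out


def read_tpm(path: str | Path) -> pd.DataFrame:
    """TPM matrix: rows = genes, columns = ``animal:tissue`` sample keys."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: TPM matrix contains negative entries")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample columns in TPM matrix")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as single-header TSV at full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def attach_phase(
    records: pd.DataFrame, phase_by_animal: Mapping[str, Mapping[str, tuple[bool, str | None]]]
) -> pd.DataFrame:
    """Join per-animal phase onto the record table.

    Adds ``alt_on_hap1`` (nullable boolean) and ``block_id``; records without
    phase keep NA and are excluded later by haplotype aggregation.
    """
    alt_on_hap1 = np.full(len(records), np.nan, dtype=object)
    block = np.full(len(records), None, dtype=object)
    for i, (animal, snv) in enumerate(zip(records["animal"], records["snv_id"])):
        entry = phase_by_animal.get(animal, {}).get(snv)
        if entry is not None:
            alt_on_hap1[i] = bool(entry[0])
            block[i] = entry[1]
    out = records.copy()
    out["alt_on_hap1"] = alt_on_hap1
    out["block_id"] = block
    return out
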