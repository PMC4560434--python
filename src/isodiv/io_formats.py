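"""Readers and writers for the formats the pipeline touches.

All genomic coordinates inside the package are 0-based half-open intervals;
GTF on disk is 1-based inclusive. The conversion happens here and nowhere
else, so every downstream module can compare and overlap intervals without
worrying about conventions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils.feature
import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "SampleMeta",
    "ExpressionTable",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_expression_table",
    "write_expression_table",
    "read_variants",
    "write_variants_vcf",
    "read_config",
]


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-interval structure of one isoform.

    Exons are 0-based half-open genomic intervals, sorted ascending by start
    and non-overlapping. Biological 5'/3' orientation is derived from
    ``strand``, never from exon order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    """All transcripts of a gene plus the count of known strain variants."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    snv_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if self.snv_count < 0:
            raise ValueError("snv_count must be non-negative")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"{self.gene_id}: transcripts on multiple chroms")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} has gene_id {t.gene_id}, "
                    f"expected {self.gene_id}"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def transcript_ids(self) -> tuple[str, ...]:
        return tuple(t.transcript_id for t in self.transcripts)


_GROUPS = ("F0_BL6", "F0_CAST", "F1")
_ALLELES = ("BL6", "CAST", "NA")


@dataclass(frozen=True)
class SampleMeta:
    """One expression column: F0 strain replicate or one F1 allele column."""

    sample_id: str
    group: str
    allele: str
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.allele not in _ALLELES:
            raise ValueError(f"unknown allele {self.allele!r}")
        if (self.group == "F1") != (self.allele != "NA"):
            raise ValueError(
                f"{self.sample_id}: allele must be BL6/CAST iff group is F1"
            )


class ExpressionTable:
    """Transcript x sample expression estimates with standard errors.

    `estimates` and `se` are aligned DataFrames (rows: transcript ids,
    columns: sample ids); `unique_reads` is a per-transcript Series playing
    the role of the number of reads mapping uniquely to each isoform, which
    governs estimate reliability. F1 replicates appear as paired BL6/CAST
    allele columns sharing a replicate index.
    """

    def __init__(
        self,
        estimates: pd.DataFrame,
        se: pd.DataFrame,
        unique_reads: pd.Series,
        samples: Sequence[SampleMeta],
    ) -> None:
        estimates = estimates.astype(float)
        se = se.astype(float)
        if estimates.shape != se.shape or not estimates.columns.equals(se.columns):
            raise ValueError("estimates and se must have identical layout")
        if not estimates.index.equals(se.index):
            raise ValueError("estimates and se must share transcript index")
        if (estimates.to_numpy() < 0).any():
            raise ValueError("negative expression estimate")
        if not np.isfinite(se.to_numpy()).all() or (se.to_numpy() < 0).any():
            raise ValueError("se must be finite and non-negative")
        sample_ids = [s.sample_id for s in samples]
        if sorted(sample_ids) != sorted(estimates.columns):
            raise ValueError("sample metadata does not match table columns")
        missing = set(estimates.index) - set(unique_reads.index)
        if missing:
            raise ValueError(f"unique_reads missing for {sorted(missing)[:3]}...")
        estimates.index.name = "transcript_id"
        se.index.name = "transcript_id"
        self.estimates = estimates
        self.se = se
        self.unique_reads = unique_reads.reindex(estimates.index).astype(int)
        self.samples = tuple(samples)
        self._by_id = {s.sample_id: s for s in self.samples}

    # -- column selections -------------------------------------------------
    def columns_for(self, group: str, allele: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.group == group and (allele is None or s.allele == allele)
        ]

    def f1_pairs(self) -> list[tuple[str, str]]:
        """(BL6-allele column, CAST-allele column) per F1 replicate."""
        by_rep: dict[int, dict[str, str]] = {}
        for s in self.samples:
            if s.group == "F1":
                by_rep.setdefault(s.replicate, {})[s.allele] = s.sample_id
        pairs = []
        for rep in sorted(by_rep):
            d = by_rep[rep]
            if set(d) != {"BL6", "CAST"}:
                raise ValueError(f"F1 replicate {rep} lacks a paired allele column")
            pairs.append((d["BL6"], d["CAST"]))
        return pairs

    def meta(self, sample_id: str) -> SampleMeta:
        return self._by_id[sample_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.estimates.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.estimates.shape


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon features from an Ensembl-dialect GTF into GeneModels.

    On-disk coordinates (1-based inclusive) are converted to the package's
    0-based half-open convention. Transcripts are grouped by gene_id; exons
    are stored ascending by genomic start regardless of strand.
    """
    exons: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises bare ValueError/etc.
                raise GtfParseError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat["transcript_id"][0]
                gid = feat["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon lacks {exc} attribute"
                ) from exc
            rec = exons.setdefault(
                tid,
                {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
                 "exons": []},
            )
            # GTF 1-based inclusive -> 0-based half-open
            rec["exons"].append((feat.start - 1, feat.end))
            if tid not in order:
                order.append(tid)

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        rec = exons[tid]
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        if t.gene_id not in genes:
            gene_order.append(t.gene_id)
        genes.setdefault(t.gene_id, []).append(t)
    return [GeneModel(gene_id=g, transcripts=tuple(genes[g])) for g in gene_order]


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write exon features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                for start, end in t.exons:
                    attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(
                        "\t".join(
                            [t.chrom, "isodiv", "exon", str(start + 1), str(end),
                             ".", t.strand, ".", attrs]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, meta_path: str | Path) -> ExpressionTable:
    """Read a transcript x sample TSV plus its sample-metadata sidecar.

    The data TSV has one row per transcript with estimate columns named
    ``<sample_id>``, matching se columns named ``<sample_id>.se``, and a
    ``unique_reads`` column. The metadata TSV maps sample_id to
    (group, allele, replicate).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(
        meta_path, sep="\t", dtype={"replicate": int}, keep_default_na=False
    )
    required = {"sample_id", "group", "allele", "replicate"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    samples = [
        SampleMeta(r.sample_id, r.group, str(r.allele), int(r.replicate))
        for r in meta.itertuples()
    ]
    sample_ids = [s.sample_id for s in samples]
    if "unique_reads" not in df.columns:
        raise ValueError("expression table lacks a unique_reads column")
    se_cols = [f"{sid}.se" for sid in sample_ids]
    missing_est = [sid for sid in sample_ids if sid not in df.columns]
    missing_se = [c for c in se_cols if c not in df.columns]
    if missing_est:
        raise ValueError(f"columns missing from table: {missing_est}")
    if missing_se:
        raise ValueError(f"standard-error columns missing: {missing_se}")
    extra = set(df.columns) - set(sample_ids) - set(se_cols) - {"unique_reads"}
    if extra:
        raise ValueError(f"columns absent from metadata: {sorted(extra)}")
    est = df[sample_ids]
    se = df[se_cols]
    se.columns = sample_ids
    return ExpressionTable(est, se, df["unique_reads"], samples)


def write_expression_table(
    table: ExpressionTable, path: str | Path, meta_path: str | Path
) -> None:
    out = table.estimates.copy()
    for sid in table.estimates.columns:
        out[f"{sid}.se"] = table.se[sid]
    out["unique_reads"] = table.unique_reads
    out.to_csv(path, sep="\t", index_label="transcript_id")
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "group": s.group, "allele": s.allele,
             "replicate": s.replicate}
            for s in table.samples
        ]
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def read_variants(
    path: str | Path, genes: Sequence[GeneModel] | None = None
) -> dict[str, int]:
    """Count known strain variants (SNVs and indels alike) per gene.

    Accepts either a 2-column TSV (gene_id, count) or a VCF, in which case
    ``genes`` is required and each variant is assigned to every gene whose
    genomic span (introns included) it overlaps. Every annotated gene gets an
    entry, defaulting to 0.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    if genes is not None:
        counts = {g.gene_id: 0 for g in genes}
    if path.suffix.lower() in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        if genes is None:
            raise ValueError("VCF mode requires gene models for overlap assignment")
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        known_chroms = set(by_chrom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vf = pysam.VariantFile(str(path))
            for rec in vf:
                if rec.chrom not in known_chroms:
                    logger.warning(
                        "variant at %s:%d on unknown chrom, skipped", rec.chrom, rec.pos
                    )
                    continue
                pos0 = rec.pos - 1  # VCF is 1-based
                for g in by_chrom[rec.chrom]:
                    s, e = g.span
                    if s <= pos0 < e:
                        counts[g.gene_id] += 1
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "count"],
                         comment="#")
        for r in df.itertuples():
            counts[str(r.gene_id)] = int(r.count)
        if genes is not None:
            for g in genes:
                counts.setdefault(g.gene_id, 0)
    return counts


def write_variants_vcf(
    variants: Mapping[str, Sequence[tuple[str, int]]], path: str | Path
) -> None:
    """Write a minimal sites-only VCF; ``variants`` maps gene_id to a list of
    (chrom, pos0) positions (0-based, converted to 1-based on disk)."""
    records = []
    for gene_id, sites in variants.items():
        for chrom, pos0 in sites:
            records.append((chrom, pos0 + 1, gene_id))
    records.sort()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({r[0] for r in records}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, gene_id in records:
            fh.write(f"{chrom}\t{pos}\t{gene_id}\tA\tG\t.\t.\t.\n")


def read_config(path: str | Path) -> dict:
    """Read a JSON run-configuration file."""
    with open(path) as fh:
        return json.load(fh)
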