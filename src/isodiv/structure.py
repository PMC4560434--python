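"""Strand-aware classification of structural differences between two isoforms.

A pair of overlapping isoforms is described by five boolean categories:

AFE  alternative first exon        — first exons do not overlap
TSS  alternative transcription start site
                                   — first exons overlap, 5' ends differ
ALE  alternative last exon         — last exons do not overlap
APA  alternative polyadenylation   — last exons overlap, 3' ends differ
INT  internal splicing difference  — private exons or shifted splice-site
                                     boundaries not attributable to the
                                     terminal categories above

AFE/TSS are mutually exclusive by construction, as are ALE/APA: each pair of
terminal exons either overlaps or it does not.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io_formats import TranscriptModel

__all__ = [
    "StructuralDiff",
    "FLAG_NAMES",
    "first_last_exons",
    "transcripts_overlap",
    "classify_pair",
    "combination_matrix",
]

FLAG_NAMES = ("AFE", "TSS", "INT", "ALE", "APA")


@dataclass(frozen=True)
class StructuralDiff:
    """Flag set for one isoform pair."""

    gene_id: str
    AFE: bool = False
    TSS: bool = False
    INT: bool = False
    ALE: bool = False
    APA: bool = False
    overlapping: bool = True

    def __post_init__(self) -> None:
        if self.AFE and self.TSS:
            raise ValueError("AFE and TSS are mutually exclusive")
        if self.ALE and self.APA:
            raise ValueError("ALE and APA are mutually exclusive")
        if not self.overlapping and self.flag_set:
            raise ValueError("non-overlapping pairs carry no flags")

    @property
    def flag_set(self) -> frozenset[str]:
        return frozenset(n for n in FLAG_NAMES if getattr(self, n))

    @property
    def n_changes(self) -> int:
        return len(self.flag_set)


def first_last_exons(
    t: TranscriptModel,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Biological (first, last) exon. On the minus strand the first exon is
    the genomically rightmost one."""
    if t.strand == "+":
        return t.exons[0], t.exons[-1]
    return t.exons[-1], t.exons[0]


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def transcripts_overlap(t1: TranscriptModel, t2: TranscriptModel) -> bool:
    """True iff the two transcripts share at least one exonic base.

    Span overlap is not enough: a transcript nested entirely inside another's
    intron does not overlap. Raises if the transcripts are not on the same
    chromosome and strand (they are not a comparable isoform pair).
    """
    if t1.chrom != t2.chrom or t1.strand != t2.strand:
        raise ValueError(
            f"{t1.transcript_id}/{t2.transcript_id}: not on the same "
            "chromosome and strand"
        )
    i = j = 0
    while i < len(t1.exons) and j < len(t2.exons):
        a, b = t1.exons[i], t2.exons[j]
        if _intervals_overlap(a, b):
            return True
        if a[1] <= b[0]:
            i += 1
        else:
            j += 1
    return False


def _five_prime(exon: tuple[int, int], strand: str) -> int:
    return exon[0] if strand == "+" else exon[1]


def _three_prime(exon: tuple[int, int], strand: str) -> int:
    return exon[1] if strand == "+" else exon[0]


def _splice_boundaries(
    t: TranscriptModel, drop_first: bool, drop_last: bool
) -> frozenset[int]:
    """Exon boundary coordinates that count as splice evidence.

    Transcript termini (5' end of the first exon, 3' end of the last exon)
    are never splice sites and are always excluded. When the pair is AFE
    (resp. ALE) the first (resp. last) exons differ wholesale and both their
    boundaries are excluded, so the difference is attributed once.
    """
    first, last = first_last_exons(t)
    strand = t.strand
    pts: set[int] = set()
    for exon in t.exons:
        for point in exon:
            pts.add(point)
    # terminal ends are not splice junctions
    pts.discard(_five_prime(first, strand))
    pts.discard(_three_prime(last, strand))
    if drop_first:
        pts.discard(first[0])
        pts.discard(first[1])
    if drop_last:
        pts.discard(last[0])
        pts.discard(last[1])
    return frozenset(pts)


def classify_pair(t1: TranscriptModel, t2: TranscriptModel) -> StructuralDiff:
    """Classify the structural differences between two overlapping isoforms.

    The terminal rules compare first exons to first exons and last exons to
    last exons, strand-aware. INT is set when the transcripts' splice-site
    boundary sets differ after excluding terminal ends and, when AFE/ALE is
    set, the whole corresponding terminal exon — so a difference is never
    double-counted between a terminal category and INT.
    """
    if not transcripts_overlap(t1, t2):
        raise ValueError(
            f"{t1.transcript_id}/{t2.transcript_id} do not overlap; "
            "call transcripts_overlap first"
        )
    strand = t1.strand
    f1, l1 = first_last_exons(t1)
    f2, l2 = first_last_exons(t2)

    afe = not _intervals_overlap(f1, f2)
    tss = (not afe) and _five_prime(f1, strand) != _five_prime(f2, strand)
    ale = not _intervals_overlap(l1, l2)
    apa = (not ale) and _three_prime(l1, strand) != _three_prime(l2, strand)

    b1 = _splice_boundaries(t1, drop_first=afe, drop_last=ale)
    b2 = _splice_boundaries(t2, drop_first=afe, drop_last=ale)
    internal = b1 != b2

    gene = t1.gene_id if t1.gene_id == t2.gene_id else f"{t1.gene_id}|{t2.gene_id}"
    return StructuralDiff(
        gene_id=gene, AFE=afe, TSS=tss, INT=internal, ALE=ale, APA=apa
    )


def combination_matrix(diffs: list[StructuralDiff]) -> dict:
    """Count flag combinations across a cohort of classified pairs.

    Returns combination counts, totals of genes by number of changes, the
    total number of discrete structural differences, and each category's
    share of that total.
    """
    combos: Counter[frozenset[str]] = Counter()
    per_count: Counter[int] = Counter()
    flag_totals: Counter[str] = Counter()
    for d in diffs:
        combos[d.flag_set] += 1
        per_count[d.n_changes] += 1
        for f in d.flag_set:
            flag_totals[f] += 1
    total_changes = sum(flag_totals.values())
    shares = {
        f: (flag_totals[f] / total_changes if total_changes else 0.0)
        for f in FLAG_NAMES
    }
    return {
        "combinations": dict(combos),
        "genes_by_n_changes": {k: per_count.get(k, 0) for k in range(6)},
        "total_changes": total_changes,
        "flag_counts": {f: flag_totals.get(f, 0) for f in FLAG_NAMES},
        "flag_shares": shares,
    }


def combination_matrix_frame(diffs: list[StructuralDiff]) -> pd.DataFrame:
    """Tabular view of the combination counts (one row per combination)."""
    summary = combination_matrix(diffs)
    rows = []
    for combo, n in sorted(
        summary["combinations"].items(), key=lambda kv: (-kv[1], sorted(kv[0]))
    ):
        row = {f: f in combo for f in FLAG_NAMES}
        row["n_changes"] = len(combo)
        row["n_genes"] = n
        rows.append(row)
    return pd.DataFrame(rows, columns=[*FLAG_NAMES, "n_changes", "n_genes"])
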