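"""Gene-selection funnel: expression thresholding, expressed-isoform
calling, the exactly-two-overlapping-isoform rule, and uncertainty-based
subsetting.

The funnel reproduces a selection designed for allele-specific isoform
analysis: a detection threshold t anchored to read-level evidence, a
replicate-consistency rule for calling a transcript expressed, and a
restriction to heterozygous genes expressing exactly two overlapping
isoforms, which isolates a single regulatory change per locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, GeneModel
from .structure import transcripts_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FunnelReport",
    "compute_expression_threshold",
    "call_expressed",
    "select_analysis_set",
    "mcse_subset",
]


@dataclass(frozen=True)
class FilterConfig:
    """min_unique_reads_for_threshold anchors the detection threshold t;
    min_replicates is the per-group consistency requirement; mcse_mode
    optionally subsets transcripts by estimate uncertainty."""

    min_unique_reads_for_threshold: int = 10
    min_replicates: int = 4
    mcse_mode: str = "off"  # off | t1 | t5

    def __post_init__(self) -> None:
        if self.mcse_mode not in ("off", "t1", "t5"):
            raise ValueError("mcse_mode must be one of off/t1/t5")


@dataclass
class FunnelReport:
    """Counts at each stage of the gene-selection funnel."""

    n_total: int
    n_two_expressed: int
    n_two_expressed_overlapping: int
    n_nonoverlapping_removed: int
    n_final: int  # two overlapping expressed isoforms and >= 1 variant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "total_genes",
                    "two_expressed_isoforms",
                    "two_expressed_overlapping",
                    "final_with_variant",
                ],
                "count": [
                    self.n_total,
                    self.n_two_expressed,
                    self.n_two_expressed_overlapping,
                    self.n_final,
                ],
            }
        )


def compute_expression_threshold(
    table: ExpressionTable, cfg: FilterConfig = FilterConfig()
) -> float:
    """Detection threshold t: the minimum mean expression among transcripts
    with at least ``min_unique_reads_for_threshold`` uniquely mapping reads.

    Transcripts with that much unique evidence are reliably quantifiable, so
    the least-expressed of them marks the boundary of trustworthy detection.
    """
    qualifying = table.unique_reads >= cfg.min_unique_reads_for_threshold
    if not qualifying.any():
        raise ValueError(
            "no transcript reaches the unique-read cutoff "
            f"({cfg.min_unique_reads_for_threshold}); lower the cutoff"
        )
    means = table.estimates.mean(axis=1)
    return float(means[qualifying].min())


def _f1_replicate_values(table: ExpressionTable, transcript_id: str) -> np.ndarray:
    """Per-F1-library expression: the sum of the two allele estimates."""
    pairs = table.f1_pairs()
    row = table.estimates.loc[transcript_id]
    return np.array([row[b] + row[c] for b, c in pairs])


def call_expressed(
    table: ExpressionTable, t: float, cfg: FilterConfig = FilterConfig()
) -> set[str]:
    """Transcripts expressed per the replicate-consistency rule.

    A transcript is expressed iff it exceeds t (strictly) in at least
    ``min_replicates`` replicates of either F0 group, and in at least
    ``min_replicates`` F1 libraries (library value = sum of the two allele
    estimates).
    """
    m = cfg.min_replicates
    bl6 = table.estimates[table.columns_for("F0_BL6")]
    cast = table.estimates[table.columns_for("F0_CAST")]
    if bl6.shape[1] < m or cast.shape[1] < m or len(table.f1_pairs()) < m:
        raise ValueError("fewer replicates than min_replicates in some group")
    expressed: set[str] = set()
    for tid in table.transcript_ids:
        f0_ok = (bl6.loc[tid] > t).sum() >= m or (cast.loc[tid] > t).sum() >= m
        f1_ok = (_f1_replicate_values(table, tid) > t).sum() >= m
        if f0_ok and f1_ok:
            expressed.add(tid)
    return expressed


def select_analysis_set(
    genes: list[GeneModel],
    expressed: set[str],
    variants: dict[str, int],
) -> tuple[list[str], FunnelReport]:
    """Keep genes expressing exactly two overlapping isoforms with >= 1
    known strain variant; report counts at every funnel stage.

    Overlap is exonic (>= 1 shared base on the same strand): two isoforms
    sharing only an intron are not a comparable pair and are removed, and
    counted separately.
    """
    n_two = 0
    n_overlap = 0
    n_nonoverlap = 0
    final: list[str] = []
    for gene in genes:
        expr_tx = [t for t in gene.transcripts if t.transcript_id in expressed]
        if len(expr_tx) != 2:
            continue
        n_two += 1
        if not transcripts_overlap(expr_tx[0], expr_tx[1]):
            n_nonoverlap += 1
            continue
        n_overlap += 1
        if variants.get(gene.gene_id, 0) >= 1:
            final.append(gene.gene_id)
    report = FunnelReport(
        n_total=len(genes),
        n_two_expressed=n_two,
        n_two_expressed_overlapping=n_overlap,
        n_nonoverlapping_removed=n_nonoverlap,
        n_final=len(final),
    )
    return final, report


def mcse_subset(table: ExpressionTable, mode: str) -> set[str]:
    """Subset transcripts by estimate uncertainty.

    The threshold is the maximum mean SE among transcripts with exactly 1
    (mode "t1") or exactly 5 (mode "t5") unique reads — i.e. the typical
    uncertainty of a barely-identifiable transcript. Transcripts whose mean
    SE is at or below that anchor are retained (inclusive, so a uniformly
    uncertain table keeps all transcripts). If no transcript has the anchor
    read count exactly, the nearest available count is used, with a warning.
    """
    if mode not in ("t1", "t5"):
        raise ValueError("mode must be 't1' or 't5'")
    anchor_reads = 1 if mode == "t1" else 5
    reads = table.unique_reads
    mean_se = table.se.mean(axis=1)
    at_anchor = reads == anchor_reads
    if not at_anchor.any():
        available = reads.unique()
        nearest = int(available[np.argmin(np.abs(available - anchor_reads))])
        logger.warning(
            "no transcript with exactly %d unique reads; anchoring on %d",
            anchor_reads, nearest,
        )
        at_anchor = reads == nearest
    threshold = float(mean_se[at_anchor].max())
    return set(mean_se.index[mean_se <= threshold])
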