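"""Synthetic F1-hybrid cohorts with known regulatory ground truth.

The generator emulates the study design the pipeline analyses: two inbred
parental strains (BL6, CAST) with six replicate expression measurements
each, and twelve F1 hybrids in which each transcript is measured once per
allele. Every gene expresses two isoforms whose relative usage is governed
by a natural-log-odds model:

* F0 BL6 replicate log-odds  ~ Normal(mu + beta_f0/2, noise_sd^2)
* F0 CAST replicate log-odds ~ Normal(mu - beta_f0/2, noise_sd^2)
* F1 BL6-allele log-odds     ~ Normal(mu + beta_f1/2, noise_sd^2)
* F1 CAST-allele log-odds    ~ Normal(mu - beta_f1/2, noise_sd^2)

so beta_f0 is the strain difference and beta_f1 the allelic difference.
Regulatory classes set (beta_f0, beta_f1): conserved (0, 0); cis (b, b) —
the allelic ratio recapitulates the strain difference; trans (b, 0) — the
shared F1 nuclear environment erases it; cis&trans (b, b/2) — both an
allele-linked and a diffusible component. Log-odds become a transcript
pair's expression levels through a per-gene total drawn log-normally;
reported standard errors decrease with expression, mirroring the behaviour
of Monte Carlo standard errors from probabilistic read deconvolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionTable,
    GeneModel,
    SampleMeta,
    TranscriptModel,
)
from .structure import FLAG_NAMES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_transcript_pair",
    "simulate_cohort",
    "simulate_expression",
    "make_insilico_f1",
]

CLASSES = ("conserved", "cis", "trans", "cis_trans")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the emulated design: 6 F0 replicates per strain, 12 F1
    replicates, effect size 1.5 on the natural-log-odds scale (a ~4.5-fold
    isoform-ratio change), replicate noise 0.2. Structural-category
    marginal probabilities approximate the relative frequencies observed in
    divergent mouse liver isoform pairs (INT most common, ALE least), with
    AFE/TSS and ALE/APA kept mutually exclusive per pair.
    """

    n_genes: int = 400
    class_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    effect_size: float = 1.5
    noise_sd: float = 0.2
    n_f0_reps: int = 6
    n_f1_reps: int = 12
    se_floor: float = 0.5
    se_scale: float = 5.0
    structure_probs: dict = field(
        default_factory=lambda: {
            "AFE": 0.43, "TSS": 0.39, "INT": 0.54, "ALE": 0.33, "APA": 0.48,
        }
    )
    dge_prob: float = 0.37
    base_expression: float = 200.0
    expression_log_sd: float = 0.4
    reads_per_unit: float = 4.0
    n_single_spikeins: int = 0
    n_multi_spikeins: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        sp = self.structure_probs
        if sp["AFE"] + sp["TSS"] > 1.0 + 1e-9:
            raise ValueError("P(AFE) + P(TSS) must not exceed 1")
        if sp["ALE"] + sp["APA"] > 1.0 + 1e-9:
            raise ValueError("P(ALE) + P(APA) must not exceed 1")


@dataclass
class GroundTruth:
    """Planted per-gene truth: regulatory class, effects, structural flags,
    divergent-gene-expression flag, and spike-in bookkeeping."""

    genes: pd.DataFrame  # index: gene_id
    variant_sites: dict = field(default_factory=dict)

    def classes(self) -> pd.Series:
        return self.genes["true_class"]

    @property
    def main_gene_ids(self) -> list[str]:
        return list(self.genes.index[~self.genes["is_spikein"]])

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Transcript structures
# ---------------------------------------------------------------------------

_GENE_LENGTH = 1200  # plus-strand construction canvas before mirroring


def simulate_transcript_pair(
    flags: set[str],
    rng: np.random.Generator,
    gene_id: str = "g",
    chrom: str = "chr1",
    offset: int = 0,
    strand: str | None = None,
    overlapping: bool = True,
) -> GeneModel:
    """Build a two-isoform gene whose pair classifies to exactly ``flags``.

    The reference isoform has four exons; the alternative isoform is derived
    from it by the requested modifications: a 5'-shifted first exon (TSS), a
    detached upstream first exon (AFE), a shifted internal donor (INT), a
    3'-extended last exon (APA), or a detached downstream last exon (ALE).
    Coordinates are randomised (strand, offsets, shift sizes) but the flag
    set is exact by construction. ``overlapping=False`` instead emits a
    disjoint pair for exercising the non-overlap exclusion.
    """
    flags = set(flags)
    unknown = flags - set(FLAG_NAMES)
    if unknown:
        raise ValueError(f"unknown flags {sorted(unknown)}")
    if "AFE" in flags and "TSS" in flags:
        raise ValueError("AFE and TSS are mutually exclusive")
    if "ALE" in flags and "APA" in flags:
        raise ValueError("ALE and APA are mutually exclusive")
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"

    base = [(100, 200), (300, 400), (500, 600), (700, 800)]

    if not overlapping:
        if flags:
            raise ValueError("a non-overlapping pair carries no flags")
        alt = [(0, int(rng.integers(40, 90)))]
    else:
        alt = list(base)
        if "TSS" in flags:
            shift = int(rng.integers(10, 80))
            alt[0] = (100 + shift, 200)
        if "AFE" in flags:
            start = int(rng.integers(0, 20))
            end = int(rng.integers(start + 20, 90))
            alt[0] = (start, end)
        if "INT" in flags:
            shift = int(rng.integers(10, 90))
            alt[1] = (300, 400 + shift)
        if "APA" in flags:
            shift = int(rng.integers(10, 80))
            alt[3] = (700, 800 + shift)
        if "ALE" in flags:
            start = int(rng.integers(900, 1080))
            end = start + int(rng.integers(20, 60))
            alt[3] = (start, end)

    def place(exons: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
        if strand == "-":
            exons = [(_GENE_LENGTH - e, _GENE_LENGTH - s) for s, e in exons]
        return tuple(sorted((s + offset, e + offset) for s, e in exons))

    t_ref = TranscriptModel(
        transcript_id=f"{gene_id}.t1", gene_id=gene_id, chrom=chrom,
        strand=strand, exons=place(base),
    )
    t_alt = TranscriptModel(
        transcript_id=f"{gene_id}.t2", gene_id=gene_id, chrom=chrom,
        strand=strand, exons=place(alt),
    )
    return GeneModel(gene_id=gene_id, transcripts=(t_ref, t_alt))


def _draw_flags(cfg: SimulationConfig, rng: np.random.Generator) -> set[str]:
    sp = cfg.structure_probs
    flags: set[str] = set()
    u5 = rng.random()
    if u5 < sp["AFE"]:
        flags.add("AFE")
    elif u5 < sp["AFE"] + sp["TSS"]:
        flags.add("TSS")
    u3 = rng.random()
    if u3 < sp["ALE"]:
        flags.add("ALE")
    elif u3 < sp["ALE"] + sp["APA"]:
        flags.add("APA")
    if rng.random() < sp["INT"]:
        flags.add("INT")
    return flags


def _multi_isoform_gene(
    gene_id: str, chrom: str, offset: int, rng: np.random.Generator
) -> GeneModel:
    """Three-isoform spike-in: base pair plus a third isoform skipping one
    internal exon."""
    pair = simulate_transcript_pair({"INT"}, rng, gene_id, chrom, offset)
    t1 = pair.transcripts[0]
    exons3 = tuple(e for i, e in enumerate(t1.exons) if i != 2)
    t3 = TranscriptModel(
        transcript_id=f"{gene_id}.t3", gene_id=gene_id, chrom=chrom,
        strand=t1.strand, exons=exons3,
    )
    return GeneModel(gene_id=gene_id, transcripts=(*pair.transcripts, t3))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], GroundTruth, dict[str, int]]:
    """Generate gene models, ground truth, and a per-gene variant count map.

    Emits ``cfg.n_genes`` two-isoform genes with at least one strain variant
    each, plus optional spike-ins — single-isoform genes (generated at low
    expression, so they anchor the unique-reads expression threshold the way
    marginally quantifiable transcripts do in practice) and three-isoform
    genes — all with zero variants, to exercise the selection funnel.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    rows: list[dict] = []
    variant_sites: dict[str, list] = {}
    spacing = 5000
    idx = 0

    def record(gene_id, true_class, b0, b1, flags, dge, spikein, n_tx, base_expr):
        rows.append(
            {
                "gene_id": gene_id,
                "true_class": true_class,
                "beta_f0": b0,
                "beta_f1": b1,
                **{f: (f in flags) for f in FLAG_NAMES},
                "dge_flag": dge,
                "is_spikein": spikein,
                "n_transcripts": n_tx,
                "base_expression": base_expr,
            }
        )

    if cfg.n_genes > 0:
        for i in range(cfg.n_genes):
            gene_id = f"g{i:05d}"
            offset = idx * spacing
            idx += 1
            cls = CLASSES[rng.choice(4, p=cfg.class_probs)]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            beta = sign * cfg.effect_size
            if cls == "conserved":
                b0, b1 = 0.0, 0.0
            elif cls == "cis":
                b0, b1 = beta, beta
            elif cls == "trans":
                b0, b1 = beta, 0.0
            else:  # cis & trans: allele-linked and diffusible components
                b0, b1 = beta, beta / 2.0
            flags = _draw_flags(cfg, rng)
            gene = simulate_transcript_pair(flags, rng, gene_id, "chr1", offset)
            n_snv = 1 + int(rng.poisson(2.0))
            span = gene.span
            sites = [
                ("chr1", int(rng.integers(span[0], span[1])))
                for _ in range(n_snv)
            ]
            genes.append(
                GeneModel(gene_id=gene_id, transcripts=gene.transcripts,
                          snv_count=n_snv)
            )
            variant_sites[gene_id] = sites
            dge = bool(rng.random() < cfg.dge_prob)
            base_expr = cfg.base_expression * math.exp(
                rng.normal(0.0, cfg.expression_log_sd)
            )
            record(gene_id, cls, b0, b1, flags, dge, False, 2, base_expr)

        for j in range(cfg.n_single_spikeins):
            gene_id = f"s{j:04d}"
            offset = idx * spacing
            idx += 1
            pair = simulate_transcript_pair(set(), rng, gene_id, "chr1", offset)
            genes.append(
                GeneModel(gene_id=gene_id, transcripts=pair.transcripts[:1])
            )
            # low expression: these transcripts sit just above the
            # 10-unique-read boundary and set the expression threshold t
            base_expr = 4.0 * math.exp(rng.normal(0.0, 0.1))
            record(gene_id, "conserved", 0.0, 0.0, set(), False, True, 1,
                   base_expr)

        for j in range(cfg.n_multi_spikeins):
            gene_id = f"m{j:04d}"
            offset = idx * spacing
            idx += 1
            genes.append(_multi_isoform_gene(gene_id, "chr1", offset, rng))
            base_expr = cfg.base_expression * math.exp(
                rng.normal(0.0, cfg.expression_log_sd)
            )
            record(gene_id, "conserved", 0.0, 0.0, set(), False, True, 3,
                   base_expr)

    columns = [
        "gene_id", "true_class", "beta_f0", "beta_f1", *FLAG_NAMES,
        "dge_flag", "is_spikein", "n_transcripts", "base_expression",
    ]
    truth_df = pd.DataFrame(rows, columns=columns)
    truth_df = truth_df.set_index("gene_id")
    truth = GroundTruth(genes=truth_df, variant_sites=variant_sites)
    variants = {g.gene_id: g.snv_count for g in genes}
    return genes, truth, variants


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _se_model(expr: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Reported estimate SE: decreasing with expression, floored."""
    return cfg.se_floor + cfg.se_scale / np.sqrt(np.maximum(expr, 1.0))


def _sample_layout(cfg: SimulationConfig) -> list[SampleMeta]:
    samples = [
        SampleMeta(f"bl6_{r + 1}", "F0_BL6", "NA", r + 1)
        for r in range(cfg.n_f0_reps)
    ]
    samples += [
        SampleMeta(f"cast_{r + 1}", "F0_CAST", "NA", r + 1)
        for r in range(cfg.n_f0_reps)
    ]
    for r in range(cfg.n_f1_reps):
        samples.append(SampleMeta(f"f1_{r + 1}.BL6", "F1", "BL6", r + 1))
        samples.append(SampleMeta(f"f1_{r + 1}.CAST", "F1", "CAST", r + 1))
    return samples


def simulate_expression(
    genes: list[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionTable:
    """Realise the log-odds model as an expression table with SEs.

    The per-gene baseline log-odds is uniform on (-0.8, 0.8) — bounded so
    both isoforms remain quantifiable, mirroring the expressed-isoform
    preselection of the emulated design. Each F1 allele carries half the
    gene total. Genes flagged for divergent total expression get a two-fold
    strain shift of the total, which leaves isoform proportions untouched:
    usage divergence and expression divergence are planted independently.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    samples = _sample_layout(cfg)
    sample_ids = [s.sample_id for s in samples]
    est_rows: dict[str, np.ndarray] = {}
    tx_order: list[str] = []

    for gene in genes:
        info = truth.genes.loc[gene.gene_id]
        total = float(info["base_expression"])
        dge_fold = 1.0
        if bool(info["dge_flag"]):
            dge_fold = 2.0 if rng.random() < 0.5 else 0.5
        k = len(gene.transcripts)
        tids = [t.transcript_id for t in gene.transcripts]
        if k == 2:
            mu = rng.uniform(-0.8, 0.8)
            b0, b1 = float(info["beta_f0"]), float(info["beta_f1"])
            vals = {tid: [] for tid in tids}
            for s in samples:
                if s.group == "F0_BL6":
                    lo = mu + b0 / 2.0
                    tot = total
                elif s.group == "F0_CAST":
                    lo = mu - b0 / 2.0
                    tot = total * dge_fold
                elif s.allele == "BL6":
                    lo = mu + b1 / 2.0
                    tot = total / 2.0
                else:
                    lo = mu - b1 / 2.0
                    tot = (total * dge_fold) / 2.0
                lo = lo + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
                p = float(_sigmoid(np.array(lo)))
                vals[tids[0]].append(tot * p)
                vals[tids[1]].append(tot * (1.0 - p))
            for tid in tids:
                est_rows[tid] = np.array(vals[tid])
                tx_order.append(tid)
        else:
            # spike-ins: softmax usage over k isoforms, no strain effects
            base_logits = np.linspace(0.5, -0.5, k)
            mat = np.zeros((k, len(samples)))
            for ci, s in enumerate(samples):
                logits = base_logits + (
                    rng.normal(0.0, cfg.noise_sd, size=k)
                    if cfg.noise_sd > 0
                    else 0.0
                )
                w = np.exp(logits - logits.max())
                p = w / w.sum()
                tot = total / 2.0 if s.group == "F1" else total
                mat[:, ci] = tot * p
            for r, tid in enumerate(tids):
                est_rows[tid] = mat[r]
                tx_order.append(tid)

    est = pd.DataFrame.from_dict(est_rows, orient="index", columns=sample_ids)
    est = est.loc[tx_order].astype(float)
    se = pd.DataFrame(
        _se_model(est.to_numpy(), cfg), index=est.index, columns=est.columns
    )
    unique_reads = (cfg.reads_per_unit * est.mean(axis=1)).round().astype(int)
    return ExpressionTable(est, se, unique_reads, samples)


# ---------------------------------------------------------------------------
# In-silico F1 construction
# ---------------------------------------------------------------------------

def make_insilico_f1(
    f0_bl6: pd.Series,
    f0_cast: pd.Series,
    rng: np.random.Generator,
    se_floor: float = 0.5,
    se_scale: float = 5.0,
    noise_scale: float = 1.0,
) -> dict:
    """Construct one pseudo-F1 replicate by combining two F0 libraries.

    Each allele column's expectation is half the corresponding F0 column
    (an F1 library splits its reads between alleles); resampling noise
    follows the expression-dependent SE model, scaled by ``noise_scale``
    (0 gives the exact noiseless halves). The originating F0 values are
    returned as truth for correlation checks.
    """
    if not f0_bl6.index.equals(f0_cast.index):
        raise ValueError("F0 columns must come from the same table")
    out = {}
    for name, col in (("bl6_allele", f0_bl6), ("cast_allele", f0_cast)):
        half = col.to_numpy(dtype=float) / 2.0
        se = (se_floor + se_scale / np.sqrt(np.maximum(half, 1.0))) * noise_scale
        noisy = half + (rng.normal(0.0, 1.0, size=half.size) * se
                        if noise_scale > 0 else 0.0)
        out[name] = pd.Series(np.maximum(noisy, 0.0), index=col.index)
    out["truth_bl6"] = f0_bl6 / 2.0
    out["truth_cast"] = f0_cast / 2.0
    return out
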