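"""End-to-end orchestration: simulate (or load) -> filter -> classify
divergence -> classify structure -> enrichment, with a JSON run manifest.

Every stage writes a plain TSV so runs are diffable; all randomness flows
from the single seed recorded in the manifest, making reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .divergence import (
    CLASS_NAMES,
    DivergenceModelSpec,
    classify_gene,
    isoform_proportion,
)
from .enrichment import category_class_table, int_alone_excess
from .filtering import (
    FilterConfig,
    call_expressed,
    compute_expression_threshold,
    select_analysis_set,
)
from .io_formats import (
    ExpressionTable,
    read_expression_table,
    read_gtf,
    read_variants,
    write_expression_table,
    write_gtf,
    write_variants_vcf,
)
from .structure import (
    FLAG_NAMES,
    StructuralDiff,
    classify_pair,
    combination_matrix,
    combination_matrix_frame,
)
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    simulate_cohort,
    simulate_expression,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "proportion_scatter_table"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name (and gene, if any)."""


@dataclass
class RunConfig:
    """Either a simulation config or paths to on-disk inputs, plus the
    filter and model settings, an output directory and the run seed."""

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    gtf_path: str | None = None
    expression_path: str | None = None
    meta_path: str | None = None
    variants_path: str | None = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    model_spec: DivergenceModelSpec = field(default_factory=DivergenceModelSpec)

    def __post_init__(self) -> None:
        has_paths = self.expression_path is not None
        if (self.simulation is None) == (not has_paths):
            raise ValueError(
                "provide exactly one of a simulation config or input paths"
            )


def proportion_scatter_table(
    table: ExpressionTable, pairs: dict[str, tuple[str, str]]
) -> pd.DataFrame:
    """Per-gene mean isoform-1 proportion in each F0 strain.

    Conserved genes fall on the diagonal of (p_BL6, p_CAST); divergent
    usage pulls a gene off it.
    """
    bl6_cols = table.columns_for("F0_BL6")
    cast_cols = table.columns_for("F0_CAST")
    rows = []
    for gene_id, (t1, t2) in pairs.items():
        e1, e2 = table.estimates.loc[t1], table.estimates.loc[t2]
        p_bl6 = np.mean([isoform_proportion(e1[c], e2[c]) for c in bl6_cols])
        p_cast = np.mean([isoform_proportion(e1[c], e2[c]) for c in cast_cols])
        rows.append({"gene_id": gene_id, "p_bl6": p_bl6, "p_cast": p_cast})
    return pd.DataFrame(rows, columns=["gene_id", "p_bl6", "p_cast"])


def _calls_frame(summaries, calls) -> pd.DataFrame:
    rows = []
    for s, c in zip(summaries, calls):
        rows.append(
            {
                "gene_id": s.gene_id,
                "d1": s.d1, "v1": s.v1, "d2": s.d2, "v2": s.v2,
                **{f"post_{k}": c.posteriors[k] for k in CLASS_NAMES},
                "label": c.label,
                "posterior_margin": c.posterior_margin,
            }
        )
    cols = ["gene_id", "d1", "v1", "d2", "v2",
            *[f"post_{k}" for k in CLASS_NAMES], "label", "posterior_margin"]
    return pd.DataFrame(rows, columns=cols)


def _flags_frame(diffs: list[StructuralDiff]) -> pd.DataFrame:
    rows = [
        {"gene_id": d.gene_id, **{f: getattr(d, f) for f in FLAG_NAMES},
         "n_changes": d.n_changes}
        for d in diffs
    ]
    return pd.DataFrame(rows, columns=["gene_id", *FLAG_NAMES, "n_changes"])


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write all outputs under ``cfg.out_dir``.

    Returns the manifest dict (also written as manifest.json): package
    version, seed, full configuration, and per-stage counts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: GroundTruth | None = None

    # -- stage: inputs -----------------------------------------------------
    try:
        if cfg.simulation is not None:
            sim = cfg.simulation
            if sim.seed != cfg.seed:
                sim = SimulationConfig(**{**asdict(sim), "seed": cfg.seed})
            genes, truth, variants = simulate_cohort(sim)
            table = simulate_expression(genes, truth, sim)
            write_gtf(genes, out / "annotation.gtf")
            write_expression_table(table, out / "expression.tsv", out / "samples.tsv")
            write_variants_vcf(truth.variant_sites, out / "variants.vcf")
            truth.to_tsv(out / "truth.tsv")
        else:
            genes = read_gtf(cfg.gtf_path)
            table = read_expression_table(cfg.expression_path, cfg.meta_path)
            variants = (
                read_variants(cfg.variants_path, genes)
                if cfg.variants_path
                else {g.gene_id: 0 for g in genes}
            )
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc

    gene_by_id = {g.gene_id: g for g in genes}

    # -- stage: filtering --------------------------------------------------
    try:
        if len(table.estimates):
            t = compute_expression_threshold(table, cfg.filter_cfg)
            expressed = call_expressed(table, t, cfg.filter_cfg)
        else:
            t, expressed = float("nan"), set()
        analysis_ids, funnel = select_analysis_set(genes, expressed, variants)
    except Exception as exc:
        raise PipelineError(f"filter stage: {exc}") from exc
    funnel.to_frame().to_csv(out / "funnel.tsv", sep="\t", index=False)
    pd.Series(sorted(expressed), name="transcript_id").to_csv(
        out / "expressed.tsv", sep="\t", index=False
    )

    pairs: dict[str, tuple[str, str]] = {}
    for gid in analysis_ids:
        expr_tx = [
            tx.transcript_id
            for tx in gene_by_id[gid].transcripts
            if tx.transcript_id in expressed
        ]
        pairs[gid] = (expr_tx[0], expr_tx[1])

    # -- stage: divergence classification ----------------------------------
    summaries, calls = [], []
    for gid, (t1, t2) in pairs.items():
        try:
            s, c = classify_gene(table, gid, t1, t2, cfg.model_spec)
        except Exception as exc:
            raise PipelineError(f"divergence stage, gene {gid}: {exc}") from exc
        summaries.append(s)
        calls.append(c)
    calls_df = _calls_frame(summaries, calls)
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
    proportion_scatter_table(table, pairs).to_csv(
        out / "proportions.tsv", sep="\t", index=False
    )

    # -- stage: structural classification ----------------------------------
    diffs: list[StructuralDiff] = []
    for gid, (t1, t2) in pairs.items():
        try:
            gene = gene_by_id[gid]
            tx = {x.transcript_id: x for x in gene.transcripts}
            diffs.append(classify_pair(tx[t1], tx[t2]))
        except Exception as exc:
            raise PipelineError(f"structure stage, gene {gid}: {exc}") from exc
    _flags_frame(diffs).to_csv(out / "flags.tsv", sep="\t", index=False)
    combination_matrix_frame(diffs).to_csv(
        out / "combinations.tsv", sep="\t", index=False
    )

    # -- stage: enrichment -------------------------------------------------
    try:
        enr = category_class_table(diffs, calls)
        enr["percentages"].to_csv(out / "category_percentages.tsv", sep="\t",
                                  index_label="flag")
        enr["tests"].to_csv(out / "enrichment_tests.tsv", sep="\t", index=False)
        int_excess = int_alone_excess(diffs) if diffs else None
    except Exception as exc:
        raise PipelineError(f"enrichment stage: {exc}") from exc

    combo = combination_matrix(diffs)
    label_counts = calls_df["label"].value_counts().to_dict() if len(calls_df) else {}
    manifest = {
        "isodiv_version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "expression_threshold": None if np.isnan(t) else t,
        "funnel": {
            "total_genes": funnel.n_total,
            "two_expressed_isoforms": funnel.n_two_expressed,
            "two_expressed_overlapping": funnel.n_two_expressed_overlapping,
            "nonoverlapping_removed": funnel.n_nonoverlapping_removed,
            "final_with_variant": funnel.n_final,
        },
        "n_classified": {k: int(label_counts.get(k, 0))
                         for k in (*CLASS_NAMES, "unclassified")},
        "total_structural_changes": combo["total_changes"],
        "flag_counts": combo["flag_counts"],
        "int_alone": (
            {k: int_excess[k] for k in
             ("observed_int_alone", "expected_int_alone", "statistic", "p")}
            if int_excess is not None else None
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
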