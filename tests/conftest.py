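import numpy as np
import pandas as pd
import pytest

from isodiv.io_formats import ExpressionTable, SampleMeta, TranscriptModel


def sample_layout(n_f0: int, n_f1: int) -> list[SampleMeta]:
    samples = [SampleMeta(f"bl6_{r+1}", "F0_BL6", "NA", r + 1) for r in range(n_f0)]
    samples += [SampleMeta(f"cast_{r+1}", "F0_CAST", "NA", r + 1) for r in range(n_f0)]
    for r in range(n_f1):
        samples.append(SampleMeta(f"f1_{r+1}.BL6", "F1", "BL6", r + 1))
        samples.append(SampleMeta(f"f1_{r+1}.CAST", "F1", "CAST", r + 1))
    return samples


def make_table(
    values: dict[str, list[float]],
    n_f0: int = 2,
    n_f1: int = 2,
    se: float | dict[str, float] = 1.0,
    unique_reads: dict[str, int] | None = None,
) -> ExpressionTable:
    """Build an ExpressionTable from per-transcript value lists ordered as
    [BL6 f0 reps..., CAST f0 reps..., (F1 BL6-allele, F1 CAST-allele)...]."""
    samples = sample_layout(n_f0, n_f1)
    cols = [s.sample_id for s in samples]
    est = pd.DataFrame(values, index=cols).T
    if isinstance(se, dict):
        se_df = pd.DataFrame(
            {c: [se[t] for t in est.index] for c in cols}, index=est.index
        )
    else:
        se_df = pd.DataFrame(se, index=est.index, columns=cols)
    if unique_reads is None:
        unique_reads = {t: 100 for t in est.index}
    return ExpressionTable(est, se_df, pd.Series(unique_reads), samples)


def tx(exons, strand="+", tid="t", gid="g", chrom="chr1") -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
        exons=tuple(exons),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
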