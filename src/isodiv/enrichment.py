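"""Cross-tabulation statistics: category-by-mechanism enrichment, the
INT-alone excess, usage-vs-expression independence, and multiple-testing
adjustment."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .divergence import DivergenceCall
from .structure import FLAG_NAMES, StructuralDiff

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "chi2_independence",
    "category_class_table",
    "int_alone_excess",
    "bh_fdr",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(t: ContingencyTable2x2) -> dict:
    """Two-sided Fisher exact test by the minimum-likelihood convention:
    the p-value sums the probabilities of all tables with the observed
    margins no more probable than the observed one.

    The odds ratio is the sample odds ratio ad/bc; degenerate cases are
    flagged rather than raised (a zero margin makes the test vacuous,
    p = 1).
    """
    arr = t.as_array()
    row_margins = arr.sum(axis=1)
    col_margins = arr.sum(axis=0)
    if 0 in row_margins or 0 in col_margins:
        return {"odds_ratio": np.nan, "p": 1.0, "odds_ratio_flag": "undefined"}
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    bc = t.b * t.c
    if bc == 0:
        oratio, flag = np.inf, "infinite"
    else:
        oratio = (t.a * t.d) / bc
        flag = "zero" if oratio == 0 else "ok"
    return {"odds_ratio": float(oratio), "p": float(p), "odds_ratio_flag": flag}


def chi2_independence(table: np.ndarray | ContingencyTable2x2) -> dict:
    """Pearson chi-square test of independence, no continuity correction.

    Emits a warning when any expected count falls below 5, where the
    asymptotic p-value is unreliable.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.sum() == 0:
        raise ValueError("empty contingency table")
    stat, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    low_expected = bool((expected < 5).any())
    if low_expected:
        logger.warning("chi-square expected count < 5; p-value is approximate")
    return {
        "statistic": float(stat),
        "p": float(p),
        "dof": int(dof),
        "expected": expected,
        "low_expected_warning": low_expected,
    }


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def category_class_table(
    flags: list[StructuralDiff],
    calls: list[DivergenceCall],
    comparison: str = "conserved",
    class_pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Percentage of genes in each regulatory class carrying each
    structural flag, with per-cell Fisher tests between classes.

    By default each divergence class is compared against ``comparison``
    (the conserved class); an explicit list of class pairs — e.g.
    [("cis", "trans")] for the last-exon contrast — can be given instead.
    P-values are BH-adjusted across all cells tested.
    """
    by_gene = {c.gene_id: c.label for c in calls}
    rows = []
    for d in flags:
        label = by_gene.get(d.gene_id)
        if label is None or label == "unclassified":
            continue
        rows.append({"gene_id": d.gene_id, "label": label,
                     **{f: getattr(d, f) for f in FLAG_NAMES}})
    df = pd.DataFrame(rows, columns=["gene_id", "label", *FLAG_NAMES])

    classes = ("conserved", "cis", "trans", "cis_trans")
    pct = pd.DataFrame(index=list(FLAG_NAMES), columns=list(classes), dtype=float)
    for cls in classes:
        sub = df[df["label"] == cls]
        for f in FLAG_NAMES:
            pct.loc[f, cls] = 100.0 * sub[f].mean() if len(sub) else np.nan

    if class_pairs is None:
        class_pairs = [(c, comparison) for c in classes if c != comparison]
    tests = []
    for f in FLAG_NAMES:
        for c1, c2 in class_pairs:
            s1 = df[df["label"] == c1]
            s2 = df[df["label"] == c2]
            if len(s1) == 0 or len(s2) == 0:
                continue
            tab = ContingencyTable2x2(
                a=int(s1[f].sum()), b=int((~s1[f]).sum()),
                c=int(s2[f].sum()), d=int((~s2[f]).sum()),
            )
            res = fisher_exact_2x2(tab)
            tests.append(
                {"flag": f, "class_1": c1, "class_2": c2,
                 "odds_ratio": res["odds_ratio"], "p": res["p"]}
            )
    tests_df = pd.DataFrame(
        tests, columns=["flag", "class_1", "class_2", "odds_ratio", "p"]
    )
    if len(tests_df):
        tests_df["p_adj"] = bh_fdr(tests_df["p"].to_numpy())
    else:
        tests_df["p_adj"] = []
    return {"percentages": pct, "tests": tests_df}


def int_alone_excess(flags: list[StructuralDiff]) -> dict:
    """Is an internal-splicing difference found *alone* more often than
    independence of the categories would predict?

    Builds the 2x2 of INT (yes/no) x any-other-flag (yes/no), runs the
    chi-square independence test, and reports the observed vs expected
    count of INT-only genes.
    """
    if not flags:
        raise ValueError("no classified pairs given")
    arr = np.zeros((2, 2), dtype=int)
    for d in flags:
        has_int = d.INT
        has_other = bool(d.flag_set - {"INT"})
        arr[0 if has_int else 1, 0 if has_other else 1] += 1
    observed = int(arr[0, 1])  # INT and nothing else
    total = arr.sum()
    expected = arr[0].sum() * arr[:, 1].sum() / total
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return {"observed_int_alone": observed, "expected_int_alone": float(expected),
                "statistic": 0.0, "p": 1.0}
    res = chi2_independence(arr)
    return {
        "observed_int_alone": observed,
        "expected_int_alone": float(expected),
        "statistic": res["statistic"],
        "p": res["p"],
    }
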