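"""Cohort-level statistical comparisons for per-DRP peptide burdens.

Donor-recipient pairs are compared by donor type (HLA-matched related, MRD,
vs matched unrelated, MUD): Fisher exact tests on median-split 2x2 tables,
Welch t-tests on counts, Pearson correlation between SB and BP burdens, and
medians/ranges of the class I / class II count ratios.

The two-sided Fisher p-value follows the point-probability convention (the
one implemented by scipy and R): the sum, over all tables with the observed
margins, of hypergeometric point probabilities no larger than that of the
observed table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts [[a, b], [c, d]]; rows = donor type, columns =
    above / at-or-below the cohort median."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (point-probability method)."""
    return float(sps.fisher_exact(table.as_array(),
                                  alternative="two-sided").pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance series")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_t(x, y) -> tuple[float, float]:
    """Unequal-variance (Welch) two-sample t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DrpSummary:
    """Per-pair SB/BP peptide counts by HLA class, with I/II ratios."""

    drp_id: str
    donor_type: str
    sb_class_i: int
    bp_class_i: int
    sb_class_ii: int
    bp_class_ii: int

    def __post_init__(self) -> None:
        if self.sb_class_i > self.bp_class_i:
            raise ValueError("class I SB count exceeds BP count")
        if self.sb_class_ii > self.bp_class_ii:
            raise ValueError("class II SB count exceeds BP count")
        if self.donor_type not in ("MRD", "MUD"):
            raise ValueError(f"unknown donor type {self.donor_type!r}")

    @property
    def ratio_bp(self) -> float | None:
        """Class I / class II BP ratio (None when undefined)."""
        return (self.bp_class_i / self.bp_class_ii
                if self.bp_class_ii > 0 else None)

    @property
    def ratio_sb(self) -> float | None:
        return (self.sb_class_i / self.sb_class_ii
                if self.sb_class_ii > 0 else None)


def median_split_table(
    summaries: list[DrpSummary], column: str
) -> ContingencyTable2x2:
    """2x2 table of donor type (MUD row first) against strictly-above vs
    at-or-below the whole-cohort median of ``column``."""
    values = np.array([getattr(s, column) for s in summaries], dtype=float)
    med = float(np.median(values))
    cells = {"MUD": [0, 0], "MRD": [0, 0]}
    for s, v in zip(summaries, values):
        cells[s.donor_type][0 if v > med else 1] += 1
    return ContingencyTable2x2(a=cells["MUD"][0], b=cells["MUD"][1],
                               c=cells["MRD"][0], d=cells["MRD"][1])


def _ratio_stats(ratios: list[float | None], what: str) -> dict:
    defined = [r for r in ratios if r is not None]
    if len(defined) < len(ratios):
        warnings.warn(
            f"{len(ratios) - len(defined)} {what} ratios undefined "
            "(zero class II count); excluded", stacklevel=3)
    if not defined:
        return {"median": None, "min": None, "max": None}
    return {"median": float(np.median(defined)),
            "min": float(min(defined)), "max": float(max(defined))}


def summarize_cohort(summaries: list[DrpSummary]) -> dict:
    """Cohort report: count statistics by donor type, I/II ratio medians
    and ranges, median-split tables with their Fisher p-values, and the
    Welch test on class II BP burden by donor type."""
    if not summaries:
        raise ValueError("need at least one DRP summary")
    df = pd.DataFrame(
        [(s.drp_id, s.donor_type, s.sb_class_i, s.bp_class_i,
          s.sb_class_ii, s.bp_class_ii) for s in summaries],
        columns=["drp_id", "donor_type", "sb_class_i", "bp_class_i",
                 "sb_class_ii", "bp_class_ii"])
    count_cols = ["sb_class_i", "bp_class_i", "sb_class_ii", "bp_class_ii"]
    by_type = df.groupby("donor_type")[count_cols].agg(
        ["mean", "std", "median", "min", "max"])

    report: dict = {
        "n": len(summaries),
        "by_donor_type": by_type,
        "ratio_bp": _ratio_stats([s.ratio_bp for s in summaries], "BP"),
        "ratio_sb": _ratio_stats([s.ratio_sb for s in summaries], "SB"),
    }
    if df["donor_type"].nunique() == 2:
        tables = {}
        for col in ("sb_class_ii", "bp_class_ii"):
            tab = median_split_table(summaries, col)
            tables[col] = {"table": tab, "fisher_p": fisher_exact_two_sided(tab)}
        report["median_split"] = tables
        mud = df.loc[df["donor_type"] == "MUD", "bp_class_ii"]
        mrd = df.loc[df["donor_type"] == "MRD", "bp_class_ii"]
        if len(mud) >= 2 and len(mrd) >= 2:
            t, p = welch_t(mud, mrd)
            report["welch_bp_class_ii"] = {"t": t, "p": p}
    return report


def plot_counts_by_donor_type(summaries: list[DrpSummary], log: bool = False):
    """Strip plot of class II SB/BP counts by donor type (linear or log
    scale).  Returns the matplotlib Figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2), sharey=False)
    rng = np.random.default_rng(0)  # jitter only
    for ax, col, title in zip(axes, ("sb_class_ii", "bp_class_ii"),
                              ("SB (class II)", "BP (class II)")):
        for i, dtype in enumerate(("MRD", "MUD")):
            vals = [getattr(s, col) for s in summaries
                    if s.donor_type == dtype]
            ax.scatter(i + rng.uniform(-0.12, 0.12, len(vals)), vals,
                       s=12, alpha=0.7)
        ax.set_xticks([0, 1], ["MRD", "MUD"])
        ax.set_title(title)
        if log:
            ax.set_yscale("log")
    fig.tight_layout()
    return fig
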