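"""Screen-to-screen comparison: top-list overlap and gene-panel alignment.

Two screens run under different drugs can be compared (a) by the
overlap of their top candidate lists and (b) by aligning a fixed gene
panel (e.g. the most frequently mutated/amplified oncogenes of the
tumor type) ordered by one screen's scores, with the other screen's
scores in an adjacent column — the basis for a two-column heat map and
for Pearson/Kendall/Spearman rank agreement between the screens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .ranking import CandidateList


@dataclass
class ComparisonResult:
    """Overlap and/or correlation statistics between two screens."""

    overlap_count: int | None = None
    overlap_fraction: float | None = None
    overlap_genes: list[str] = field(default_factory=list)
    pearson: float | None = None
    kendall: float | None = None
    spearman: float | None = None

    def to_dict(self) -> dict:
        return {
            "overlap_count": self.overlap_count,
            "overlap_fraction": self.overlap_fraction,
            "overlap_genes": self.overlap_genes,
            "pearson": self.pearson,
            "kendall": self.kendall,
            "spearman": self.spearman,
        }


def top_list_overlap(
    list_a: CandidateList | list[str], list_b: CandidateList | list[str]
) -> ComparisonResult:
    """Intersection of two candidate lists.

    The fraction is relative to list_a's size (the reference screen);
    the count itself is symmetric.
    """
    a = list(list_a.genes if isinstance(list_a, CandidateList) else list_a)
    b = list_b.genes if isinstance(list_b, CandidateList) else list_b
    if not a or not b:
        raise ParameterError("both candidate lists must be non-empty")
    bset = set(b)
    shared = [g for g in a if g in bset]  # reference order, deterministic
    return ComparisonResult(
        overlap_count=len(shared),
        overlap_fraction=len(shared) / len(a),
        overlap_genes=shared,
    )


def align_panel(
    panel_genes: list[str],
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    score: str = "mean_lfc",
) -> pd.DataFrame:
    """Align a gene panel across two screens, ordered by screen A.

    Returns a DataFrame with columns ``gene, value_a, value_b`` sorted
    descending by ``value_a`` (stable: equal scores keep panel order).
    Genes missing from either screen are dropped with a warning. The
    two value columns are the heat-map matrix.
    """
    if not panel_genes:
        raise ParameterError("panel gene list is empty")
    if len(set(panel_genes)) != len(panel_genes):
        raise ValidationError("panel genes must be unique")
    rows, dropped = [], 0
    for g in panel_genes:
        if g in summaries_a.index and g in summaries_b.index:
            rows.append(
                {
                    "gene": g,
                    "value_a": float(summaries_a.loc[g, score]),
                    "value_b": float(summaries_b.loc[g, score]),
                }
            )
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} panel gene(s) missing from one of the screens; dropped",
            stacklevel=2,
        )
    panel = pd.DataFrame(rows, columns=["gene", "value_a", "value_b"])
    return panel.sort_values(
        "value_a", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def panel_correlations(panel: pd.DataFrame) -> ComparisonResult:
    """Pearson, Kendall tau-b and Spearman rho between the two columns."""
    if len(panel) < 3:
        raise ParameterError("need at least 3 genes for panel correlations")
    a = panel["value_a"].to_numpy(float)
    b = panel["value_b"].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("zero variance in a value column; correlations undefined")
    return ComparisonResult(
        pearson=float(stats.pearsonr(a, b).statistic),
        kendall=float(stats.kendalltau(a, b).statistic),  # tau-b handles ties
        spearman=float(stats.spearmanr(a, b).statistic),
    )
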