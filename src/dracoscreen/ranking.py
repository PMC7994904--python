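"""Per-guide log fold-changes, terrace ranking and DRACO selection.

For every non-noisy guide, the dropout statistic is the pseudocounted
log2 ratio of normalized abundances between a drug-treated sample and
its same-timepoint vehicle control:

    lfc = log2((N_drug + 1) / (N_control + 1))

Genes are then summarized over their guide sets (six guides per gene in
a GeCKOv2-style library):

* mean_lfc — arithmetic mean of the gene's guide lfc values;
* concordance_k — number of guide lfc values whose strict sign matches
  the sign of mean_lfc (a zero lfc matches neither sign);
* terrace rank — an integer 1..6 equal to concordance_k, used to group
  genes on a terraced plot; the higher the rank, the more internally
  consistent the gene's knockout phenotype.

DRACO (decisive ranking of CRISPR outputs) addresses the opposite
failure mode of mean-based ranking: heterogeneous guide editing
efficiency can dilute a real effect, while a single hyper-efficient (or
off-target) guide can fake one. DRACO keeps only genes whose guide set
is sign-concordant (at least four of six guides matching the mean's
sign) and then scores each surviving gene by its single most extreme
guide — the max-|lfc| guide reported at its actual signed value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .qc import NoiseMask, NormalizedTable
from .screen_io import GuideLibrary

DEFAULT_MIN_CONCORDANT = 4
DIRECTIONS = ("depleted", "enriched")


def compute_lfc(
    norm: NormalizedTable,
    drug_sample: str,
    control_sample: str,
    mask: NoiseMask | None = None,
    library: GuideLibrary | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide log2((N_drug+1)/(N_control+1)) for non-flagged guides.

    Returns a DataFrame with columns ``guide_id, gene, lfc, n_drug,
    n_control`` (gene requires `library`; the normalized abundances are
    kept so gene summaries can optionally use log-of-means).
    """
    if drug_sample == control_sample:
        raise ParameterError("drug and control sample must differ")
    values = norm.values
    for s in (drug_sample, control_sample):
        if s not in values.columns:
            raise ParameterError(f"sample {s!r} not in normalized table")
    keep = values.index
    if mask is not None:
        keep = keep.intersection(mask.usable())
    nd = values.loc[keep, drug_sample].to_numpy(float)
    nc = values.loc[keep, control_sample].to_numpy(float)
    lfc = np.log2((nd + pseudocount) / (nc + pseudocount))
    out = pd.DataFrame(
        {
            "guide_id": keep,
            "gene": [library.gene_of(g) for g in keep] if library is not None else pd.NA,
            "lfc": lfc,
            "n_drug": nd,
            "n_control": nc,
            "is_control": [library.guide(g).is_control for g in keep]
            if library is not None
            else False,
        }
    )
    return out.reset_index(drop=True)


def _strict_sign(x: np.ndarray | float) -> np.ndarray | float:
    return np.sign(x)


def summarize_genes(
    records: pd.DataFrame,
    library: GuideLibrary | None = None,
    mean_mode: str = "mean_of_logs",
    pseudocount: float = 1.0,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Collapse per-guide fold-changes into per-gene summaries.

    Parameters
    ----------
    records
        Output of :func:`compute_lfc` (requires ``gene`` populated).
    mean_mode
        ``mean_of_logs`` (default): mean_lfc is the arithmetic mean of
        the guide lfc values. ``log_of_means``: mean_lfc is
        log2((mean N_drug + 1)/(mean N_control + 1)) over the gene's
        guides. Concordance always counts guide lfc signs against the
        sign of mean_lfc, whichever way it was computed.
    include_controls
        Non-targeting control guides do not form a real gene set and
        are excluded from gene summaries unless this is True.

    Returns
    -------
    DataFrame indexed by gene with columns ``n_guides, mean_lfc,
    concordance_k, terrace_rank``, sorted by gene id.
    """
    if mean_mode not in ("mean_of_logs", "log_of_means"):
        raise ParameterError(f"unknown mean_mode {mean_mode!r}")
    if records["gene"].isna().any():
        raise ParameterError("records lack gene annotation; pass library to compute_lfc")
    if not include_controls and "is_control" in records.columns:
        records = records[~records["is_control"].astype(bool)]
    if library is not None:
        known = set(library.genes)
        stray = set(records["gene"]) - known
        if stray:
            raise ParameterError(f"gene(s) not in library: {sorted(stray)[:10]}")
    rows = []
    for gene, grp in records.groupby("gene", sort=True):
        lfc = grp["lfc"].to_numpy(float)
        n = len(lfc)
        if n == 0:
            continue
        if mean_mode == "mean_of_logs":
            mean_lfc = float(lfc.mean())
        else:
            mean_lfc = float(
                np.log2(
                    (grp["n_drug"].mean() + pseudocount)
                    / (grp["n_control"].mean() + pseudocount)
                )
            )
        s = _strict_sign(mean_lfc)
        k = int(np.sum(_strict_sign(lfc) == s)) if s != 0 else 0
        rows.append(
            {
                "gene": gene,
                "n_guides": n,
                "mean_lfc": mean_lfc,
                "concordance_k": k,
                "terrace_rank": k if s != 0 else 0,
            }
        )
    if not rows:
        warnings.warn("no genes with usable guides", stacklevel=2)
        return pd.DataFrame(
            columns=["n_guides", "mean_lfc", "concordance_k", "terrace_rank"]
        ).rename_axis("gene")
    return pd.DataFrame(rows).set_index("gene")


def terrace_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready terrace chart table.

    Genes with rank 0 (exact-zero mean) are excluded; rows are grouped
    by terrace rank 1..6 (highest first) and ordered by mean_lfc within
    rank (most depleted first), ties broken by gene id.
    """
    if summaries.empty:
        raise ParameterError("summaries is empty")
    t = summaries[summaries["terrace_rank"] >= 1].reset_index()
    t = t.sort_values(
        ["terrace_rank", "mean_lfc", "gene"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return t[["gene", "mean_lfc", "terrace_rank"]].reset_index(drop=True)


def draco_select(
    records: pd.DataFrame,
    library: GuideLibrary | None = None,
    min_concordant: int = DEFAULT_MIN_CONCORDANT,
    proportional: bool = False,
    mean_mode: str = "mean_of_logs",
) -> pd.DataFrame:
    """Apply the four-of-six filter and pick each gene's strongest guide.

    Literal mode (default) keeps genes with concordance_k >=
    `min_concordant` regardless of how many usable guides remain after
    noise filtering (genes with fewer than `min_concordant` usable
    guides can never pass). Proportional mode instead requires
    k/n >= min_concordant/6 with n >= 3.

    For every passing gene the guide with the highest |lfc| (the most
    efficient guide) is reported at its actual signed lfc; ties on
    |lfc| are broken by lexicographic guide_id.

    Returns a DataFrame indexed by gene with columns ``selected_guide,
    selected_lfc, concordance_k, n_guides``.
    """
    if min_concordant < 1:
        raise ParameterError("min_concordant must be >= 1")
    summaries = summarize_genes(records, library, mean_mode=mean_mode)
    if proportional:
        ratio = min_concordant / 6.0
        passed = summaries[
            (summaries["n_guides"] >= 3)
            & (summaries["concordance_k"] / summaries["n_guides"] >= ratio)
        ]
    else:
        passed = summaries[summaries["concordance_k"] >= min_concordant]
    rows = []
    grouped = records.groupby("gene", sort=True)
    for gene in passed.index:
        grp = grouped.get_group(gene).copy()
        grp = grp.assign(_abs=grp["lfc"].abs()).sort_values(
            ["_abs", "guide_id"], ascending=[False, True], kind="mergesort"
        )
        best = grp.iloc[0]
        rows.append(
            {
                "gene": gene,
                "selected_guide": best["guide_id"],
                "selected_lfc": float(best["lfc"]),
                "concordance_k": int(passed.loc[gene, "concordance_k"]),
                "n_guides": int(passed.loc[gene, "n_guides"]),
            }
        )
    cols = ["selected_guide", "selected_lfc", "concordance_k", "n_guides"]
    if not rows:
        return pd.DataFrame(columns=cols).rename_axis("gene")
    return pd.DataFrame(rows).set_index("gene")[cols]


@dataclass
class CandidateList:
    """Ordered candidate genes from one method x timepoint x direction."""

    genes: list[str]
    method: str                  # "terrace" or "draco"
    direction: str               # "depleted" or "enriched"
    timepoint: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def label(self) -> str:
        tp = self.timepoint or "?"
        return f"{self.method}:{tp}:{self.direction}"

    def __len__(self) -> int:
        return len(self.genes)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("candidate list contains duplicate genes")

    def multi_group(self, min_groups: int = 2) -> list[str]:
        """Genes that appeared in at least `min_groups` source lists."""
        return [g for g in self.genes if len(self.provenance.get(g, [])) >= min_groups]


def select_top(
    table: pd.DataFrame,
    method: str,
    direction: str = "depleted",
    n: int = 25,
    min_concordant: int = DEFAULT_MIN_CONCORDANT,
    timepoint: str | None = None,
) -> CandidateList:
    """Pick the n most dropped-out (or enriched) candidate genes.

    ``method="terrace"`` expects gene summaries; genes below
    `min_concordant` terrace rank are excluded and the rest ordered by
    rank (highest first) then mean_lfc (ascending for depleted,
    descending for enriched). ``method="draco"`` expects the
    :func:`draco_select` output and orders by selected_lfc alone.
    Ties always fall back to lexicographic gene id.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if direction not in DIRECTIONS:
        raise ParameterError(f"direction must be one of {DIRECTIONS}")
    ascending = direction == "depleted"
    if method == "terrace":
        pool = table[table["terrace_rank"] >= min_concordant].reset_index()
        pool = pool.sort_values(
            ["terrace_rank", "mean_lfc", "gene"],
            ascending=[False, ascending, True],
            kind="mergesort",
        )
        score_col = "mean_lfc"
    elif method == "draco":
        pool = table.reset_index().sort_values(
            ["selected_lfc", "gene"], ascending=[ascending, True], kind="mergesort"
        )
        score_col = "selected_lfc"
    else:
        raise ParameterError(f"unknown method {method!r}")
    if direction == "depleted":
        pool = pool[pool[score_col] < 0]
    else:
        pool = pool[pool[score_col] > 0]
    if len(pool) < n:
        warnings.warn(
            f"only {len(pool)} eligible genes for {method}/{direction} "
            f"(requested {n})",
            stacklevel=2,
        )
    top = pool.head(n)
    genes = list(top["gene"])
    return CandidateList(
        genes=genes,
        method=method,
        direction=direction,
        timepoint=timepoint,
        scores=dict(zip(genes, top[score_col].astype(float))),
    )


def merge_candidates(lists: list[CandidateList]) -> CandidateList:
    """Union of candidate lists with per-gene provenance.

    Genes keep first-appearance order across the input lists. The
    provenance records which method x timepoint x direction groups each
    gene came from, so genes appearing in more than one of the groups
    can be flagged as particularly robust candidates.
    """
    if not lists:
        raise ParameterError("need at least one candidate list")
    genes: list[str] = []
    provenance: dict[str, list[str]] = {}
    scores: dict[str, float] = {}
    for cl in lists:
        for g in cl.genes:
            if g not in provenance:
                genes.append(g)
                provenance[g] = []
            provenance[g].append(cl.label)
            scores.setdefault(g, cl.scores.get(g, float("nan")))
    methods = sorted({cl.method for cl in lists})
    directions = sorted({cl.direction for cl in lists})
    return CandidateList(
        genes=genes,
        method="+".join(methods),
        direction=directions[0] if len(directions) == 1 else "+".join(directions),
        timepoint=None,
        scores=scores,
        provenance=provenance,
    )


def gene_subset_view(summaries: pd.DataFrame, genes: set[str]) -> pd.DataFrame:
    """Terrace table restricted to a gene panel (e.g. all OR genes).

    Values are identical to the full-table values for the same genes;
    genes absent from the summaries are dropped (empty result warns).
    """
    genes = set(genes)
    if not genes:
        raise ParameterError("gene subset is empty")
    present = summaries.index.intersection(sorted(genes))
    if present.empty:
        warnings.warn("no subset gene present in summaries", stacklevel=2)
        return pd.DataFrame(columns=["gene", "mean_lfc", "terrace_rank"])
    return terrace_table(summaries.loc[present])
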