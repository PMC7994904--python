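"""Count normalization, noise filtering and screen-quality diagnostics.

Normalization rescales each sample to reads-per-1e7: every guide's
count is divided by the sample total and multiplied by 1e7, so each
positive sample column sums to exactly 1e7 and columns are directly
comparable regardless of sequencing depth.

The noise filter flags guides whose baseline (T0) counts fall strictly
below a read threshold (default 50, about 10% of the expected per-guide
count at 500x coverage); such guides are too poorly sampled at the
start of the screen for their fold-changes to be meaningful and are
removed identically from every downstream arm and timepoint.

Diagnostics: per-sample coverage (reads per guide), replicate Pearson
correlation, and the editing-efficiency check comparing abundance CDFs
of guides targeting a known-essential set (e.g. ribosomal genes)
against the rest of the library — an increasing gap at later timepoints
indicates effective Cas9 editing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .screen_io import CountTable, GuideLibrary

NORMALIZATION_SCALE = 1e7


@dataclass
class NormalizedTable:
    """Guides x samples matrix of reads-per-1e7 normalized abundances."""

    values: pd.DataFrame
    scale: float = NORMALIZATION_SCALE

    @property
    def guide_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class NoiseMask:
    """Boolean per-guide noise flags derived from baseline counts."""

    flagged: pd.Series
    threshold: float
    basis: list[str]

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def fraction_flagged(self) -> float:
        return float(self.flagged.mean()) if len(self.flagged) else 0.0

    def usable(self) -> pd.Index:
        return self.flagged.index[~self.flagged]


def normalize_counts(table: CountTable) -> NormalizedTable:
    """Normalize each sample to reads-per-1e7 of its total.

    Raises
    ------
    ValidationError
        If any sample column is all zero (normalization undefined).
    """
    totals = table.total_reads
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with zero total reads: {list(map(str, zero))}"
        )
    values = table.counts / totals * NORMALIZATION_SCALE
    return NormalizedTable(values=values)


def flag_noisy_guides(
    table: CountTable,
    threshold: float = 50,
    combine: str = "mean",
    t0_samples: list[str] | None = None,
    fraction_of_expected: float | None = None,
) -> NoiseMask:
    """Flag guides with baseline counts strictly below `threshold`.

    Parameters
    ----------
    table
        Raw counts; the T0/baseline columns supply the statistic.
    threshold
        Raw-read cutoff; a guide is noisy when its combined T0 count is
        strictly less than this. Ignored if `fraction_of_expected` set.
    combine
        How multiple T0 replicates are reduced per guide: ``mean``
        (default), ``min``, or ``all-below`` (flag only when every
        replicate is below threshold).
    t0_samples
        Explicit baseline column names; defaults to all samples with
        timepoint T0.
    fraction_of_expected
        Alternative threshold framing: this fraction of the expected
        per-guide count (mean T0 column total / #guides), e.g. 0.1.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    if combine not in ("mean", "min", "all-below"):
        raise ParameterError(f"unknown combine mode {combine!r}")
    if t0_samples is None:
        t0_samples = table.select(timepoint="T0")
    if not t0_samples:
        raise ParameterError("no T0/baseline samples available for noise filtering")
    t0 = table.counts[t0_samples]
    if fraction_of_expected is not None:
        threshold = float(fraction_of_expected) * float(t0.sum(axis=0).mean()) / len(t0)
    if combine == "all-below":
        flagged = (t0 < threshold).all(axis=1)
    else:
        stat = t0.mean(axis=1) if combine == "mean" else t0.min(axis=1)
        flagged = stat < threshold
    return NoiseMask(flagged=flagged, threshold=float(threshold), basis=list(t0_samples))


def replicate_correlation(
    table: CountTable,
    a: str,
    b: str,
    on: str = "normalized",
) -> float:
    """Pearson correlation between two sample columns.

    `on` selects the scale: ``raw`` counts, ``normalized`` (reads per
    1e7, default), or ``log`` (log1p of normalized).
    """
    if on not in ("raw", "normalized", "log"):
        raise ParameterError(f"unknown scale {on!r}")
    if on == "raw":
        x, y = table.counts[a], table.counts[b]
    else:
        norm = normalize_counts(table).values
        x, y = norm[a], norm[b]
        if on == "log":
            x, y = np.log1p(x), np.log1p(y)
    if len(x) < 2:
        raise ParameterError("need at least 2 guides for a correlation")
    if float(np.std(x)) == 0 or float(np.std(y)) == 0:
        raise ValidationError(
            f"zero variance in sample {a if float(np.std(x)) == 0 else b!r}; "
            "Pearson correlation undefined"
        )
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CdfComparison:
    """Empirical abundance CDFs for an essential guide set vs the rest."""

    essential_values: np.ndarray   # sorted abundances, essential-targeting guides
    other_values: np.ndarray       # sorted abundances, all remaining guides
    gap: float                     # max vertical CDF distance (two-sample KS)
    sample_id: str

    def cdf(self, which: str, grid: np.ndarray) -> np.ndarray:
        vals = self.essential_values if which == "essential" else self.other_values
        return np.searchsorted(vals, grid, side="right") / len(vals)


def editing_efficiency_cdf(
    norm: NormalizedTable,
    library: GuideLibrary,
    essential_genes: set[str],
    sample_id: str,
) -> CdfComparison:
    """Compare abundance CDFs of essential-targeting vs other guides.

    Under effective editing, guides knocking out essential genes (the
    canonical choice is ribosome-related genes) deplete over time, so
    the maximum vertical distance between the two CDFs — the two-sample
    Kolmogorov–Smirnov statistic — grows at later timepoints.
    """
    essential_genes = set(essential_genes)
    if not essential_genes:
        raise ParameterError("essential gene set is empty")
    ess_guides = [r.guide_id for r in library if r.gene in essential_genes]
    other_guides = [r.guide_id for r in library if r.gene not in essential_genes]
    if not ess_guides:
        raise ParameterError("no library guide targets the essential set")
    if not other_guides:
        raise ParameterError("essential set must be a strict subset of library genes")
    col = norm.values[sample_id]
    ess = np.sort(col.loc[[g for g in ess_guides if g in col.index]].to_numpy())
    other = np.sort(col.loc[[g for g in other_guides if g in col.index]].to_numpy())
    gap = float(stats.ks_2samp(ess, other, method="asymp").statistic)
    return CdfComparison(
        essential_values=ess, other_values=other, gap=gap, sample_id=sample_id
    )


def coverage_check(
    table: CountTable, min_reads_per_guide: float = 500
) -> pd.DataFrame:
    """Per-sample coverage (total reads / #guides) vs a threshold.

    Screens are designed for >=500 reads per guide so that dropout is
    measurable above sampling noise.
    """
    n = len(table.counts)
    totals = table.total_reads
    coverage = totals / n
    return pd.DataFrame(
        {
            "total_reads": totals,
            "coverage": coverage,
            "passed": coverage >= min_reads_per_guide,
        }
    )


@dataclass
class QcReport:
    """Bundle of screen-quality diagnostics, JSON-serializable."""

    totals: dict[str, int]
    coverage: dict[str, float]
    coverage_passed: dict[str, bool]
    replicate_correlations: dict[str, float] = field(default_factory=dict)
    cdf_gaps: dict[str, float] = field(default_factory=dict)
    n_noisy_guides: int | None = None
    fraction_noisy: float | None = None

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "coverage": self.coverage,
            "coverage_passed": self.coverage_passed,
            "replicate_correlations": self.replicate_correlations,
            "cdf_gaps": self.cdf_gaps,
            "n_noisy_guides": self.n_noisy_guides,
            "fraction_noisy": self.fraction_noisy,
        }


def qc_report(
    table: CountTable,
    library: GuideLibrary,
    essential_genes: set[str] | None = None,
    replicate_pairs: list[tuple[str, str]] | None = None,
    min_reads_per_guide: float = 500,
    noise_threshold: float = 50,
) -> QcReport:
    """Assemble the standard QC bundle for one screen."""
    cov = coverage_check(table, min_reads_per_guide)
    report = QcReport(
        totals={k: int(v) for k, v in table.total_reads.items()},
        coverage={k: float(v) for k, v in cov["coverage"].items()},
        coverage_passed={k: bool(v) for k, v in cov["passed"].items()},
    )
    if replicate_pairs is None:
        t0 = table.select(timepoint="T0")
        replicate_pairs = [(t0[0], t0[1])] if len(t0) >= 2 else []
    for a, b in replicate_pairs:
        report.replicate_correlations[f"{a}~{b}"] = replicate_correlation(table, a, b)
    if essential_genes:
        norm = normalize_counts(table)
        for sid in table.sample_ids:
            report.cdf_gaps[sid] = editing_efficiency_cdf(
                norm, library, essential_genes, sid
            ).gap
    try:
        mask = flag_noisy_guides(table, threshold=noise_threshold)
        report.n_noisy_guides = mask.n_flagged
        report.fraction_noisy = mask.fraction_flagged
    except ParameterError:
        pass  # no T0 samples; noise stats unavailable
    return report
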