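"""Viability-plate processing and the 5-level combo-efficacy ranking.

A 96-well MTS viability plate is reduced to per-condition viability by
subtracting the mean media-only (blank) absorbance from every well and
expressing each well's signal relative to the mean vehicle signal:

    viability% = 100 * (A - mean(blank)) / (mean(vehicle) - mean(blank))

The killing effect is 100 - viability. A drug combination's additive
benefit is the gap, in percentage points, between the combo's killing
and the best (most potent) single agent's killing. The gap maps onto a
five-level efficacy ranking: levels 1-2 for gaps below 20 points,
levels 3-4 for gaps in [20, 30), and level 5 for gaps of 30 points or
more. A combination is called effective only when its killing is
significantly higher than the best single agent's (two-tailed t-test on
replicate wells); a negative gap indicates a rescue-like interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, PlateError, ValidationError

BLANK = "blank"
VEHICLE = "vehicle"
DEFAULT_LEVEL_CUTOFFS = (10.0, 20.0, 25.0, 30.0)


@dataclass
class PlateLayout:
    """Well -> condition-label map with the blank/vehicle conventions.

    Condition labels are free-form (e.g. ``"SI-12 1uM"``,
    ``"combo SI-12+SGI1027"``) except for the reserved ``blank`` and
    ``vehicle`` labels. Wells sharing a label are technical replicates.
    """

    conditions: dict[str, str]

    def __post_init__(self) -> None:
        labels = set(self.conditions.values())
        if BLANK not in labels:
            raise ValidationError("plate layout needs at least one 'blank' well")
        if VEHICLE not in labels:
            raise ValidationError("plate layout needs at least one 'vehicle' well")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        """Build from a long-format table with ``well`` and ``condition``."""
        for col in ("well", "condition"):
            if col not in df.columns:
                raise ValidationError(f"layout table missing column {col!r}")
        return cls(dict(zip(df["well"].astype(str), df["condition"].astype(str))))

    def wells_for(self, condition: str) -> list[str]:
        return [w for w, c in self.conditions.items() if c == condition]

    @property
    def treatments(self) -> list[str]:
        seen = []
        for c in self.conditions.values():
            if c not in (BLANK, VEHICLE) and c not in seen:
                seen.append(c)
        return seen


@dataclass
class ViabilityTable:
    """Per-condition relative viability with replicate-level values."""

    viability: dict[str, np.ndarray]   # condition -> replicate viability %
    clamped_wells: list[str] = field(default_factory=list)

    def mean_viability(self, condition: str) -> float:
        return float(np.mean(self.viability[condition]))

    def killing(self, condition: str) -> np.ndarray:
        return 100.0 - self.viability[condition]

    def mean_killing(self, condition: str) -> float:
        return float(np.mean(self.killing(condition)))

    @property
    def conditions(self) -> list[str]:
        return list(self.viability)


def compute_viability(
    reads: pd.DataFrame, layout: PlateLayout, clamp: bool = True
) -> ViabilityTable:
    """Blank-subtract raw absorbances and normalize to vehicle.

    `reads` is a long-format table with columns ``well`` and
    ``absorbance``. Vehicle viability is 100% by construction;
    negative signals are clamped to 0% viability and flagged.
    """
    for col in ("well", "absorbance"):
        if col not in reads.columns:
            raise ValidationError(f"plate table missing column {col!r}")
    ab = dict(zip(reads["well"].astype(str), reads["absorbance"].astype(float)))
    missing = [w for w in layout.conditions if w not in ab]
    if missing:
        raise ValidationError(f"layout well(s) missing from plate reads: {missing[:5]}")
    blank_mean = float(np.mean([ab[w] for w in layout.wells_for(BLANK)]))
    vehicle_signal = float(
        np.mean([ab[w] - blank_mean for w in layout.wells_for(VEHICLE)])
    )
    if vehicle_signal <= 0:
        raise PlateError("mean vehicle signal is non-positive; plate invalid")
    viability: dict[str, np.ndarray] = {}
    clamped: list[str] = []
    for condition in [VEHICLE] + layout.treatments:
        vals = []
        for w in layout.wells_for(condition):
            v = 100.0 * (ab[w] - blank_mean) / vehicle_signal
            if clamp and v < 0:
                clamped.append(w)
                v = 0.0
            vals.append(v)
        viability[condition] = np.asarray(vals, dtype=float)
    return ViabilityTable(viability=viability, clamped_wells=clamped)


def level_from_gap(
    gap: float, cutoffs: tuple[float, float, float, float] = DEFAULT_LEVEL_CUTOFFS
) -> int:
    """Map an additive-killing gap (percentage points) to level 1-5.

    Only two boundaries are fixed by the ranking scheme itself:
    gap >= 20 implies level >= 3 and gap >= 30 implies level 5; the
    sub-boundaries within [0, 20) and [20, 30) are configurable
    (defaults 10 and 25). Negative gaps (rescue) are level 1.
    """
    c1, c2, c3, c4 = cutoffs
    if not (c1 < c2 < c3 < c4):
        raise ParameterError("level cutoffs must be strictly increasing")
    if gap >= c4:
        return 5
    if gap >= c3:
        return 4
    if gap >= c2:
        return 3
    if gap >= c1:
        return 2
    return 1


@dataclass
class ComboAssessment:
    """Additive-killing verdict for one drug pair on one cell line."""

    combo: str
    single_a: str
    single_b: str
    best_single: str
    gap: float                     # killing(combo) - killing(best single), points
    level: int                     # efficacy level 1-5
    p_value: float                 # two-tailed t-test, combo vs best single
    effective: bool | None         # significant AND positive gap; None if untestable
    rescue: bool                   # gap < 0

    def to_dict(self) -> dict:
        return {
            "combo": self.combo,
            "single_a": self.single_a,
            "single_b": self.single_b,
            "best_single": self.best_single,
            "gap": self.gap,
            "level": self.level,
            "p_value": None if math.isnan(self.p_value) else self.p_value,
            "effective": self.effective,
            "rescue": self.rescue,
        }


def assess_combo(
    v: ViabilityTable,
    combo_condition: str,
    single_a: str,
    single_b: str,
    alpha: float = 0.05,
    equal_var: bool = False,
    cutoffs: tuple[float, float, float, float] = DEFAULT_LEVEL_CUTOFFS,
) -> ComboAssessment:
    """Gap, efficacy level and significance for one combination.

    The gap is measured against the most potent single agent (the one
    with the higher mean killing). Significance is a two-tailed
    two-sample t-test of combo vs best-single replicate killing values
    (Welch by default; `equal_var=True` for pooled-variance Student).
    With fewer than 2 replicates in either group the level is still
    computed but significance — and hence the effective flag — is
    unavailable.
    """
    for c in (combo_condition, single_a, single_b):
        if c not in v.viability:
            raise ParameterError(f"condition {c!r} not on plate")
    ka = v.mean_killing(single_a)
    kb = v.mean_killing(single_b)
    best = single_a if ka >= kb else single_b
    gap = v.mean_killing(combo_condition) - max(ka, kb)
    level = level_from_gap(gap, cutoffs)
    combo_reps = v.killing(combo_condition)
    best_reps = v.killing(best)
    if len(combo_reps) < 2 or len(best_reps) < 2:
        p_value: float = float("nan")
    elif np.var(combo_reps) == 0 and np.var(best_reps) == 0:
        # degenerate (e.g. noiseless synthetic plates): t undefined
        p_value = float("nan")
    else:
        p_value = float(
            stats.ttest_ind(combo_reps, best_reps, equal_var=equal_var).pvalue
        )
    if gap <= 0:
        effective: bool | None = False  # never effective without added killing
    elif math.isnan(p_value):
        effective = None  # significance untestable
    else:
        effective = bool(p_value < alpha)
    return ComboAssessment(
        combo=combo_condition,
        single_a=single_a,
        single_b=single_b,
        best_single=best,
        gap=float(gap),
        level=level,
        p_value=p_value,
        effective=effective,
        rescue=bool(gap < 0),
    )


def efficacy_heatmap(
    assessments: list[tuple[str, str, ComboAssessment]]
) -> pd.DataFrame:
    """Compounds x cell-lines matrix of efficacy levels.

    `assessments` is a list of ``(compound, cell_line, assessment)``
    triples. Missing pairs are left as <NA> (never 0, which would read
    as a level); duplicate pairs are an error.
    """
    if not assessments:
        raise ParameterError("no assessments provided")
    seen = set()
    compounds, lines = [], []
    for compound, line, _ in assessments:
        if (compound, line) in seen:
            raise ValidationError(f"duplicate assessment for {(compound, line)}")
        seen.add((compound, line))
        if compound not in compounds:
            compounds.append(compound)
        if line not in lines:
            lines.append(line)
    matrix = pd.DataFrame(index=compounds, columns=lines, dtype="Int64")
    for compound, line, a in assessments:
        matrix.loc[compound, line] = a.level
    return matrix
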