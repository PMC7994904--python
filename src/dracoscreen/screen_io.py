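"""Guide libraries, count tables and spacer counting.

The countable unit of a pooled CRISPR knockout screen is the sgRNA,
identified by its 20-nt spacer. This module holds the in-memory
containers for a guide library (guide -> gene map with spacers), the
per-sample metadata, and the guides x samples integer count matrix,
together with delimited-text readers/writers and an exact-match spacer
counter for raw FASTQ.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParameterError, ValidationError

SPACER_ALPHABET = frozenset("ACGT")
DEFAULT_SPACER_LENGTH = 20
DEFAULT_ANCHOR = "CACCG"

ARMS = ("vehicle", "drug_A", "drug_B", "baseline")
TIMEPOINTS = ("T0", "T1", "T2", "T3")


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: unique id, 20-nt spacer, target gene (or control label)."""

    guide_id: str
    spacer: str
    gene: str
    is_control: bool = False


class GuideLibrary:
    """Ordered, validated collection of guides with gene/guide lookup.

    Parameters
    ----------
    records
        Guide records; order is preserved and defines the canonical
        guide index of every count table built against this library.
    guides_per_gene
        Expected set size per gene (6 for GeCKOv2-style libraries).
        Informational: actual per-gene counts may differ.
    spacer_length
        Required spacer length; every record is checked against it.
    """

    def __init__(
        self,
        records: Iterable[GuideRecord],
        guides_per_gene: int = 6,
        spacer_length: int = DEFAULT_SPACER_LENGTH,
    ):
        self.records: list[GuideRecord] = list(records)
        self.guides_per_gene = guides_per_gene
        self.spacer_length = spacer_length
        self._by_id: dict[str, GuideRecord] = {}
        self._by_gene: dict[str, list[GuideRecord]] = {}
        self._by_spacer: dict[str, GuideRecord] = {}
        self._validate()

    def _validate(self) -> None:
        dup_ids, dup_spacers = [], []
        for rec in self.records:
            if not rec.gene:
                raise ValidationError(f"guide {rec.guide_id!r} has an empty gene label")
            if len(rec.spacer) != self.spacer_length:
                raise ValidationError(
                    f"guide {rec.guide_id!r}: spacer length {len(rec.spacer)} "
                    f"!= {self.spacer_length}"
                )
            bad = set(rec.spacer) - SPACER_ALPHABET
            if bad:
                raise ValidationError(
                    f"guide {rec.guide_id!r}: spacer contains invalid symbols "
                    f"{sorted(bad)}"
                )
            if rec.guide_id in self._by_id:
                dup_ids.append(rec.guide_id)
                continue
            if rec.spacer in self._by_spacer:
                dup_spacers.append(rec.guide_id)
                continue
            self._by_id[rec.guide_id] = rec
            self._by_spacer[rec.spacer] = rec
            self._by_gene.setdefault(rec.gene, []).append(rec)
        if dup_ids:
            raise ValidationError(f"duplicate guide_id(s): {sorted(dup_ids)}")
        if dup_spacers:
            raise ValidationError(
                f"duplicate spacer(s) on guide_id(s): {sorted(dup_spacers)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GuideRecord]:
        return iter(self.records)

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        return list(self._by_gene)

    def guide(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    def guides_for(self, gene: str) -> list[GuideRecord]:
        return list(self._by_gene[gene])

    def gene_of(self, guide_id: str) -> str:
        return self._by_id[guide_id].gene

    def spacer_index(self) -> dict[str, str]:
        """Map spacer -> guide_id (spacers are unique by construction)."""
        return {s: r.guide_id for s, r in self._by_spacer.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "spacer": [r.spacer for r in self.records],
                "gene": [r.gene for r in self.records],
                "is_control": [r.is_control for r in self.records],
            }
        )


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: arm, timepoint and replicate number."""

    sample_id: str
    arm: str
    timepoint: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if self.arm == "baseline" and self.timepoint != "T0":
            raise ValidationError("baseline samples must carry timepoint T0")
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")


class CountTable:
    """Guides x samples matrix of non-negative integer read counts."""

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleInfo]):
        if list(counts.columns) != [s.sample_id for s in samples]:
            raise ValidationError("count columns do not match sample metadata order")
        keys = [(s.arm, s.timepoint, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (arm, timepoint, replicate) in samples")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = counts
        self.samples = list(samples)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(self, arm: str | None = None, timepoint: str | None = None) -> list[str]:
        """Sample ids matching the given arm and/or timepoint."""
        out = []
        for s in self.samples:
            if arm is not None and s.arm != arm:
                continue
            if timepoint is not None and s.timepoint != timepoint:
                continue
            out.append(s.sample_id)
        return out


@dataclass
class SpacerCountStats:
    """Read-accounting from count_spacers; used for library QC."""

    total_reads: int = 0
    anchor_missing: int = 0
    matched: int = 0
    unmapped: int = 0

    @property
    def conserved(self) -> bool:
        return self.matched + self.unmapped + self.anchor_missing == self.total_reads


def _sep_for(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_library(
    path: str | Path,
    guide_col: str = "guide_id",
    spacer_col: str = "spacer",
    gene_col: str = "gene",
    control_labels: Iterable[str] = ("CTRL", "NonTargeting", "NTC"),
    guides_per_gene: int = 6,
    spacer_length: int = DEFAULT_SPACER_LENGTH,
) -> GuideLibrary:
    """Read a guide library from a delimited text file.

    The file must carry a header with guide id, spacer and gene columns
    (names configurable). An optional boolean ``is_control`` column
    overrides the `control_labels` gene-name matching.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = {guide_col, spacer_col, gene_col} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    controls = set(control_labels)
    if "is_control" in df.columns:
        is_ctrl = df["is_control"].astype(str).str.lower().isin({"true", "1", "yes"})
    else:
        is_ctrl = df[gene_col].isin(controls)
    records = [
        GuideRecord(
            guide_id=str(row[guide_col]),
            spacer=str(row[spacer_col]).upper(),
            gene=str(row[gene_col]),
            is_control=bool(ctrl),
        )
        for (_, row), ctrl in zip(df.iterrows(), is_ctrl)
    ]
    return GuideLibrary(records, guides_per_gene=guides_per_gene, spacer_length=spacer_length)


def write_library(library: GuideLibrary, path: str | Path) -> None:
    path = Path(path)
    library.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_counts(
    path: str | Path,
    library: GuideLibrary,
    samples: Sequence[SampleInfo],
) -> CountTable:
    """Read a guides x samples count table.

    First column holds guide ids; remaining columns must match the
    sample ids in `samples`. Guides present in the library but absent
    from the file get count 0 with a warning (legitimate dropout);
    guides absent from the library are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    sample_ids = [s.sample_id for s in samples]
    missing_cols = set(sample_ids) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing sample column(s) {sorted(missing_cols)}")
    df = df[sample_ids]
    unknown = [g for g in df.index if g not in library]
    if unknown:
        raise ValidationError(
            f"{path}: guide(s) not in library: {sorted(map(str, unknown))[:10]}"
        )
    for col in sample_ids:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (np.mod(vals.fillna(0), 1) != 0)]
        if len(bad):
            raise FormatError(
                f"{path}: non-integer or negative count at row {bad[0]!r}, "
                f"column {col!r}"
            )
    absent = [g for g in library.guide_ids if g not in df.index]
    if absent:
        warnings.warn(
            f"{len(absent)} library guide(s) absent from {path.name}; zero-filled",
            stacklevel=2,
        )
    full = df.reindex(library.guide_ids, fill_value=0).astype(np.int64)
    return CountTable(full, samples)


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a count table as delimited text; round-trip stable."""
    path = Path(path)
    out = table.counts.copy()
    out.index.name = "guide_id"
    out.to_csv(path, sep=_sep_for(path))


def _open_maybe_gzip(path: Path):
    if path.name.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_spacers(
    fastq: str | Path | Sequence[str | Path],
    library: GuideLibrary,
    anchor: str = DEFAULT_ANCHOR,
    anchor_free: bool = False,
    sample: SampleInfo | None = None,
) -> tuple[CountTable, SpacerCountStats]:
    """Count exact spacer matches in FASTQ read(s) for one sample.

    A read contributes one count to the guide whose spacer exactly
    matches the `spacer_length` bases following the first occurrence of
    `anchor` (the vector sequence immediately 5' of the spacer). With
    ``anchor_free=True`` the read is instead scanned for any library
    spacer as a substring. Reads with no anchor and reads whose
    post-anchor k-mer matches no spacer are tallied separately so that
    matched + unmapped + anchor_missing == total reads.
    """
    if sample is None:
        sample = SampleInfo("sample", "baseline", "T0", 1)
    if not anchor_free and not anchor:
        raise ParameterError("anchor must be non-empty unless anchor_free=True")
    paths = [fastq] if isinstance(fastq, (str, Path)) else list(fastq)
    index = library.spacer_index()
    k = library.spacer_length
    counts = dict.fromkeys(library.guide_ids, 0)
    stats = SpacerCountStats()
    for p in paths:
        p = Path(p)
        with _open_maybe_gzip(p) as handle:
            try:
                for rec in SeqIO.parse(handle, "fastq"):
                    seq = str(rec.seq).upper()
                    stats.total_reads += 1
                    if anchor_free:
                        hit = None
                        for i in range(len(seq) - k + 1):
                            gid = index.get(seq[i : i + k])
                            if gid is not None:
                                hit = gid
                                break
                        if hit is None:
                            stats.unmapped += 1
                        else:
                            counts[hit] += 1
                            stats.matched += 1
                        continue
                    pos = seq.find(anchor)
                    if pos < 0 or pos + len(anchor) + k > len(seq):
                        stats.anchor_missing += 1
                        continue
                    start = pos + len(anchor)
                    gid = index.get(seq[start : start + k])
                    if gid is None:
                        stats.unmapped += 1
                    else:
                        counts[gid] += 1
                        stats.matched += 1
            except ValueError as exc:
                raise FormatError(
                    f"{p}: truncated or malformed FASTQ near read "
                    f"{stats.total_reads + 1}: {exc}"
                ) from exc
    df = pd.DataFrame(
        {sample.sample_id: [counts[g] for g in library.guide_ids]},
        index=pd.Index(library.guide_ids, name="guide_id"),
    )
    return CountTable(df, [sample]), stats
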