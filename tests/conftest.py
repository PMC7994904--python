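import numpy as np
import pandas as pd
import pytest

from dracoscreen import (
    CountTable,
    GuideLibrary,
    GuideRecord,
    NormalizedTable,
    SampleInfo,
)

from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_spacer(rng, length=20):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_library():
    """Two genes x 2 guides plus one control guide."""
    return GuideLibrary(
        [
            GuideRecord("g1", "A" * 20, "G1"),
            GuideRecord("g2", "C" * 20, "G1"),
            GuideRecord("g3", "G" * 20, "G2"),
            GuideRecord("g4", "T" * 20, "G2"),
            GuideRecord("g5", "AC" * 10, "CTRL", is_control=True),
        ],
        guides_per_gene=2,
    )


@pytest.fixture
def tiny_samples():
    return [
        SampleInfo("s1", "baseline", "T0", 1),
        SampleInfo("s2", "baseline", "T0", 2),
        SampleInfo("veh", "vehicle", "T1", 1),
        SampleInfo("drug", "drug_A", "T1", 1),
    ]


@pytest.fixture
def tiny_counts(tiny_library, tiny_samples):
    data = pd.DataFrame(
        {
            "s1": [100, 200, 300, 400, 50],
            "s2": [110, 190, 310, 390, 60],
            "veh": [100, 210, 290, 410, 55],
            "drug": [20, 40, 300, 420, 50],
        },
        index=pd.Index(tiny_library.guide_ids, name="guide_id"),
    )
    return CountTable(data, tiny_samples)


def norm_from_values(values: dict[str, list[float]], guide_ids=None) -> NormalizedTable:
    """Build a NormalizedTable directly from per-sample value lists."""
    n = len(next(iter(values.values())))
    idx = guide_ids or [f"g{i}" for i in range(1, n + 1)]
    return NormalizedTable(pd.DataFrame(values, index=pd.Index(idx, name="guide_id")))


def library_for_lfc_sets(lfc_sets: dict[str, list[float]]) -> GuideLibrary:
    """A library with one gene per lfc set, guides named <gene>_i."""
    rng = np.random.default_rng(7)
    records = []
    for gene, lfcs in lfc_sets.items():
        for i in range(len(lfcs)):
            records.append(GuideRecord(f"{gene}_{i+1}", random_spacer(rng), gene))
    return GuideLibrary(records)


def records_frame(lfc_sets: dict[str, list[float]]) -> pd.DataFrame:
    """Fold-change records built directly from per-gene lfc lists."""
    rows = []
    for gene, lfcs in lfc_sets.items():
        for i, x in enumerate(lfcs):
            rows.append(
                {
                    "guide_id": f"{gene}_{i+1}",
                    "gene": gene,
                    "lfc": float(x),
                    "n_drug": 2.0 ** float(x) * 100 - 1,  # consistent with lfc at n_control=99
                    "n_control": 99.0,
                    "is_control": False,
                }
            )
    return pd.DataFrame(rows)
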