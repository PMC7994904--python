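"""Fold-changes, terrace ranking and DRACO selection vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dracoscreen import (
    CandidateList,
    ParameterError,
    compute_lfc,
    draco_select,
    gene_subset_view,
    merge_candidates,
    select_top,
    summarize_genes,
    terrace_table,
)
from tests.conftest import norm_from_values, records_frame


# ---------------------------------------------------------------- oracle

def oracle_summary(lfcs):
    """Naive mean / sign-count / argmax-|lfc| reference implementation."""
    lfcs = list(map(float, lfcs))
    mean = sum(lfcs) / len(lfcs)
    if mean > 0:
        k = sum(1 for x in lfcs if x > 0)
    elif mean < 0:
        k = sum(1 for x in lfcs if x < 0)
    else:
        k = 0
    best = 0
    for i in range(1, len(lfcs)):
        if abs(lfcs[i]) > abs(lfcs[best]):
            best = i
    return mean, k, best


# ---------------------------------------------------------------- compute_lfc

class TestComputeLfc:
    def test_pseudocounted_ratios(self):
        norm = norm_from_values({"veh": [0.0, 1.0, 7.0], "drug": [0.0, 3.0, 1.0]})
        rec = compute_lfc(norm, "drug", "veh")
        assert rec["lfc"].tolist() == pytest.approx([0.0, 1.0, -2.0])

    def test_identical_samples_rejected(self):
        norm = norm_from_values({"a": [1.0, 2.0]})
        with pytest.raises(ParameterError):
            compute_lfc(norm, "a", "a")

    def test_unknown_sample_rejected(self):
        norm = norm_from_values({"a": [1.0], "b": [2.0]})
        with pytest.raises(ParameterError):
            compute_lfc(norm, "a", "nope")


# ---------------------------------------------------------------- summarize

class TestSummarizeGenes:
    def test_worked_example_four_of_six(self):
        rec = records_frame({"G": [-1, -2, -0.5, -3, 0.2, 0.1]})
        s = summarize_genes(rec)
        assert s.loc["G", "mean_lfc"] == pytest.approx(-1.0333333333)
        assert s.loc["G", "concordance_k"] == 4
        assert s.loc["G", "terrace_rank"] == 4

    def test_fully_concordant_gene_ranks_six(self):
        s = summarize_genes(records_frame({"G": [-1, -2, -3, -1, -2, -3]}))
        assert s.loc["G", "terrace_rank"] == 6

    def test_zero_mean_gets_rank_zero_and_is_excluded(self):
        s = summarize_genes(records_frame({"G": [1.0, -1.0], "H": [-1, -2]}))
        assert s.loc["G", "terrace_rank"] == 0
        assert "G" not in set(terrace_table(s)["gene"])

    def test_control_guides_excluded_by_default(self):
        rec = records_frame({"G": [-1, -2]})
        ctrl = records_frame({"CTRL": [0.5] * 10})
        ctrl["is_control"] = True
        s = summarize_genes(pd.concat([rec, ctrl], ignore_index=True))
        assert "CTRL" not in s.index
        s_with = summarize_genes(
            pd.concat([rec, ctrl], ignore_index=True), include_controls=True
        )
        assert "CTRL" in s_with.index

    def test_log_of_means_mode(self):
        # guides at N_drug (3, 1), N_control (1, 3): means equal -> lfc 0
        rec = pd.DataFrame(
            {
                "guide_id": ["g1", "g2"],
                "gene": ["G", "G"],
                "lfc": [1.0, -1.0],
                "n_drug": [3.0, 1.0],
                "n_control": [1.0, 3.0],
                "is_control": [False, False],
            }
        )
        s = summarize_genes(rec, mean_mode="log_of_means")
        assert s.loc["G", "mean_lfc"] == pytest.approx(0.0)
        assert s.loc["G", "terrace_rank"] == 0


# ---------------------------------------------------------------- draco

class TestDracoSelect:
    def test_four_of_six_passes_with_most_extreme_guide(self):
        rec = records_frame({"G": [-1, -2, -0.5, -3, 0.2, 0.1]})
        hits = draco_select(rec)
        assert list(hits.index) == ["G"]
        assert hits.loc["G", "selected_guide"] == "G_4"
        assert hits.loc["G", "selected_lfc"] == pytest.approx(-3.0)
        assert hits.loc["G", "concordance_k"] == 4

    def test_zero_mean_gene_fails(self):
        hits = draco_select(records_frame({"G": [-1, -1, -1, 1, 1, 1]}))
        assert hits.empty

    def test_single_extreme_guide_fails_filter(self):
        """The false positive the concordance filter exists to reject."""
        hits = draco_select(records_frame({"G": [-5, 0.1, 0.2, 0.3, 0.4, 0.5]}))
        assert hits.empty

    def test_selected_lfc_is_signed_not_absolute(self):
        hits = draco_select(records_frame({"G": [-1, -2, -4, -3, -0.2, -0.1]}))
        assert hits.loc["G", "selected_lfc"] == -4.0

    def test_tie_on_abs_breaks_by_guide_id(self):
        hits = draco_select(records_frame({"G": [-2, -2, -1, -1]}), min_concordant=4)
        assert hits.loc["G", "selected_guide"] == "G_1"

    def test_proportional_mode_admits_short_sets(self):
        rec = records_frame({"G": [-1, -2, -3]})  # 3 usable guides, all concordant
        assert draco_select(rec, min_concordant=4).empty
        assert not draco_select(rec, min_concordant=4, proportional=True).empty

    def test_min_concordant_validated(self):
        with pytest.raises(ParameterError):
            draco_select(records_frame({"G": [-1]}), min_concordant=0)

    @given(
        st.lists(
            st.lists(
                st.floats(-10, 10, allow_nan=False, width=32).filter(lambda x: x != 0),
                min_size=1,
                max_size=6,
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_enumeration_oracle(self, lfc_sets):
        sets = {f"G{i:02d}": lfcs for i, lfcs in enumerate(lfc_sets)}
        rec = records_frame(sets)
        summaries = summarize_genes(rec)
        hits = draco_select(rec)
        for gene, lfcs in sets.items():
            mean, k, best = oracle_summary(lfcs)
            assert summaries.loc[gene, "mean_lfc"] == pytest.approx(mean, abs=1e-9)
            assert summaries.loc[gene, "concordance_k"] == k
            if k >= 4:
                assert gene in hits.index
                assert abs(hits.loc[gene, "selected_lfc"]) == pytest.approx(
                    max(abs(x) for x in lfcs)
                )
            else:
                assert gene not in hits.index

    @given(
        st.lists(
            st.floats(-8, 8, allow_nan=False, width=32).filter(lambda x: x != 0),
            min_size=2,
            max_size=6,
        )
    )
    def test_sign_symmetry(self, lfcs):
        """Negating every lfc negates means/selections, preserves k and pass."""
        rec_pos = records_frame({"G": lfcs})
        rec_neg = records_frame({"G": [-x for x in lfcs]})
        sp, sn = summarize_genes(rec_pos), summarize_genes(rec_neg)
        assert sp.loc["G", "mean_lfc"] == pytest.approx(-sn.loc["G", "mean_lfc"])
        assert sp.loc["G", "concordance_k"] == sn.loc["G", "concordance_k"]
        hp, hn = draco_select(rec_pos, min_concordant=2), draco_select(rec_neg, min_concordant=2)
        assert ("G" in hp.index) == ("G" in hn.index)
        if "G" in hp.index:
            assert hp.loc["G", "selected_lfc"] == pytest.approx(
                -hn.loc["G", "selected_lfc"]
            )


# ---------------------------------------------------------------- terraces & top lists

class TestTerraceTable:
    def test_depleted_ordering_within_rank(self):
        s = summarize_genes(
            records_frame({"A": [-1] * 6, "B": [-2] * 6, "C": [-1, -1, 1, 1, -1, -1]})
        )
        t = terrace_table(s)
        assert t["gene"].tolist() == ["B", "A", "C"]  # rank 6 (-12, -6), then rank 4

    def test_single_gene_input(self):
        t = terrace_table(summarize_genes(records_frame({"A": [-1.0]})))
        assert len(t) == 1 and t.loc[0, "terrace_rank"] == 1

    def test_empty_summaries_rejected(self):
        with pytest.raises(ParameterError):
            terrace_table(pd.DataFrame())


class TestSelectTop:
    def test_most_depleted_first(self):
        sets = {g: [m] * 6 for g, m in zip("ABCDE", (-3, -2, -1, 1, 2))}
        s = summarize_genes(records_frame(sets))
        top = select_top(s, "terrace", "depleted", n=2)
        assert top.genes == ["A", "B"]

    def test_enriched_reverses_ordering(self):
        sets = {g: [m] * 6 for g, m in zip("ABCDE", (-3, -2, -1, 1, 2))}
        s = summarize_genes(records_frame(sets))
        top = select_top(s, "terrace", "enriched", n=2)
        assert top.genes == ["E", "D"]

    def test_short_pool_warns(self):
        s = summarize_genes(records_frame({"A": [-1] * 6}))
        with pytest.warns(UserWarning, match="eligible"):
            top = select_top(s, "terrace", "depleted", n=25)
        assert top.genes == ["A"]

    def test_draco_orders_by_selected_lfc(self):
        rec = records_frame({"A": [-1, -1, -1, -4], "B": [-2, -2, -2, -2]})
        hits = draco_select(rec, min_concordant=4)
        top = select_top(hits, "draco", "depleted", n=2)
        assert top.genes == ["A", "B"]  # -4 beats -2

    def test_rank_precedes_mean_for_terrace(self):
        s = summarize_genes(
            records_frame({"LO": [-5, -5, -5, -5, 4.9, 4.9], "HI": [-1] * 6})
        )
        # LO has larger dropout mean but rank 4; HI rank 6 comes first
        top = select_top(s, "terrace", "depleted", n=2)
        assert top.genes == ["HI", "LO"]


class TestMergeCandidates:
    def make(self, genes, method="terrace", tp="T2"):
        return CandidateList(genes=list(genes), method=method, direction="depleted", timepoint=tp)

    def test_disjoint_lists_concatenate(self):
        lists = [
            self.make([f"G{i}{j}" for i in range(25)], tp=tp, method=m)
            for j, (m, tp) in enumerate(
                [("terrace", "T2"), ("terrace", "T3"), ("draco", "T2"), ("draco", "T3")]
            )
        ]
        merged = merge_candidates(lists)
        assert len(merged) == 100
        assert all(len(v) == 1 for v in merged.provenance.values())

    def test_identical_lists_union_once_with_provenance(self):
        a = self.make([f"G{i}" for i in range(25)], tp="T2")
        b = self.make([f"G{i}" for i in range(25)], tp="T3")
        merged = merge_candidates([a, b])
        assert len(merged) == 25
        assert all(len(v) == 2 for v in merged.provenance.values())
        assert merged.multi_group() == merged.genes

    def test_partial_overlap_set_arithmetic(self):
        a = self.make([f"A{i}" for i in range(22)] + ["X", "Y", "Z"], tp="T2")
        b = self.make(["X", "Y", "Z"] + [f"B{i}" for i in range(22)], tp="T3")
        merged = merge_candidates([a, b])
        assert len(merged) == 47
        assert sorted(merged.multi_group()) == ["X", "Y", "Z"]


class TestGeneSubsetView:
    def test_restriction_preserves_values(self):
        sets = {g: [m] * 6 for g, m in zip("ABCD", (-3, -2, -1, 2))}
        s = summarize_genes(records_frame(sets))
        sub = gene_subset_view(s, {"B", "D"})
        full = terrace_table(s).set_index("gene")
        for g in ("B", "D"):
            assert sub.set_index("gene").loc[g, "mean_lfc"] == full.loc[g, "mean_lfc"]
        assert set(sub["gene"]) == {"B", "D"}

    def test_disjoint_subset_warns_empty(self):
        s = summarize_genes(records_frame({"A": [-1] * 6}))
        with pytest.warns(UserWarning):
            sub = gene_subset_view(s, {"NOPE"})
        assert sub.empty
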