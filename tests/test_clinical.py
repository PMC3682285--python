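import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sepsistypes as st
from sepsistypes.errors import DegenerateInputError


def clinical_table(data, sample_ids=None):
    sample_ids = sample_ids or [f"s{i}" for i in range(len(next(iter(data.values()))))]
    return st.ClinicalTable(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing probabilities of tables at most as likely."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestCompareClinical:
    def test_perfectly_separated_binary_attribute(self):
        table = clinical_table({"flag": [1] * 5 + [0] * 5})
        labels = np.array([1] * 5 + [2] * 5)
        out = st.compare_clinical(table, labels)
        row = out[out.attribute == "flag"].iloc[0]
        assert row.p_value == pytest.approx(2 / comb(10, 5), abs=1e-9)
        assert row.subtype_1 == 100.0 and row.subtype_2 == 0.0

    def test_identical_continuous_distributions_p_one(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        table = clinical_table({"age": vals})
        out = st.compare_clinical(table, np.array([1, 1, 1, 2, 2, 2]))
        row = out.iloc[0]
        assert row.type == "continuous"
        assert row.p_value == pytest.approx(1.0)

    def test_single_level_attribute_noted(self):
        table = clinical_table({"always": [1, 1, 1, 1]})
        out = st.compare_clinical(table, np.array([1, 1, 2, 2]))
        assert out.iloc[0].p_value == 1.0 and out.iloc[0].note

    def test_fisher_agrees_with_enumeration_on_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert p_scipy == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-9)

    def test_detects_severe_sepsis_prevalence_gap(self):
        """36% vs 9% prevalence at 250/subtype is nearly always significant."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            x1 = rng.random(250) < 0.36
            x2 = rng.random(250) < 0.09
            table = clinical_table({"severe_sepsis": np.concatenate([x1, x2]).astype(int)},
                                   [f"s{i}" for i in range(500)])
            out = st.compare_clinical(table, np.array([1] * 250 + [2] * 250))
            hits += out.iloc[0].p_value < 0.05
        assert hits >= 95


class TestFoldChanges:
    @pytest.fixture
    def two_group_matrix(self):
        values = np.array([
            [3.0, 3.0, 2.0, 2.0],   # FC 2
            [1.0, 1.0, 1.0, 1.0],   # FC 1
            [0.5, 0.5, 1.5, 1.5],   # FC 0.5
        ])
        return st.ExpressionMatrix(values, ["up", "flat", "down"], list("abcd"))

    def test_reference_values(self, two_group_matrix):
        labels = np.array([1, 1, 2, 2])
        out = st.fold_changes(two_group_matrix, labels, ["up", "flat", "down"])
        assert np.allclose(out.fold_change, [2.0, 1.0, 0.5])

    def test_label_swap_gives_reciprocals(self, two_group_matrix):
        labels = np.array([1, 1, 2, 2])
        genes = ["up", "flat", "down"]
        a = st.fold_changes(two_group_matrix, labels, genes)
        b = st.fold_changes(two_group_matrix, 3 - labels, genes)
        assert np.allclose(a.fold_change.to_numpy() * b.fold_change.to_numpy(), 1.0,
                           atol=1e-10)

    def test_missing_genes_skipped_and_reported(self, two_group_matrix):
        out = st.fold_changes(two_group_matrix, np.array([1, 1, 2, 2]), ["up", "ghost"])
        assert list(out.gene_id) == ["up"]
        assert out.attrs["skipped_genes"] == ["ghost"]

    def test_sam_q_values_attached(self, signal_cohort, signal_matrix):
        r = st.sam_two_class(signal_matrix, signal_cohort.truth_labels,
                             n_permutations=50, seed=0)
        out = st.fold_changes(signal_matrix, signal_cohort.truth_labels,
                              signal_cohort.truth_signal_genes, sam_result=r)
        assert "q_value" in out.columns
        assert np.isfinite(out.q_value).all()


class TestOverrepresentation:
    def test_exact_enumeration_example(self):
        # universe 20, set 5, signature 4, overlap 4 -> 5/4845
        universe = [f"g{i}" for i in range(20)]
        sets = st.GeneSetCollection({"hit": universe[:5]})
        out = st.overrepresentation(universe[:4], sets, universe)
        assert out.iloc[0].p_value == pytest.approx(5 / 4845, rel=1e-9)
        assert out.iloc[0].overlap == 4

    def test_agrees_with_hypergeometric_enumeration(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            set_genes = list(rng.choice(universe, size=rng.integers(3, 10), replace=False))
            sig = list(rng.choice(universe, size=rng.integers(3, 10), replace=False))
            out = st.overrepresentation(sig, st.GeneSetCollection({"s": set_genes}), universe)
            K, n = len(set_genes), len(sig)
            overlap = len(set(set_genes) & set(sig))
            p_enum = sum(
                comb(K, x) * comb(30 - K, n - x) / comb(30, n)
                for x in range(overlap, min(K, n) + 1)
            )
            assert out.iloc[0].p_value == pytest.approx(p_enum, rel=1e-9)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(50)]
        sets = st.GeneSetCollection({"s": universe[:3]})
        out = st.overrepresentation(universe[40:45], sets, universe)
        assert out.iloc[0].p_value == pytest.approx(1.0)

    def test_bonferroni_capped_at_one(self):
        universe = [f"g{i}" for i in range(40)]
        sets = st.GeneSetCollection({f"s{i}": universe[i:i + 5] for i in range(5)})
        out = st.overrepresentation(universe[:5], sets, universe)
        assert np.all(out.bonferroni <= 1.0)
        assert np.allclose(out.bonferroni, np.minimum(1.0, out.p_value * 5))

    def test_p_monotone_decreasing_in_overlap(self):
        universe = [f"g{i}" for i in range(25)]
        set_genes = universe[:8]
        ps = []
        for overlap in range(0, 6):
            sig = set_genes[:overlap] + universe[8:8 + (5 - overlap)]
            out = st.overrepresentation(sig, st.GeneSetCollection({"s": set_genes}), universe)
            ps.append(out.iloc[0].p_value)
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_empty_universe_rejected(self):
        with pytest.raises(DegenerateInputError):
            st.overrepresentation(["g"], st.GeneSetCollection({"s": ["g"]}), [])
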