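"""Pearson statistics, permutation empirical P, and the S/NS/NA/EXCLUDED calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenocoex import (
    LABEL_EXCLUDED,
    LABEL_NA,
    LABEL_NS,
    LABEL_S,
    Thresholds,
    classify_group,
    classify_pair,
    empirical_p,
    pearson_with_p,
)
from phenocoex.expression_data import GroupMatrix


def make_group(data: np.ndarray, genes=None) -> GroupMatrix:
    genes = genes or [f"G{i + 1}" for i in range(data.shape[0])]
    cols = [f"s{j + 1}" for j in range(data.shape[1])]
    return GroupMatrix("L1", "ctrl", pd.DataFrame(data, index=genes, columns=cols))


class TestPearsonWithP:
    def test_perfect_and_inverted_lines(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = pearson_with_p(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-8
        r, _ = pearson_with_p(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula_on_hand_example(self):
        # independent oracle: the definitional sums plus the exact t CDF
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 3, 2, 5, 4])
        xm, ym = x - x.mean(), y - y.mean()
        r_direct = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
        t = r_direct * math.sqrt(3 / (1 - r_direct**2))
        p_direct = 2 * stats.t.sf(abs(t), 3)
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 8, 20])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_pearsonr(self, n, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, p = pearson_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_vector_yields_undefined(self):
        r, p = pearson_with_p(np.ones(5), np.arange(5.0))
        assert math.isnan(r) and math.isnan(p)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_with_p(np.arange(5.0), np.arange(6.0))


class TestEmpiricalP:
    def test_exact_mode_equals_brute_force_enumeration(self, rng):
        """At n=5 the exact mode must agree with an independent scan of all
        120 relative orderings evaluated through scipy."""
        for _ in range(5):
            x, y = rng.lognormal(2, 0.6, 5), rng.lognormal(2, 0.6, 5)
            p_obs = stats.pearsonr(x, y).pvalue
            beats = sum(
                stats.pearsonr(x, np.asarray(perm)).pvalue < p_obs
                for perm in itertools.permutations(y)
            )
            assert empirical_p(x, y, p_obs, exact=True) == pytest.approx(beats / 120)

    def test_bounds_and_p_obs_one(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        emp = empirical_p(x, y, 1.0, n_perm=200, seed=3)
        assert 0.0 <= emp <= 1.0
        assert emp > 0.5  # nearly every permutation has P < 1 on non-degenerate data

    def test_seeded_determinism(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        a = empirical_p(x, y, 0.5, n_perm=200, seed=42)
        b = empirical_p(x, y, 0.5, n_perm=200, seed=42)
        assert a == b

    def test_monotone_in_observed_p(self, rng):
        """On the fixed exact permutation set, a smaller observed P can only
        reduce the beat fraction."""
        x, y = rng.normal(size=5), rng.normal(size=5)
        values = [empirical_p(x, y, p, exact=True) for p in (0.001, 0.01, 0.1, 0.9)]
        assert values == sorted(values)

    def test_strict_inequality_excludes_identity_ordering(self):
        """A perfectly collinear pair beats every non-identity ordering and
        ties itself, so the exact empirical P is exactly zero."""
        x = np.array([1.0, 3.0, 4.0, 7.0, 11.0])
        y = 2 * x + 1
        _, p_obs = pearson_with_p(x, y)
        assert empirical_p(x, y, p_obs, exact=True) == 0.0


class TestClassifyPair:
    def test_all_zero_gene_is_na(self):
        group = make_group(np.array([[0.0] * 5, [1, 2, 3, 4, 5.0]]))
        st = classify_pair(group, "G1", "G2")
        assert st.label == LABEL_NA
        assert math.isnan(st.r) and math.isnan(st.p)

    def test_nonsignificant_band(self):
        group = make_group(np.array([[5, 1, 4, 2, 6.0], [2, 6, 1, 4, 3.0]]))
        st = classify_pair(group, "G1", "G2")
        assert st.p > 0.05
        assert st.label == LABEL_NS
        assert math.isnan(st.emp_p)  # no permutations run outside the S band

    def test_intermediate_band_is_excluded(self):
        # r ~ 0.93 at n=5 sits between 0.005 and 0.05
        group = make_group(np.array([[1, 2, 3, 4, 5.0], [1.1, 2.3, 2.8, 4.5, 4.1]]))
        st = classify_pair(group, "G1", "G2")
        assert 0.005 < st.p < 0.05
        assert st.label == LABEL_EXCLUDED

    def test_significant_pair(self):
        group = make_group(np.array([[1, 3, 4, 7, 11.0], [2.1, 6.1, 8.0, 14.2, 22.1]]))
        st = classify_pair(group, "G1", "G2", seed=1)
        assert st.p < 0.005 and st.emp_p < 0.005
        assert st.label == LABEL_S
        assert st.r_sign == "+"

    def test_constant_nonzero_gene_is_excluded_not_na(self):
        group = make_group(np.array([[2.0] * 5, [1, 2, 3, 4, 5.0]]))
        st = classify_pair(group, "G1", "G2")
        assert st.label == LABEL_EXCLUDED

    def test_too_few_distinct_tuples_is_excluded(self):
        group = make_group(np.array([[0, 0, 0, 0, 1.0], [0, 0, 0, 0, 2.0]]))
        st = classify_pair(group, "G1", "G2")
        assert st.n_distinct == 2
        assert st.label == LABEL_EXCLUDED

    def test_distinct_tuples_counts_value_pairs(self):
        group = make_group(np.array([[0, 0, 0, 1, 2.0], [0, 0, 0, 3, 4.0]]))
        st = classify_pair(group, "G1", "G2")
        assert st.n_distinct == 3
        assert st.n_valid == 2


class TestClassifyGroup:
    def test_pair_count_and_label_partition(self, rng):
        data = rng.lognormal(2, 1, (6, 5))
        data[2] = 0.0
        frame = classify_group(make_group(data))
        assert frame.shape[0] == 15  # C(6,2)
        assert frame["label"].isin([LABEL_S, LABEL_NS, LABEL_NA, LABEL_EXCLUDED]).all()
        assert (frame[frame["label"] == LABEL_NA].shape[0] == 5)  # pairs touching G3

    def test_all_zero_matrix_all_na(self):
        frame = classify_group(make_group(np.zeros((4, 5))))
        assert (frame["label"] == LABEL_NA).all()
        assert frame.shape[0] == 6

    def test_determinism_and_agreement_with_single_pair_path(self, rng):
        data = rng.lognormal(2, 0.8, (8, 5))
        group = make_group(data)
        a = classify_group(group, seed=9)
        b = classify_group(group, seed=9)
        pd.testing.assert_frame_equal(a, b)
        for row in a.sample(6, random_state=0).itertuples():
            st = classify_pair(group, row.gene_a, row.gene_b, seed=9)
            assert st.label == row.label
            if not math.isnan(row.r):
                assert st.r == pytest.approx(row.r, abs=1e-12)

    def test_emp_gate_only_affects_candidate_band(self, rng):
        """With one planted collinear pair the S call appears; everything in
        the NS band carries no empirical P."""
        data = rng.lognormal(2, 0.8, (5, 5))
        data[1] = 2.0 * data[0] + 0.5
        frame = classify_group(make_group(data), seed=2)
        planted = frame[(frame["gene_a"] == "G1") & (frame["gene_b"] == "G2")]
        assert planted["label"].iloc[0] == LABEL_S
        ns = frame[frame["label"] == LABEL_NS]
        assert ns["emp_p"].isna().all()

    def test_too_few_replicates_is_error(self):
        with pytest.raises(ValueError, match="3 replicates"):
            classify_group(make_group(np.ones((2, 2))))

    def test_matrix_scheme_is_deterministic_and_labels_valid(self, rng):
        data = rng.lognormal(2, 0.8, (5, 5))
        data[1] = 2.0 * data[0] + 0.5
        a = classify_group(make_group(data), seed=4, perm_scheme="matrix")
        b = classify_group(make_group(data), seed=4, perm_scheme="matrix")
        pd.testing.assert_frame_equal(a, b)
        assert a["label"].isin([LABEL_S, LABEL_NS, LABEL_NA, LABEL_EXCLUDED]).all()


class TestThresholds:
    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(p_sig=0.5, p_nonsig=0.05)
        with pytest.raises(ValueError):
            Thresholds(n_perm=0)
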