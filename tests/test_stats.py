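from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from sleepkit import (
    CohortSpec,
    condition_comparison,
    generate_cohort,
    spearman_rho,
    split_by_psqi,
    wilcoxon_signed_rank,
)
from sleepkit.exceptions import DegenerateInputError


def wilcoxon_enumeration_oracle(a, b):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2
    w_small = min(w_obs, total - w_obs)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= w_small + 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxonSignedRank:
    def test_identical_samples_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_constant_positive_shift_n6(self):
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        stat, p = wilcoxon_signed_rank(b + 2.0, b)
        assert stat == 0.0
        assert p == pytest.approx(0.03125)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_sign_flip_enumeration_n10(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(wilcoxon_enumeration_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("n", range(5, 13))
    def test_exact_p_matches_enumeration_for_all_small_n(self, n):
        rng = np.random.default_rng(n)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(wilcoxon_enumeration_oracle(a, b), abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        assert spearman_rho([1, 2, 5], [10, 20, 21]) == pytest.approx(1.0)

    def test_antitone_is_minus_one(self, rng):
        x = np.sort(rng.normal(size=20))
        assert spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):  # pragma: no cover
            pytest.skip("degenerate draw")
        oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(base, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSplitByPsqi:
    def _records(self, scores):
        return pd.DataFrame({"subject_id": range(len(scores)), "psqi": scores})

    def test_default_cutoff_splits_cohort_five_five(self):
        poor, good = split_by_psqi(self._records([2, 3, 4, 5, 5, 6, 7, 8, 9, 10]))
        assert len(poor) == 5 and len(good) == 5
        assert poor["psqi"].min() > 5

    def test_cutoff_at_scale_maximum_puts_everyone_in_good(self):
        poor, good = split_by_psqi(self._records([2, 10, 21]), cutoff=21)
        assert len(poor) == 0 and len(good) == 3

    def test_cutoff_zero_with_positive_scores_puts_everyone_in_poor(self):
        poor, good = split_by_psqi(self._records([1, 5, 9]), cutoff=0)
        assert len(poor) == 3 and len(good) == 0


class TestConditionComparison:
    def test_injected_rem_effect_is_detected(self):
        ps = []
        for seed in range(9):
            records, _ = generate_cohort(CohortSpec(seed=seed, conditions=("A", "SH")))
            tab = condition_comparison(records, indices=["rem_min"])
            ps.append(tab.loc["rem_min", "p_value"])
        assert np.median(ps) < 0.05

    def test_null_cohort_renders_with_missing_p_for_identical_values(self):
        records = pd.DataFrame(
            {
                "subject_id": list(range(6)) * 2,
                "condition": ["A"] * 6 + ["SH"] * 6,
                "se": [0.8] * 12,
            }
        )
        tab = condition_comparison(records, indices=["se"])
        assert np.isnan(tab.loc["se", "p_value"])
        assert tab.loc["se", "significance"] == ""

    def test_unpaired_subjects_excluded_with_warning(self):
        records = pd.DataFrame(
            {
                "subject_id": [0, 1, 2, 3, 0, 1, 2],
                "condition": ["A"] * 4 + ["SH"] * 3,
                "rnr": [20, 21, 22, 23, 30, 31, 32],
            }
        )
        with pytest.warns(UserWarning, match="unpaired"):
            tab = condition_comparison(records, indices=["rnr"])
        assert tab.loc["rnr", "n_pairs"] == 3

    def test_direction_aware_comparator_selection(self):
        # ssi is lower-better: SH (lower mean) should be chosen over S
        records = pd.DataFrame(
            {
                "subject_id": list(range(6)) * 3,
                "condition": ["A"] * 6 + ["S"] * 6 + ["SH"] * 6,
                "ssi": list(np.linspace(10, 15, 6))
                + list(np.linspace(12, 17, 6))
                + list(np.linspace(6, 9, 6)),
            }
        )
        tab = condition_comparison(records, indices=["ssi"])
        assert tab.loc["ssi", "comparator"] == "SH"

    def test_significance_stars_follow_thresholds(self):
        records, _ = generate_cohort(CohortSpec(seed=3, conditions=("A", "SH")))
        tab = condition_comparison(records)
        for _, row in tab.iterrows():
            p = row["p_value"]
            if np.isnan(p):
                assert row["significance"] == ""
            elif p < 0.01:
                assert row["significance"] == "**"
            elif p < 0.05:
                assert row["significance"] == "*"
            else:
                assert row["significance"] == ""
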