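"""High-block counts and Mann-Whitney design-effect tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from audlearn import cohort, metrics, states
from audlearn.dynamics import (
    button_effect_test,
    count_state_blocks,
    high_block_counts,
    mann_whitney_u,
    pairwise_config_tests,
    partition_counts,
    significance_category,
)


def brute_force_u(x, y):
    """#{(xi, yj): xi > yj} + half-ties, counted pair by pair."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestMannWhitney:
    def test_small_exact_case(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.U == 0.0
        assert r.p == pytest.approx(1 / 3)
        assert r.method == "exact"

    def test_complete_ties_give_half_u(self):
        r = mann_whitney_u([5.0], [5.0])
        assert r.U == pytest.approx(0.5)  # n1*n2/2
        assert r.method == "normal_tie_corrected"

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, 15).astype(float)
        y = rng.integers(0, 10, 12).astype(float)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.U + b.U == pytest.approx(a.n1 * a.n2)
        assert a.p == pytest.approx(b.p)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.integers(0, 24), min_size=1, max_size=30),
        st.lists(st.integers(0, 24), min_size=1, max_size=30),
    )
    def test_u_matches_all_pairs_count(self, x, y):
        r = mann_whitney_u(x, y)
        assert r.U == pytest.approx(brute_force_u(x, y))
        assert 0 <= r.U <= len(x) * len(y)
        assert 0 <= r.p <= 1

    def test_exact_close_to_normal_approximation(self):
        """Tie-free data with n1, n2 >= 8: enumeration and the corrected
        normal approximation agree within 0.03."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.permutation(np.arange(0, 40, 2.0))[:8]
            y = rng.permutation(np.arange(1, 41, 2.0))[:9]
            from scipy import stats

            exact = stats.mannwhitneyu(x, y, method="exact").pvalue
            approx = stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(exact - approx) < 0.03

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays in [0.03, 0.07] at the
        cohort's group sizes (35 vs 41, tied integer counts)."""
        rng = np.random.default_rng(2)
        n_sims = 1000
        rej = sum(
            mann_whitney_u(rng.binomial(24, 0.5, 35), rng.binomial(24, 0.5, 41)).p < 0.05
            for _ in range(n_sims)
        )
        assert 0.03 <= rej / n_sims <= 0.07


class TestCounts:
    def test_count_state_blocks(self):
        assert count_state_blocks(["high"] * 24, "high") == 24
        assert count_state_blocks(["med", "low"] * 12, "high") == 0
        assert count_state_blocks(["high", "med"] * 12, "high") == 12
        with pytest.raises(ValueError):
            count_state_blocks(["high", "banana"], "high")
        with pytest.raises(ValueError):
            count_state_blocks(["high"], "banana")

    def test_partition_counts(self):
        assert partition_counts(["high"] * 24) == (8, 8, 8)
        seq = ["med"] * 16 + ["high"] * 8
        assert partition_counts(seq) == (0, 0, 8)
        with pytest.raises(ValueError):
            partition_counts(["high"] * 25)

    def test_partitions_sum_to_total(self):
        rng = np.random.default_rng(3)
        seq = [("low", "med", "high")[i] for i in rng.integers(0, 3, 24)]
        parts = partition_counts(seq)
        assert sum(parts) == count_state_blocks(seq, "high")

    def test_high_block_counts_table(self):
        states_df = pd.DataFrame(
            {
                "participant_id": ["a"] * 24 + ["b"] * 24,
                "block_index": list(range(1, 25)) * 2,
                "state": ["high"] * 24 + ["med"] * 24,
            }
        )
        meta = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "config": [1, 2],
                "button": ["left", "right"],
                "label": ["L", "notL"],
            }
        )
        counts = high_block_counts(states_df, meta)
        assert counts.set_index("participant_id").loc["a", "count_total"] == 24
        assert counts.set_index("participant_id").loc["b", "count_total"] == 0
        assert (
            counts[["partition_1", "partition_2", "partition_3"]].sum(axis=1)
            == counts["count_total"]
        ).all()


def _counts_frame(rng, left_counts, right_counts, configs=None):
    n = len(left_counts) + len(right_counts)
    if configs is None:
        configs = rng.integers(1, 5, n)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "config": configs,
            "button": ["left"] * len(left_counts) + ["right"] * len(right_counts),
            "count_total": list(left_counts) + list(right_counts),
        }
    )


class TestButtonEffect:
    def test_extreme_separation_is_significant(self):
        rng = np.random.default_rng(4)
        counts = _counts_frame(rng, [24] * 10, [0] * 10)
        assert button_effect_test(counts).p < 0.001

    def test_u_bounded_by_group_product(self):
        rng = np.random.default_rng(5)
        counts = _counts_frame(rng, rng.integers(0, 25, 35), rng.integers(0, 25, 41))
        r = button_effect_test(counts)
        assert 0 <= r.U <= 35 * 41

    def test_null_p_uniform_on_average(self):
        """Permuted labels: mean p over 1000 permutations is near 0.5."""
        rng = np.random.default_rng(6)
        base = rng.integers(0, 25, 76)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(base)
            ps.append(mann_whitney_u(perm[:35], perm[35:]).p)
        assert 0.45 <= float(np.mean(ps)) <= 0.6

    def test_single_button_cohort_rejected(self):
        rng = np.random.default_rng(7)
        counts = _counts_frame(rng, [1, 2, 3], [])
        with pytest.raises(ValueError):
            button_effect_test(counts)


class TestPairwiseConfigs:
    def test_identical_groups_not_significant(self):
        configs = np.repeat([1, 2, 3, 4], 10)
        counts = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(40)],
                "config": configs,
                "button": ["left", "right"] * 20,
                "count_total": [12] * 40,
            }
        )
        mat = pairwise_config_tests(counts)
        assert (mat["category"] == "n.s.").all()

    def test_p_symmetric_and_u_complementary(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(40)],
                "config": np.repeat([1, 2, 3, 4], 10),
                "button": ["left", "right"] * 20,
                "count_total": rng.integers(0, 25, 40),
            }
        )
        mat = pairwise_config_tests(counts).set_index(["config_a", "config_b"])
        for a in range(1, 5):
            for b in range(a + 1, 5):
                ab, ba = mat.loc[(a, b)], mat.loc[(b, a)]
                assert ab["p"] == pytest.approx(ba["p"])
                assert ab["U"] + ba["U"] == pytest.approx(100)

    def test_dominant_config_flagged(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(40)],
                "config": np.repeat([1, 2, 3, 4], 10),
                "button": ["left", "right"] * 20,
                "count_total": np.concatenate(
                    [rng.integers(0, 8, 30), rng.integers(18, 25, 10)]
                ),
            }
        )
        mat = pairwise_config_tests(counts)
        flagged = mat[(mat["config_a"] == 4) & (mat["category"] == "significant")]
        assert len(flagged) == 3

    def test_missing_config_group_rejected(self):
        counts = pd.DataFrame(
            {
                "participant_id": ["p0", "p1"],
                "config": [1, 2],
                "button": ["left", "right"],
                "count_total": [3, 4],
            }
        )
        with pytest.raises(ValueError):
            pairwise_config_tests(counts)

    def test_significance_bands(self):
        assert significance_category(0.01) == "significant"
        assert significance_category(0.05) == "marginal"
        assert significance_category(0.19) == "marginal"
        assert significance_category(0.2) == "n.s."


class TestPlantedEffectDetection:
    def test_boosted_config_flagged_in_most_cohorts(self):
        """A planted transition boost toward the high state for one target
        configuration is flagged as significant by the pairwise matrix in
        >=90% of 50 simulated cohorts (full generate -> metrics -> states
        -> dynamics chain)."""
        base = cohort.LearnerProfile(
            initial_state_distribution=np.array([0.5, 0.5, 0.0]),
            transition_matrix=np.array(
                [[0.60, 0.35, 0.05], [0.20, 0.60, 0.20], [0.10, 0.30, 0.60]]
            ),
        )
        flagged = 0
        for seed in range(50):
            recs = cohort.generate_cohort(
                effects=cohort.CohortEffects(config={3: 0.25}, button={}),
                master_seed=seed,
                learner_profile=base,
                nonlearner_profile=base,
            )
            frame = cohort.cohort_to_frame(recs)
            blocks = metrics.block_series_frame(frame, "sensitivity", 10)
            model = states.fit_gmm_em(blocks["value"].to_numpy(), 3, seed=seed)
            blocks["state"] = states.state_labels(model, blocks["value"].to_numpy())
            meta = frame.drop_duplicates("participant_id")[
                ["participant_id", "config", "button", "label"]
            ]
            counts = high_block_counts(blocks, meta)
            mat = pairwise_config_tests(counts)
            if (mat.loc[mat["config_a"] == 3, "category"] == "significant").any():
                flagged += 1
        assert flagged >= 45
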