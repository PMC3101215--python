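import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adapart import (
    Block,
    Mode,
    Partition,
    TimeCourse,
    block_negloglik,
    block_stats,
    estimate_variance,
    from_long_format,
    partition_objective,
)
from adapart.timecourse import block_objective, make_partition


class TestFromLongFormat:
    def test_sorting_and_grouping(self):
        tc = from_long_format([(2, 5), (1, 3), (2, 7)])
        assert tc.times.tolist() == [1.0, 2.0]
        assert tc.observations[0].tolist() == [3.0]
        assert tc.observations[1].tolist() == [5.0, 7.0]
        assert tc.m.tolist() == [1, 2]
        assert tc.N == 3

    def test_binary_grouping(self):
        tc = from_long_format([(1, 0), (1, 1)], mode="binary")
        assert tc.times.tolist() == [1.0]
        assert tc.observations[0].tolist() == [0.0, 1.0]

    def test_empty_input(self):
        with pytest.raises(ValueError, match="no observations"):
            from_long_format([])

    def test_binary_rejects_other_values(self):
        with pytest.raises(ValueError, match="record 2"):
            from_long_format([(1, 0), (1, 2)], mode="binary")

    def test_duplicate_times_rejected_in_constructor(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeCourse([1, 1], [[0], [1]])


class TestBlockStats:
    def test_simple_block(self):
        tc = from_long_format([(1, 1), (1, 2), (2, 3), (2, 4)])
        count, mean, sse = block_stats(tc, Block(1, 2))
        assert count == 4
        assert mean == pytest.approx(2.5)
        assert sse == pytest.approx(5.0)  # 2*1.5^2 + 2*0.5^2

    def test_single_observation_sse_zero(self):
        tc = from_long_format([(1, 3.7)])
        _, mean, sse = block_stats(tc, Block(1, 1))
        assert mean == 3.7
        assert sse == 0.0

    def test_prefix_matches_direct_two_pass(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            obs = [rng.normal(0, 5, size=int(rng.integers(1, 6))) for _ in range(n)]
            tc = TimeCourse(np.arange(1, n + 1), obs)
            a = int(rng.integers(1, n + 1))
            b = int(rng.integers(a, n + 1))
            pooled = np.concatenate(obs[a - 1 : b])
            _, mean, sse = block_stats(tc, Block(a, b))
            # independent oracle: direct two-pass sum of squared deviations
            direct = float(np.sum((pooled - pooled.mean()) ** 2))
            assert mean == pytest.approx(pooled.mean(), rel=1e-12)
            assert sse == pytest.approx(direct, rel=1e-9, abs=1e-9)

    def test_block_beyond_n_rejected(self):
        tc = from_long_format([(1, 0), (2, 1)])
        with pytest.raises(ValueError):
            block_stats(tc, Block(1, 3))


class TestBlockNegloglik:
    def test_three_of_ten(self):
        tc = from_long_format([(1, 1)] * 3 + [(1, 0)] * 7, mode="binary")
        assert block_negloglik(tc, Block(1, 1)) == pytest.approx(6.1086, abs=1e-4)

    def test_all_failures_is_zero(self):
        tc = from_long_format([(1, 0)] * 5, mode="binary")
        assert block_negloglik(tc, Block(1, 1)) == 0.0

    def test_even_split(self):
        tc = from_long_format([(1, 1)] * 5 + [(1, 0)] * 5, mode="binary")
        assert block_negloglik(tc, Block(1, 1)) == pytest.approx(10 * math.log(2))

    def test_rejected_on_continuous_data(self):
        tc = from_long_format([(1, 0.5)])
        with pytest.raises(ValueError, match="binary objective on continuous data"):
            block_negloglik(tc, Block(1, 1))


class TestPartitionObjective:
    def test_single_block_equals_block_sse(self, two_level_tc):
        p = Partition((Block(1, 4),))
        assert partition_objective(two_level_tc, p) == pytest.approx(
            block_stats(two_level_tc, Block(1, 4))[2]
        )

    def test_all_singletons(self, two_level_tc):
        p = Partition(tuple(Block(i, i) for i in range(1, 5)))
        expected = sum(block_stats(two_level_tc, Block(i, i))[2] for i in range(1, 5))
        assert partition_objective(two_level_tc, p) == pytest.approx(expected)

    def test_non_covering_rejected(self, two_level_tc):
        with pytest.raises(ValueError):
            partition_objective(two_level_tc, Partition((Block(1, 3),)))
        with pytest.raises(ValueError):
            Partition((Block(1, 2), Block(4, 4)))
        with pytest.raises(ValueError):
            Partition((Block(2, 4),))

    def test_refinement_never_increases_objective(self, random_tc):
        # enumerate every partition of small random instances; any refinement
        # has objective <= its coarsening
        rng = np.random.default_rng(7)
        for _ in range(10):
            tc = random_tc(rng, n=5)
            n = tc.n
            parts = {}
            for mask in range(1 << (n - 1)):
                starts = [1] + [i + 2 for i in range(n - 1) if (mask >> i) & 1]
                ends = [s - 1 for s in starts[1:]] + [n]
                blocks = tuple(Block(a, b) for a, b in zip(starts, ends))
                parts[mask] = partition_objective(tc, Partition(blocks))
            for mask, obj in parts.items():
                for sub in range(1 << (n - 1)):
                    if sub & mask == mask and sub != mask:  # sub refines mask
                        assert parts[sub] <= obj + 1e-9


class TestEstimateVariance:
    def test_formula(self):
        tc = from_long_format([(i, float(v)) for i in range(1, 7) for v in (0, 1)])
        assert tc.N == 12
        assert estimate_variance(tc, 8.0) == pytest.approx(8.0 / 12.0)

    def test_zero_sse(self):
        tc = from_long_format([(1, 0), (2, 0)])
        assert estimate_variance(tc, 0.0) == 0.0

    def test_binary_mode_rejected(self):
        tc = from_long_format([(1, 0), (2, 1)], mode="binary")
        with pytest.raises(ValueError):
            estimate_variance(tc, 1.0)


class TestFitResultInvariants:
    def test_pointwise_reconstructs_blocks(self, two_level_tc):
        from adapart import fit_dp

        fit = fit_dp(two_level_tc, 0.05)
        for k, b in enumerate(fit.partition.blocks):
            seg = fit.pointwise_estimates[b.start - 1 : b.end]
            assert np.all(seg == fit.block_estimates[k])

    def test_objective_additivity_and_sigma2(self, two_level_tc):
        from adapart import fit_dp

        fit = fit_dp(two_level_tc, 0.05)
        assert fit.objective == pytest.approx(
            partition_objective(two_level_tc, fit.partition), rel=1e-12
        )
        assert fit.sigma2_hat == pytest.approx(fit.objective / two_level_tc.N)

    def test_change_points_are_left_block_ends(self, two_level_tc):
        from adapart import fit_dp

        fit = fit_dp(two_level_tc, 0.05)
        assert fit.change_points == (2.0,)


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=6),
            st.floats(min_value=-50, max_value=50, allow_nan=False),
        ),
        min_size=1,
        max_size=40,
    )
)
def test_prefix_stats_property(data):
    tc = from_long_format(data)
    # cumulative count at n equals N, and whole-course stats match numpy
    assert tc._pc[-1] == tc.N
    pooled = tc.pooled()
    count, mean, sse = block_stats(tc, Block(1, tc.n))
    assert count == tc.N
    assert mean == pytest.approx(float(pooled.mean()), rel=1e-9, abs=1e-9)
    assert sse == pytest.approx(float(np.sum((pooled - pooled.mean()) ** 2)), rel=1e-9, abs=1e-6)
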