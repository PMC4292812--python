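"""Perturb-and-test simulation: rank-sum oracles, null behaviour, reproducibility."""

import functools
import itertools

import numpy as np
import pytest

from pdxmeth import power, synth


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p by exhaustive enumeration of rank partitions.

    Enumerates every way of assigning the combined ranks to group A and
    computes the probability of a U statistic at least as extreme (per
    tail, doubled and capped).  Valid for tie-free samples.
    """
    combined = sorted(list(a) + list(b))
    n1, n2 = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = _null_u_distribution(n1, n2)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return min(1.0, 2 * min(lo, hi))


@functools.lru_cache(maxsize=None)
def _null_u_distribution(n1, n2):
    us = [
        sum(subset) - n1 * (n1 + 1) / 2
        for subset in itertools.combinations(range(1, n1 + n2 + 1), n1)
    ]
    return np.array(us)


class TestRankSumPvalue:
    def test_identical_groups_p_one(self):
        assert power.rank_sum_pvalue([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_fully_separated_triples(self):
        # only 2 of the 20 rank partitions are as extreme -> p = 0.1
        assert power.rank_sum_pvalue([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_path_matches_enumeration_all_small_cases(self, rng):
        """All no-tie rank arrangements with combined size <= 12 (spot sizes)."""
        for n1, n2 in [(2, 2), (3, 3), (2, 5), (4, 4), (5, 5), (6, 6), (4, 8)]:
            total = n1 + n2
            for subset in itertools.combinations(range(total), n1):
                values = np.arange(1.0, total + 1)
                a = values[list(subset)]
                b = np.delete(values, list(subset))
                assert power.rank_sum_pvalue(a, b) == pytest.approx(
                    exact_ranksum_p(a, b), abs=1e-12
                )

    def test_approximation_close_to_exact(self, rng):
        diffs = []
        for _ in range(200):
            n = int(rng.integers(8, 11))
            a = rng.random(n)
            b = rng.random(n) + rng.normal(0, 0.3)
            exact = exact_ranksum_p(a, b)
            approx = float(power.ranksum_pvalues_matrix(a[None, :], b[None, :])[0])
            diffs.append(abs(approx - exact))
        assert max(diffs) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            power.rank_sum_pvalue([], [1.0])


class TestRanksumMatrix:
    def test_matches_scipy_asymptotic_with_ties(self, rng):
        from scipy import stats

        n = 12
        a = np.round(rng.random((50, n)), 1)  # heavy ties
        b = np.round(rng.random((50, n)), 1)
        mine = power.ranksum_pvalues_matrix(a, b)
        for i in range(50):
            combined = np.concatenate([a[i], b[i]])
            if np.all(combined == combined[0]):
                expected = 1.0
            else:
                expected = stats.mannwhitneyu(
                    a[i], b[i], alternative="two-sided", method="asymptotic"
                ).pvalue
            assert mine[i] == pytest.approx(expected, abs=1e-10)

    def test_singleton_perturbation_never_significant(self, rng):
        """A probe perturbed in 1 of n samples cannot reach p <= 0.05."""
        for n in (5, 15, 30, 50):
            a = rng.random((200, n))
            b = a.copy()
            j = rng.integers(n, size=200)
            rows = np.arange(200)
            b[rows, j] = np.clip(a[rows, j] + 0.51, 0, 1)
            p = power.ranksum_pvalues_matrix(a, b)
            assert p.min() > 0.05


class TestPerturbSample:
    @pytest.fixture()
    def config(self):
        return power.SimConfig(
            n_grid=(5,), n_perturb=100, n_up=50, n_down=50, n_probes=2_000, pool_size=10
        )

    def test_zero_perturbation_identity(self, rng):
        config = power.SimConfig(n_grid=(5,), n_perturb=0, n_up=0, n_down=0)
        beta = rng.random(500)
        out, record = power.perturb_sample(beta, config, rng)
        assert np.array_equal(out, beta) and record.all.size == 0

    def test_exact_counts_and_magnitudes(self, rng, config):
        beta = rng.random(2_000)
        out, record = power.perturb_sample(beta, config, rng)
        diff = out - beta
        assert (diff != 0).sum() == 100
        assert record.up.size == 50 and record.down.size == 50
        assert np.allclose(diff[record.up], 0.51)
        assert np.allclose(diff[record.down], -0.51)
        assert out.min() >= 0 and out.max() <= 1

    def test_shortfall_reported(self, rng):
        config = power.SimConfig(
            n_grid=(5,), n_perturb=80, n_up=40, n_down=40, n_probes=100, pool_size=10
        )
        beta = np.full(100, 0.9)  # no probe can take +0.51
        with pytest.raises(ValueError, match="shortfall"):
            power.perturb_sample(beta, config, rng)


@pytest.fixture(scope="module")
def small_pool():
    model = synth.MethylomeModel(n_probes=5_000, seed=21)
    return synth.SyntheticPool(model, 40)


@pytest.fixture(scope="module")
def small_config():
    # perturbed fraction matches the full-scale default (11,110 / 463,558)
    return power.SimConfig(
        n_grid=(5, 15), n_perturb=120, n_up=60, n_down=60,
        n_probes=5_000, pool_size=40, n_reps=2, seed=21,
    )


class TestRunOneRep:
    def test_zero_perturbation_null_is_exactly_zero(self, small_pool):
        config = power.SimConfig(
            n_grid=(5,), n_perturb=0, n_up=0, n_down=0, n_probes=5_000, pool_size=40
        )
        for n in (5, 10, 20):
            rng = np.random.default_rng(0)
            assert power.run_one_rep(small_pool, n, config, rng) == 0

    def test_count_invariant_to_column_order(self, small_config, rng):
        pool = synth.SyntheticPool(
            synth.MethylomeModel(n_probes=5_000, seed=22), 20
        )
        cols = pool.columns(range(20))
        seed = 123
        a = power.run_one_rep(cols, 15, small_config, np.random.default_rng(seed))
        shuffled = cols[:, rng.permutation(20)]
        b = power.run_one_rep(shuffled, 15, small_config, np.random.default_rng(seed))
        assert a == b

    def test_group_larger_than_pool_rejected(self, small_pool, small_config, rng):
        with pytest.raises(ValueError, match="pool"):
            power.run_one_rep(small_pool, 99, small_config, rng)

    def test_skip_singletons_does_not_change_count(self, small_pool, small_config):
        strict = power.SimConfig(
            **{**small_config.__dict__, "skip_singletons": False}
        )
        for n in (5, 15):
            a = power.run_one_rep(small_pool, n, small_config, np.random.default_rng(7))
            b = power.run_one_rep(small_pool, n, strict, np.random.default_rng(7))
            assert a == b


class TestRunSimulation:
    def test_single_rep_zero_sem(self, small_pool, small_config):
        config = power.SimConfig(**{**small_config.__dict__, "n_reps": 1})
        curve = power.run_simulation(small_pool, config)
        assert (curve.summary["sem"] == 0).all()

    def test_reproducible_under_master_seed(self, small_pool, small_config):
        a = power.run_simulation(small_pool, small_config)
        b = power.run_simulation(small_pool, small_config)
        assert a.raw.equals(b.raw)

    def test_mean_count_decreases_from_n5_to_n50(self):
        model = synth.MethylomeModel(n_probes=8_000, seed=31)
        pool = synth.SyntheticPool(model, 120)
        config = power.SimConfig(
            n_grid=(5, 50), n_perturb=192, n_up=96, n_down=96,
            n_probes=8_000, pool_size=120, n_reps=5, seed=31,
        )
        curve = power.run_simulation(pool, config)
        means = curve.summary.set_index("n")["mean"]
        assert means[50] <= means[5]
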