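"""MDT, median flora age, and the permutation SES-MDT."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import floraphylo as fp
from conftest import clade_table
from _oracles import bootstrap_se


class TestMdt:
    def test_single_genus_identity(self):
        assert fp.mdt(clade_table([10.0], [3])).mdt == pytest.approx(10.0)

    def test_hand_weighted_mean(self):
        # (20·2 + 10·6) / 8 = 12.5
        assert fp.mdt(clade_table([20.0, 10.0], [2, 6])).mdt == pytest.approx(12.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(fp.ValidationError):
            fp.mdt(clade_table([], []))

    def test_nonpositive_count_rejected(self):
        with pytest.raises(fp.ValidationError, match="species_count"):
            clade_table([10.0], [0])

    def test_nonpositive_age_rejected(self):
        with pytest.raises(fp.ValidationError, match="positive"):
            clade_table([0.0], [2])

    def test_duplicate_genus_rejected(self):
        with pytest.raises(fp.ValidationError, match="duplicate"):
            clade_table([1.0, 2.0], [1, 1], genera=["g", "g"])

    @given(
        ages=st.lists(st.floats(0.1, 200.0), min_size=1, max_size=30),
        counts=st.lists(st.integers(1, 50), min_size=1, max_size=30),
        scale=st.integers(1, 7),
    )
    @settings(derandomize=True, max_examples=60)
    def test_bounds_and_count_scale_invariance(self, ages, counts, scale):
        """min age ≤ MDT ≤ max age; multiplying all Sᵢ by a constant is a no-op."""
        n = min(len(ages), len(counts))
        ages, counts = ages[:n], counts[:n]
        base = fp.mdt(clade_table(ages, counts)).mdt
        assert min(ages) - 1e-9 <= base <= max(ages) + 1e-9
        scaled = fp.mdt(clade_table(ages, [c * scale for c in counts])).mdt
        assert scaled == pytest.approx(base, rel=1e-12)

    @given(ages=st.lists(st.floats(0.1, 200.0), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=40)
    def test_equal_counts_reduce_to_plain_mean(self, ages):
        got = fp.mdt(clade_table(ages, [4] * len(ages))).mdt
        assert got == pytest.approx(float(np.mean(ages)), rel=1e-12)

    def test_median_default_unweighted(self):
        t = clade_table([10.0, 20.0, 30.0], [100, 1, 1])
        assert fp.mdt(t).median_age == pytest.approx(20.0)

    def test_weighted_median_variant(self):
        t = clade_table([10.0, 20.0, 30.0], [100, 1, 1])
        assert fp.mdt(t, weighted_median=True).median_age == pytest.approx(10.0)

    def test_per_site_counts_restrict(self):
        t = clade_table([10.0, 30.0], [5, 5], count_s1=[2, 0], count_s2=[1, 3])
        assert fp.mdt(t.for_site("s1")).mdt == pytest.approx(10.0)
        assert fp.mdt(t.for_site("s2")).mdt == pytest.approx(25.0)


class TestSesMdt:
    def test_exhaustive_four_genus_example(self):
        """Pool ages {10,10,10,30}, singleton sample of the age-30 genus."""
        pool = clade_table([10.0, 10.0, 10.0, 30.0], [1, 1, 1, 1])
        s = fp.ses_mdt(pool.subset([pool.genera[3]]), pool, mode="exhaustive")
        assert s.null_mean == pytest.approx(15.0)
        assert s.null_sd == pytest.approx(math.sqrt(75.0))
        assert s.ses == pytest.approx(math.sqrt(3.0), abs=1e-9)
        assert s.n_reps == 4

    def test_sample_equals_pool_degenerate(self):
        pool = clade_table([5.0, 9.0, 13.0], [1, 2, 3])
        s = fp.ses_mdt(pool, pool, n_reps=19, seed=0)
        assert s.null_sd == 0.0 and s.ses == 0.0
        assert s.classification == "degenerate"

    def test_sample_larger_than_pool_rejected(self):
        pool = clade_table([5.0, 9.0], [1, 2])
        big = clade_table([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(fp.ValidationError, match="pool"):
            fp.ses_mdt(big, pool)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_montecarlo_agrees_with_exhaustive(self, seed):
        """MC SES (9999 reps) within 3 bootstrap SEs of exhaustive enumeration."""
        rng = np.random.default_rng(seed)
        pool = fp.simulate_clade_table(n_clades=8, seed=seed + 10)
        sample = pool.subset(list(np.array(pool.genera)[rng.choice(8, 4, replace=False)]))
        ex = fp.ses_mdt(sample, pool, mode="exhaustive")
        mc = fp.ses_mdt(sample, pool, n_reps=9999, seed=seed)
        se = bootstrap_se(
            _null_mdts(pool, 4, 9999, np.random.default_rng(seed)),
            ex.observed,
            lambda obs, nv: (obs - nv.mean()) / nv.std(),
            n_boot=200,
            rng=rng,
        )
        assert abs(mc.ses - ex.ses) < 3 * se

    def test_null_rng_stream_reproducible(self):
        pool = fp.simulate_clade_table(n_clades=12, seed=3)
        sample = pool.subset(pool.genera[:5])
        a = fp.ses_mdt(sample, pool, n_reps=99, seed=42)
        b = fp.ses_mdt(sample, pool, n_reps=99, seed=42)
        assert a == b

    def test_old_shifted_samples_raise_ses_monotonically(self):
        """Shifting a sample's ages upward by δ drives mean SES up."""
        rng = np.random.default_rng(8)
        base = fp.simulate_clade_table(n_clades=30, seed=8)
        means = []
        for delta in (0.0, 5.0, 15.0):
            sess = []
            for rep in range(30):
                idx = rng.choice(30, 8, replace=False)
                df = base.df.iloc[idx].copy()
                df["age_ma"] += delta
                sample = fp.CladeAgeTable(df)
                sess.append(fp.ses_mdt(sample, base, n_reps=199, seed=rng).ses)
            means.append(np.mean(sess))
        assert means[0] < means[1] < means[2]


def _null_mdts(pool, k, n_reps, rng):
    from floraphylo._null import subset_draws

    draws = subset_draws(len(pool), k, n_reps, rng)
    ages, counts = pool.ages[draws], pool.counts[draws]
    return (ages * counts).sum(axis=1) / counts.sum(axis=1)


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (2.10, "ancient"),
            (1.96, "nonsignificant"),   # strict inequality at the threshold
            (-1.95, "nonsignificant"),
            (-1.97, "young"),
            (0.0, "nonsignificant"),
        ],
    )
    def test_threshold_rule(self, value, expected):
        assert fp.classify_flora(value) == expected

    def test_degenerate_passes_through(self):
        pool = clade_table([5.0, 9.0], [1, 2])
        s = fp.ses_mdt(pool, pool, n_reps=9, seed=0)
        assert fp.classify_flora(s) == "degenerate"
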