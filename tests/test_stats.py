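"""Nonparametric statistics against exact enumeration oracles."""

from itertools import combinations, permutations

import numpy as np
import pytest
from scipy import stats as sstats

from eibalance.stats import (iqr_outliers, kruskal_wallis, mann_whitney,
                             mann_whitney_pairwise, bky_fdr, spearman,
                             compare_groups, per_frequency_comparison,
                             significant_ranges)


def brute_force_iqr(values, k=3.0):
    v = np.asarray(values, float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return set(np.flatnonzero((v > q3 + k * iqr) | (v < q1 - k * iqr)))


def brute_force_h(groups):
    pooled = np.concatenate(groups)
    ranks = sstats.rankdata(pooled)
    n = len(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i:i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


class TestIqrOutliers:
    def test_clean_set(self):
        kept, flagged = iqr_outliers([1, 2, 3, 4, 5])
        assert flagged.size == 0 and kept.size == 5

    def test_extreme_flagged(self):
        kept, flagged = iqr_outliers([1, 2, 3, 4, 1000])
        assert list(flagged) == [4]
        assert 1000 not in kept

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_t(df=2, size=rng.integers(5, 40))
        _, flagged = iqr_outliers(v)
        assert set(flagged) == brute_force_iqr(v)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning):
            kept, flagged = iqr_outliers([1.0, 2.0, 1e9])
        assert flagged.size == 0


class TestKruskalWallis:
    def test_identical_values(self):
        h, df, p = kruskal_wallis([[2.0, 2.0], [2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0 and df == 2

    def test_two_groups_exact_h(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(brute_force_h([[1, 2, 3], [4, 5, 6]]))
        assert df == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_h_matches_rank_formula(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.standard_normal(rng.integers(3, 8)) for _ in range(3)]
        h, _, _ = kruskal_wallis(groups)
        assert h == pytest.approx(brute_force_h(groups), abs=1e-10)

    def test_null_p_uniform_under_permutation(self):
        rng = np.random.default_rng(0)
        pooled = rng.standard_normal(45)
        ps = []
        for _ in range(2000):
            rng.shuffle(pooled)
            ps.append(kruskal_wallis([pooled[:15], pooled[15:30],
                                      pooled[30:]])[2])
        assert sstats.kstest(ps, "uniform").pvalue > 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])


class TestMannWhitney:
    def test_textbook_example(self):
        u, ra, rb, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)
        assert (ra, rb) == (1.5, 3.5)

    def test_identical_vectors(self):
        u, ra, rb, p = mann_whitney([5.0, 6.0], [5.0, 6.0])
        assert p == pytest.approx(1.0)
        assert ra == rb

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(5)
        b = rng.standard_normal(6) + 0.5
        u_obs, _, _, p_obs = mann_whitney(a, b)
        # enumerate all C(11,5) group assignments of the pooled sample
        pooled = np.concatenate([a, b])
        n1 = len(a)
        count = total = 0
        for idx in combinations(range(len(pooled)), n1):
            x = pooled[list(idx)]
            y = np.delete(pooled, list(idx))
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
            if min(u, n1 * len(y) - u) <= min(u_obs, n1 * len(y) - u_obs):
                count += 1
            total += 1
        assert p_obs == pytest.approx(count / total, abs=1e-12)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(30)
        ps = [mann_whitney(a, a + shift)[3] for shift in (0.2, 0.7, 1.5)]
        assert ps[0] > ps[1] > ps[2]

    def test_pairwise_reference_layout(self):
        out = mann_whitney_pairwise([1, 2, 3], {"g1": [4, 5], "g2": [0, 1]},
                                    reference_label="HE")
        assert [r.group_b for r in out] == ["g1", "g2"]
        assert all(r.group_a == "HE" for r in out)


class TestBkyFdr:
    def test_all_ones_no_rejection(self):
        assert not bky_fdr(np.ones(20)).any()

    def test_all_tiny_all_rejected(self):
        assert bky_fdr(np.full(100, 1e-8)).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        m = rng.integers(5, 120)
        p = np.concatenate([rng.uniform(0, 1, m),
                            rng.uniform(0, 1e-3, rng.integers(0, 6))])
        rng.shuffle(p)
        mask = bky_fdr(p, q=0.01)
        ref = multipletests(p, alpha=0.01, method="fdr_tsbky")[0]
        np.testing.assert_array_equal(mask, ref)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bky_fdr([0.5, 1.5])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman([1, 2, 3, 4], [9, 7, 5, 3])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        rho, p = spearman(x, y)
        rx, ry = sstats.rankdata(x), sstats.rankdata(y)
        count = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 720, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(rho)


class TestPerFrequency:
    def _spectra(self, shift, n=12, bins=40, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(0, 0.3, size=(n, bins))
        other = rng.lognormal(0, 0.3, size=(n, bins))
        other[:, 5:15] *= np.exp(shift)
        return {"freqs": np.linspace(1, 40, bins), "ref": base, "g": other}

    def test_identical_groups_empty_mask(self):
        rng = np.random.default_rng(1)
        mat = rng.lognormal(0, 0.3, size=(10, 30))
        df = per_frequency_comparison(
            {"freqs": np.linspace(1, 30, 30), "ref": mat, "g": mat.copy()},
            "ref")
        assert not df["significant"].any()

    def test_shifted_band_detected_and_mask_matches_bky(self):
        df = per_frequency_comparison(self._spectra(2.0), "ref")
        sig = df[df.significant]
        assert len(sig) > 0
        assert sig["freq_index"].between(5, 14).all()
        mask = bky_fdr(df["p"].to_numpy(), q=0.01)
        np.testing.assert_array_equal(mask, df["significant"].to_numpy())

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            per_frequency_comparison(
                {"ref": np.ones((4, 10)), "g": np.ones((4, 11))}, "ref")

    def test_significant_ranges_contiguous(self):
        df = per_frequency_comparison(self._spectra(2.5), "ref")
        ranges = significant_ranges(df, "g")
        assert len(ranges) >= 1
        for lo, hi in ranges:
            assert lo <= hi

    def test_family_wise_type_i_control(self):
        """Global null: any-rejection rate across 200 replicate families
        stays at or below 5% at q = 1%."""
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(200):
            a = rng.lognormal(0, 0.3, size=(10, 25))
            b = rng.lognormal(0, 0.3, size=(10, 25))
            df = per_frequency_comparison(
                {"freqs": np.linspace(1, 25, 25), "ref": a, "g": b}, "ref")
            hits += df["significant"].any()
        assert hits / 200 <= 0.05


class TestCompareGroups:
    def test_outliers_removed_before_tests(self):
        groups = {"a": [1.0, 1.1, 1.2, 1.3, 50.0], "b": [1.0, 1.1, 1.2, 1.35]}
        comp = compare_groups(groups, measure="m", reference="a")
        assert comp.p > 0.05  # the outlier no longer drives the comparison
        assert comp.pairwise[0].group_b == "b"

    def test_nan_measures_dropped(self):
        groups = {"a": [0.1, 0.2, np.nan, 0.3], "b": [0.4, 0.5, 0.6]}
        comp = compare_groups(groups, reference="a")
        assert np.isfinite(comp.p)
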