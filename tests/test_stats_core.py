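"""Filtering, imputation, S0 test, permutation FDR, boundary, PCA QC, BH."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trexkit.errors import ConfigurationError, ImputationError
from trexkit.stats_core import TestConfig as TConfig
from trexkit.stats_core import (
    EnrichmentResult,
    ImputeConfig,
    benjamini_hochberg,
    filter_min_valid,
    impute_gaussian_downshift,
    log2_transform,
    pca_qc,
    permutation_fdr,
    significance_boundary,
    two_sample_s0_test,
)


def groups_series(n_a, n_b, names=("A", "B")):
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return pd.Series([names[0]] * n_a + [names[1]] * n_b, index=cols)


def perm_fdr_oracle(data, n_a, s0, alpha):
    """Brute-force exhaustive permutation FDR, written independently."""
    n = data.shape[1]

    def d_stats(idx_a):
        idx_b = [j for j in range(n) if j not in idx_a]
        xa, xb = data[:, list(idx_a)], data[:, idx_b]
        na, nb = xa.shape[1], xb.shape[1]
        diff = xa.mean(1) - xb.mean(1)
        sp2 = ((na - 1) * xa.var(1, ddof=1) + (nb - 1) * xb.var(1, ddof=1)) \
            / (na + nb - 2)
        return diff / (np.sqrt(sp2 * (1 / na + 1 / nb)) + s0)

    obs = np.abs(d_stats(tuple(range(n_a))))
    perms = [np.abs(d_stats(c)) for c in combinations(range(n), n_a)]
    q = np.empty_like(obs)
    for i, c in enumerate(obs):
        fdrs = []
        for thr in obs[obs <= c]:
            n_obs = (obs >= thr).sum()
            n_perm = np.mean([(p >= thr).sum() for p in perms])
            fdrs.append(n_perm / n_obs)
        q[i] = min(1.0, min(fdrs))
    return obs, q


class TestLog2:
    def test_values_and_missing(self):
        table = pd.DataFrame({"s1": [8.0, 1.0, np.nan]})
        out = log2_transform(table)
        assert out["s1"].tolist()[:2] == [3.0, 0.0]
        assert np.isnan(out["s1"].iloc[2])

    def test_nonpositive_present_raises(self):
        with pytest.raises(ValueError):
            log2_transform(pd.DataFrame({"s1": [4.0, 0.0]}))


class TestFilterMinValid:
    def test_kept_when_one_group_complete(self):
        groups = groups_series(3, 5)
        table = pd.DataFrame([[1.0] * 3 + [np.nan] * 5], index=["P1"],
                             columns=groups.index)
        assert list(filter_min_valid(table, groups).index) == ["P1"]

    def test_dropped_when_sparse_everywhere(self):
        groups = groups_series(5, 5)
        row = [1.0, 1.0] + [np.nan] * 3 + [1.0, 1.0] + [np.nan] * 3
        table = pd.DataFrame([row, [np.nan] * 10],
                             index=["P1", "P2"], columns=groups.index)
        assert len(filter_min_valid(table, groups)) == 0

    def test_min_valid_above_group_size_raises(self):
        groups = groups_series(2, 2)
        table = pd.DataFrame([[1.0] * 4], columns=groups.index)
        with pytest.raises(ConfigurationError):
            filter_min_valid(table, groups, min_valid=3)


class TestImputation:
    def test_no_missing_returns_unchanged(self, rng):
        table = pd.DataFrame(rng.normal(20, 2, size=(50, 4)))
        table.columns = [f"s{i}" for i in range(4)]
        out = impute_gaussian_downshift(table, ImputeConfig(seed=1))
        pd.testing.assert_frame_equal(out, table)

    def test_deterministic_and_only_missing_changed(self, rng):
        table = pd.DataFrame(rng.normal(20, 2, size=(200, 4)),
                             columns=list("abcd"))
        mask = rng.random(table.shape) < 0.2
        table = table.mask(mask)
        out1 = impute_gaussian_downshift(table, ImputeConfig(seed=5))
        out2 = impute_gaussian_downshift(table, ImputeConfig(seed=5))
        pd.testing.assert_frame_equal(out1, out2)
        # present cells untouched, all missing filled
        present = table.notna()
        pd.testing.assert_frame_equal(out1[present], table[present])
        assert out1.notna().all().all()

    def test_too_few_observed_names_column(self):
        table = pd.DataFrame({"good": [1.0, 2.0, 3.0],
                              "bad": [5.0, np.nan, np.nan]})
        with pytest.raises(ImputationError, match="bad"):
            impute_gaussian_downshift(table)


class TestS0Test:
    def test_reduces_to_classical_t_at_s0_zero(self, rng):
        for _ in range(25):
            xa = rng.normal(0, 1, size=rng.integers(2, 9))
            xb = rng.normal(0.5, 2, size=rng.integers(2, 9))
            res = two_sample_s0_test(xa, xb, s0=0.0)
            t, p = sps.ttest_ind(xa, xb, equal_var=True)
            assert res["d_stat"] == pytest.approx(t, rel=1e-12)
            assert res["p"] == pytest.approx(p, rel=1e-12)

    def test_identical_groups_give_zero(self):
        x = [1.0, 2.0, 3.0]
        res = two_sample_s0_test(x, x)
        assert res == {"difference": 0.0, "d_stat": 0.0, "p": 1.0}

    def test_d_shrinks_monotonically_with_s0(self, rng):
        xa = rng.normal(1, 1, size=5)
        xb = rng.normal(0, 1, size=5)
        ds = [abs(two_sample_s0_test(xa, xb, s0)["d_stat"])
              for s0 in (0.0, 0.1, 1.0, 10.0, 100.0)]
        assert all(a >= b for a, b in zip(ds, ds[1:]))
        assert ds[-1] < 0.05

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            two_sample_s0_test([1.0], [1.0, 2.0])


class TestPermutationFdr:
    def test_matches_exhaustive_oracle_3v3(self, rng):
        groups = groups_series(3, 3)
        data = rng.normal(0, 1, size=(40, 6))
        data[:5, :3] += 3.0
        table = pd.DataFrame(data, columns=groups.index)
        cfg = TConfig(s0=0.1, n_perm=100, seed=0)  # covers all C(6,3)=20
        res = permutation_fdr(table, groups, cfg)
        assert res.exhaustive and res.n_perm_used == 20
        obs, q = perm_fdr_oracle(data, 3, 0.1, 0.05)
        np.testing.assert_allclose(res.frame["q"].to_numpy(), q, rtol=1e-10)

    def test_deterministic_given_seed(self, rng):
        groups = groups_series(5, 5)
        table = pd.DataFrame(rng.normal(0, 1, size=(100, 10)),
                             columns=groups.index)
        r1 = permutation_fdr(table, groups, TConfig(seed=11))
        r2 = permutation_fdr(table, groups, TConfig(seed=11))
        pd.testing.assert_frame_equal(r1.frame, r2.frame)

    def test_invariants(self, rng):
        groups = groups_series(4, 4)
        data = rng.normal(0, 1, size=(60, 8))
        data[:8, :4] += 4.0
        res = permutation_fdr(pd.DataFrame(data, columns=groups.index), groups,
                              TConfig(seed=2))
        f = res.frame
        assert ((f["q"] >= 0) & (f["q"] <= 1)).all()
        assert (f.loc[f["significant"], "q"] <= res.alpha).all()
        nonzero = f["difference"] != 0
        assert (np.sign(f.loc[nonzero, "d_stat"])
                == np.sign(f.loc[nonzero, "difference"])).all()

    def test_missing_values_rejected(self):
        groups = groups_series(2, 2)
        table = pd.DataFrame([[1.0, np.nan, 2.0, 3.0]], columns=groups.index)
        with pytest.raises(ValueError):
            permutation_fdr(table, groups)


class TestSignificanceBoundary:
    def test_s0_zero_is_horizontal_line(self):
        curve = significance_boundary(0.0, d_cut=2.5, df=8,
                                      diff_grid=np.linspace(0.1, 5, 40))
        expected = -np.log10(2 * sps.t.sf(2.5, 8))
        np.testing.assert_allclose(curve["neg_log10_p"], expected, rtol=1e-10)

    def test_monotone_nonincreasing_and_symmetric(self):
        grid = np.linspace(0.3, 6, 100)
        curve = significance_boundary(0.1, d_cut=2.5, df=8, diff_grid=grid)
        y = curve["neg_log10_p"].to_numpy()
        assert (np.diff(y) <= 1e-12).all()
        mirrored = significance_boundary(0.1, 2.5, 8, -grid)
        np.testing.assert_allclose(mirrored["neg_log10_p"], y)

    def test_unreachable_region_is_infinite(self):
        curve = significance_boundary(0.1, d_cut=2.0, df=8,
                                      diff_grid=[0.05, 0.19, 0.21])
        assert np.isinf(curve["neg_log10_p"].iloc[0])
        assert np.isinf(curve["neg_log10_p"].iloc[1])  # x <= d_cut*s0
        assert np.isfinite(curve["neg_log10_p"].iloc[2])

    def test_boundary_consistent_with_d_rule(self, rng):
        """Volcano points above the curve have |d| >= d_cut and vice versa."""
        s0, d_cut, df = 0.1, 2.5, 8
        for _ in range(200):
            x = rng.uniform(0.3, 4.0)
            se = rng.uniform(0.01, 2.0)
            d = x / (se + s0)
            p = 2 * sps.t.sf(x / se, df)
            ylim = significance_boundary(s0, d_cut, df, [x])["neg_log10_p"][0]
            above = -np.log10(max(p, 1e-300)) >= ylim
            assert above == (d >= d_cut - 1e-9)

    def test_empty_grid(self):
        assert len(significance_boundary(0.1, 2.0, 8, [])) == 0


class TestPcaQc:
    def test_duplicated_replicates_not_flagged(self):
        base = np.arange(30, dtype=float)
        table = pd.DataFrame({f"a{i}": base for i in range(3)}
                             | {f"b{i}": base + 5 for i in range(3)})
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=table.columns)
        res = pca_qc(table, groups)
        assert res.flagged == []

    def test_shifted_replicate_flagged(self, rng):
        data = rng.normal(20, 1, size=(200, 8))
        data[:, 3] += 25.0  # one aberrant replicate
        groups = groups_series(4, 4)
        table = pd.DataFrame(data, columns=groups.index)
        res = pca_qc(table, groups)
        assert res.flagged == ["a3"]

    def test_variance_fractions_sorted_and_bounded(self, rng):
        groups = groups_series(4, 4)
        table = pd.DataFrame(rng.normal(size=(100, 8)), columns=groups.index)
        res = pca_qc(table, groups)
        v = res.variance_fractions
        assert (np.diff(v) <= 1e-12).all()
        assert v.sum() <= 1 + 1e-9

    def test_too_few_samples_raises(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        groups = pd.Series(["A", "A"], index=table.columns)
        with pytest.raises(ConfigurationError):
            pca_qc(table, groups)


class TestBenjaminiHochberg:
    def test_hand_computed_oracle(self):
        q = benjamini_hochberg([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_single_and_equal_pvalues(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), 0.2)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
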