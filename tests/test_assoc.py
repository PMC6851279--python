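"""Mutual-information scan, PLS regression, and simple correlations."""

import numpy as np
import pandas as pd
import pytest

from lacreg.assoc import (
    AssocError,
    SnpMatrix,
    equal_frequency_bins,
    mi_scan,
    mutual_information,
    param_lag_correlations,
    pls_fit,
    pls_permutation_test,
    snp_matrix_from_alignment,
)


def brute_force_mi(x, y):
    """Enumeration oracle: explicit double loop over the joint table."""
    xs, ys = sorted(set(x)), sorted(set(y))
    n = len(x)
    mi = 0.0
    for xv in xs:
        for yv in ys:
            pxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv) / n
            if pxy == 0:
                continue
            px = sum(1 for a in x if a == xv) / n
            py = sum(1 for b in y if b == yv) / n
            mi += pxy * np.log2(pxy / (px * py))
    return mi


class TestMutualInformation:
    def test_perfect_split_is_one_bit(self):
        vals = np.arange(20.0)
        alleles = (vals >= 10).astype(int)
        assert mutual_information(vals, alleles, 2) == pytest.approx(1.0)

    def test_constant_parameter_zero_bits(self):
        assert mutual_information(np.ones(12),
                                  np.array([0, 1] * 6), 2) == 0.0

    def test_matches_enumeration_oracle(self, rng):
        vals = rng.standard_normal(12)
        alleles = rng.integers(0, 3, 12)
        while len(np.unique(alleles)) < 2:
            alleles = rng.integers(0, 3, 12)
        bins = equal_frequency_bins(vals, 2)
        got = mutual_information(vals, alleles, 2)
        assert got == pytest.approx(brute_force_mi(list(alleles), list(bins)),
                                    abs=1e-12)

    def test_invariant_under_monotone_transform_and_relabel(self, rng):
        vals = rng.uniform(1, 10, 16)
        alleles = rng.integers(0, 2, 16)
        while len(np.unique(alleles)) < 2:
            alleles = rng.integers(0, 2, 16)
        base = mutual_information(vals, alleles, 2)
        assert mutual_information(np.log(vals), alleles, 2) == pytest.approx(base)
        assert mutual_information(vals ** 3, alleles, 2) == pytest.approx(base)
        assert mutual_information(vals, 1 - alleles, 2) == pytest.approx(base)

    def test_monomorphic_rejected(self):
        with pytest.raises(AssocError):
            mutual_information(np.arange(8.0), np.zeros(8, dtype=int), 2)


def small_snps(rng, n=12, s=20):
    cols = []
    while len(cols) < s:
        a = rng.integers(0, 2, n)
        if 0 < a.sum() < n:
            cols.append(a)
    return SnpMatrix(strain_labels=[f"S{i}" for i in range(n)],
                     site_positions=np.arange(1, s + 1),
                     alleles=np.column_stack(cols))


class TestMiScan:
    def test_single_site_reduces_to_single_test(self, rng):
        snps_full = small_snps(rng)
        one = SnpMatrix(strain_labels=snps_full.strain_labels,
                        site_positions=snps_full.site_positions[:1],
                        alleles=snps_full.alleles[:, :1])
        pt = pd.DataFrame({"p": rng.standard_normal(12)},
                          index=snps_full.strain_labels)
        res = mi_scan(pt, one, n_perm=499, seed=3)[0]
        assert res.mi.size == 1
        assert 0 < res.p_corrected[0] <= 1

    def test_p_monotone_in_mi(self, rng):
        snps = small_snps(rng, n=16, s=30)
        pt = pd.DataFrame({"p": rng.standard_normal(16)},
                          index=snps.strain_labels)
        res = mi_scan(pt, snps, n_perm=299, seed=1)[0]
        order = np.argsort(-res.mi)
        # ties broken by a single shared draw keep p monotone in MI
        assert np.all(np.diff(res.p_corrected[order]) >= -1e-12)

    def test_linked_copies_identical_mi(self, rng):
        from lacreg.simulate import (SimulationConfig, params_to_table,
                                     sample_params, simulate_snp_matrix)
        cfg = SimulationConfig(seed=31, n_strains=20, n_sites=60,
                               n_causal=1, n_linked=3, effect_size=3.0)
        table = params_to_table(sample_params(cfg))
        snps, registry = simulate_snp_matrix(table, cfg)
        res = mi_scan(np.log10(table[["alpha"]]), snps, n_perm=199, seed=0)[0]
        idx = [list(res.site_positions).index(p) for p in sorted(registry)]
        assert np.allclose(res.mi[idx], res.mi[idx[0]])

    def test_deterministic_given_seed(self, rng):
        snps = small_snps(rng)
        pt = pd.DataFrame({"p": rng.standard_normal(12)},
                          index=snps.strain_labels)
        a = mi_scan(pt, snps, n_perm=199, seed=9)[0]
        b = mi_scan(pt, snps, n_perm=199, seed=9)[0]
        assert np.array_equal(a.p_corrected, b.p_corrected)

    def test_no_overlap_rejected(self, rng):
        snps = small_snps(rng)
        pt = pd.DataFrame({"p": rng.standard_normal(5)},
                          index=[f"X{i}" for i in range(5)])
        with pytest.raises(AssocError):
            mi_scan(pt, snps, n_perm=199)


class TestSnpFromAlignment:
    def test_polymorphic_extraction_with_gaps(self):
        records = {"s1": "ACGTA", "s2": "ACGAA", "s3": "AC-TA"}
        snps = snp_matrix_from_alignment(records)
        # column 3 (gap vs G) and column 4 (T/A) are polymorphic
        assert list(snps.site_positions) == [3, 4]
        assert len(np.unique(snps.alleles[:, 0])) == 2

    def test_unaligned_rejected(self):
        with pytest.raises(AssocError):
            snp_matrix_from_alignment({"a": "ACGT", "b": "ACG"})


class TestPLS:
    def test_single_informative_column(self, rng):
        # other columns sample-orthogonal to y so component 1 is exactly y
        M = rng.standard_normal((20, 5))
        y = M[:, 2].copy()
        yc = (y - y.mean())
        for j in (0, 1, 3, 4):
            M[:, j] -= yc * (M[:, j] @ yc) / (yc @ yc)
        X = pd.DataFrame(M, columns=list("abcde"))
        res = pls_fit(X, y, n_components=2)
        assert res.y_variance_explained[0] == pytest.approx(100.0, abs=1e-8)
        assert res.contributions[2, 0] == pytest.approx(100.0, abs=1e-6)

    def test_two_driver_recovery(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 10)),
                         columns=[f"v{i}" for i in range(10)])
        y = 2.0 * X["v2"] - 1.5 * X["v8"] + 0.2 * rng.standard_normal(30)
        res = pls_fit(X, y, n_components=2)
        top2 = np.argsort(-res.contributions[:, 0])[:2]
        assert {res.variable_names[i] for i in top2} == {"v2", "v8"}
        assert res.contributions[top2, 0].sum() > 50.0

    def test_contributions_sum_to_100(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 7)),
                         columns=[f"v{i}" for i in range(7)])
        y = rng.standard_normal(25)
        res = pls_fit(X, y, n_components=4)
        assert np.allclose(res.contributions.sum(axis=0), 100.0)

    def test_full_rank_equals_ols_r2(self, rng):
        n, p = 24, 6
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"v{i}" for i in range(p)])
        y = rng.standard_normal(n) + X["v0"]
        res = pls_fit(X, y, n_components=p)
        A = np.c_[np.ones(n), X.to_numpy()]
        beta, *_ = np.linalg.lstsq(A, np.asarray(y), rcond=None)
        resid = np.asarray(y) - A @ beta
        yc = np.asarray(y) - np.mean(y)
        r2 = 100.0 * (1 - resid @ resid / (yc @ yc))
        assert res.cumulative_variance_explained[-1] == pytest.approx(
            r2, abs=1e-8)

    def test_cumulative_variance_non_decreasing(self, rng):
        X = pd.DataFrame(rng.standard_normal((22, 8)),
                         columns=[f"v{i}" for i in range(8)])
        y = rng.standard_normal(22)
        res = pls_fit(X, y, n_components=5)
        assert np.all(np.diff(res.cumulative_variance_explained) >= -1e-10)

    def test_matches_sklearn_weights(self, rng):
        sk = pytest.importorskip("sklearn.cross_decomposition")
        X = pd.DataFrame(rng.standard_normal((26, 6)),
                         columns=[f"v{i}" for i in range(6)])
        y = X["v1"] * 1.5 + rng.standard_normal(26)
        res = pls_fit(X, y, n_components=2)
        Xs = (X - X.mean()) / X.std(ddof=0)
        m = sk.PLSRegression(n_components=2, scale=False).fit(
            Xs.to_numpy(), np.asarray(y) - np.mean(y))
        for h in range(2):
            ours = res.x_weights[:, h]
            theirs = m.x_weights_[:, h]
            assert np.allclose(np.abs(ours), np.abs(theirs), atol=1e-8)

    def test_constant_response_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 3)), columns=list("abc"))
        with pytest.raises(AssocError):
            pls_fit(X, np.ones(12))

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(15),
                          "b": np.ones(15),
                          "c": rng.standard_normal(15)})
        res = pls_fit(X, rng.standard_normal(15), n_components=2)
        assert res.dropped_variables == ["b"]
        assert res.variable_names == ["a", "c"]


class TestPLSPermutation:
    def test_strong_signal_minimal_p(self, rng):
        X = pd.DataFrame(rng.standard_normal((24, 6)),
                         columns=[f"v{i}" for i in range(6)])
        y = 3.0 * X["v0"] + 0.1 * rng.standard_normal(24)
        out = pls_permutation_test(X, y, n_perm=199, seed=2)
        assert out["p_component1_variance"] == pytest.approx(1 / 200)

    def test_deterministic(self, rng):
        X = pd.DataFrame(rng.standard_normal((18, 4)),
                         columns=list("abcd"))
        y = rng.standard_normal(18)
        a = pls_permutation_test(X, y, n_perm=199, seed=8)
        b = pls_permutation_test(X, y, n_perm=199, seed=8)
        assert a["p_component1_variance"] == b["p_component1_variance"]
        assert a["p_top2_contribution"] == b["p_top2_contribution"]


class TestCorrelations:
    def test_perfect_lines(self):
        idx = [f"S{i}" for i in range(6)]
        x = pd.DataFrame({"p": [1.0, 2, 3, 4, 5, 6]}, index=idx)
        up = param_lag_correlations(x, pd.Series([2.0, 4, 6, 8, 10, 12],
                                                 index=idx))
        assert up.loc["p", "r"] == pytest.approx(1.0)
        down = param_lag_correlations(
            x, pd.Series([-1.0, -2, -3.001, -4, -5.002, -6], index=idx))
        assert down.loc["p", "r"] == pytest.approx(-1.0, abs=1e-3)

    def test_hand_formula_six_points(self):
        idx = [f"S{i}" for i in range(6)]
        xv = np.array([1.0, 3, 2, 5, 4, 6])
        yv = np.array([2.0, 1, 4, 3, 6, 5])
        r_hand = (np.sum((xv - xv.mean()) * (yv - yv.mean()))
                  / np.sqrt(np.sum((xv - xv.mean()) ** 2)
                            * np.sum((yv - yv.mean()) ** 2)))
        res = param_lag_correlations(pd.DataFrame({"p": xv}, index=idx),
                                     pd.Series(yv, index=idx))
        assert res.loc["p", "r"] == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_flagged(self):
        idx = [f"S{i}" for i in range(5)]
        res = param_lag_correlations(
            pd.DataFrame({"p": np.ones(5)}, index=idx),
            pd.Series([1.0, 2, 3, 4, 5], index=idx))
        assert bool(res.loc["p", "undefined"])
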