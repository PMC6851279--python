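"""Forward promoter model, logic phenotypes, landscape distance/clustering."""

import math

import numpy as np
import pytest

from lacreg.model import (
    DegenerateLandscapeError,
    ExpressionLandscape,
    GridMismatchError,
    InducerGrid,
    ModelError,
    RegulatoryParams,
    cluster_landscapes,
    crp_activity,
    laci_activity,
    landscape_distance,
    logic_phenotype,
    paper_grid,
    predict_expression,
    predict_landscape,
)
from conftest import random_params


def manual_expression(camp, iptg, p: RegulatoryParams) -> float:
    """Independent step-by-step evaluation of A, R, P_act, F_rep, G using
    plain Python floats (the oracle for the vectorized implementation)."""
    A = camp ** p.n / (p.Km_cAMP ** p.n + camp ** p.n) if camp > 0 else 0.0
    R = 1.0 / (1.0 + (iptg / p.Km_IPTG) ** p.m)
    p_act = (p.a + p.a * p.d * p.eta * A) / (1.0 + p.a + p.d * A
                                             + p.a * p.d * p.eta * A)
    f_rep = 1.0 / (1.0 + p.b * R)
    return p.gamma + p.alpha * p_act * f_rep


class TestActivities:
    def test_crp_hill_values(self, example_params):
        p = example_params
        assert crp_activity(0.0, p) == 0.0
        assert crp_activity(p.Km_cAMP, p) == pytest.approx(0.5, abs=1e-15)
        # n = 2, camp = 2 Km -> 4 / 5
        p2 = RegulatoryParams(**{**p.to_dict(), "n": 2.0})
        assert crp_activity(2 * p2.Km_cAMP, p2) == pytest.approx(0.8, abs=1e-15)

    def test_laci_hill_values(self, example_params):
        p = example_params
        assert laci_activity(0.0, p) == 1.0
        assert laci_activity(p.Km_IPTG, p) == pytest.approx(0.5, abs=1e-15)
        p2 = RegulatoryParams(**{**p.to_dict(), "m": 2.0})
        assert laci_activity(2 * p2.Km_IPTG, p2) == pytest.approx(0.2, abs=1e-15)

    def test_monotonicity(self, example_params, rng):
        camp = np.sort(rng.uniform(0, 50, 40))
        iptg = np.sort(rng.uniform(0, 300, 40))
        assert np.all(np.diff(crp_activity(camp, example_params)) >= 0)
        assert np.all(np.diff(laci_activity(iptg, example_params)) <= 0)

    def test_negative_concentration_rejected(self, example_params):
        with pytest.raises(ModelError):
            crp_activity(-1.0, example_params)
        with pytest.raises(ModelError):
            laci_activity(-0.1, example_params)


class TestParams:
    def test_validation(self):
        with pytest.raises(ModelError):
            RegulatoryParams(alpha=0, gamma=0, a=1, b=1, d=1, eta=1, n=1,
                             m=1, Km_cAMP=1, Km_IPTG=1)
        with pytest.raises(ModelError):
            RegulatoryParams(alpha=1, gamma=-1, a=1, b=1, d=1, eta=1, n=1,
                             m=1, Km_cAMP=1, Km_IPTG=1)

    def test_serialization_round_trip(self, rng):
        for _ in range(5):
            p = random_params(rng)
            assert RegulatoryParams.from_json(p.to_json()) == p
            assert RegulatoryParams.from_vector(p.to_vector()) == p


class TestPredictExpression:
    def test_alpha_zero_limit_is_gamma(self, example_params):
        # alpha must stay positive; a tiny alpha approaches the basal rate
        p = RegulatoryParams(**{**example_params.to_dict(), "alpha": 1e-12})
        assert predict_expression(5.0, 50.0, p) == pytest.approx(p.gamma)

    def test_no_repression_no_activation_half(self):
        p = RegulatoryParams(alpha=1.0, gamma=1e-300, a=1.0, b=0.0, d=0.0,
                             eta=1.0, n=1, m=1, Km_cAMP=1, Km_IPTG=1)
        for c, i in [(0, 0), (3, 7), (40, 200)]:
            assert predict_expression(c, i, p) == pytest.approx(0.5, abs=1e-12)

    def test_matches_manual_oracle(self, rng):
        for _ in range(100):
            p = random_params(rng)
            c = float(rng.uniform(0, 40))
            i = float(rng.uniform(0, 200))
            assert predict_expression(c, i, p) == pytest.approx(
                manual_expression(c, i, p), rel=1e-12, abs=1e-12)

    def test_bounded_by_gamma_and_gamma_plus_alpha(self, rng):
        for _ in range(30):
            p = random_params(rng)
            c = float(rng.uniform(0, 100))
            i = float(rng.uniform(0, 1000))
            g = predict_expression(c, i, p)
            assert p.gamma - 1e-9 <= g <= p.gamma + p.alpha + 1e-9


class TestPredictLandscape:
    def test_flat_when_alpha_tiny(self):
        grid = InducerGrid((0.0, 1.0), (0.0, 10.0))
        p = RegulatoryParams(alpha=1e-12, gamma=7.0, a=1, b=1, d=1, eta=1,
                             n=1, m=1, Km_cAMP=1, Km_IPTG=1)
        ls = predict_landscape(grid, p)
        assert np.allclose(ls.values, 7.0)

    def test_paper_grid_shape(self, example_params):
        ls = predict_landscape(paper_grid(), example_params)
        assert ls.values.shape == (8, 10)

    def test_pointwise_idempotence(self, rng):
        p = random_params(rng)
        grid = paper_grid()
        ls = predict_landscape(grid, p)
        again = np.array([[predict_expression(c, i, p)
                           for i in grid.iptg_levels]
                          for c in grid.camp_levels])
        assert np.array_equal(ls.values, again)

    def test_b_zero_flat_along_iptg(self, example_params):
        p = RegulatoryParams(**{**example_params.to_dict(), "b": 0.0})
        ls = predict_landscape(paper_grid(), p)
        assert np.allclose(ls.values, ls.values[:, [0]])

    def test_d_zero_flat_along_camp(self, example_params):
        p = RegulatoryParams(**{**example_params.to_dict(), "d": 0.0})
        ls = predict_landscape(paper_grid(), p)
        assert np.allclose(ls.values, ls.values[[0], :])


def make_corner_landscape(e_ll, e_hl, e_lh, e_hh):
    """2x2 landscape with prescribed corners [camp][iptg]."""
    grid = InducerGrid((0.0, 40.0), (0.0, 200.0))
    values = np.array([[e_ll, e_hl], [e_lh, e_hh]], dtype=float)
    return ExpressionLandscape("corner", grid, values)


class TestLogicPhenotype:
    def test_constant_landscape(self):
        ls = make_corner_landscape(5.0, 5.0, 5.0, 5.0)
        ph = logic_phenotype(ls)
        assert (ph.pi1, ph.pi2, ph.pi3) == (1.0, 1.0, 1.0)
        assert ph.f_iptg == ph.f_camp == 1.0
        assert ph.synergy == pytest.approx(0.0, abs=1e-15)

    def test_corner_values_oracle(self):
        # rescaled corners 100 / 57 / 21 / 1
        ls = make_corner_landscape(1.0, 57.0, 21.0, 100.0)
        ph = logic_phenotype(ls)
        assert ph.f_iptg == pytest.approx(0.57, abs=1e-12)
        assert ph.f_camp == pytest.approx(0.21, abs=1e-12)
        assert ph.synergy == pytest.approx(1 - (0.57 + 0.21 - 0.57 * 0.21),
                                           abs=1e-12)
        assert ph.pi1 == pytest.approx(0.0, abs=1e-12)
        assert ph.pi2 == pytest.approx(math.log10(57) / 2, abs=1e-12)

    def test_scale_invariance(self):
        a = logic_phenotype(make_corner_landscape(1.0, 57.0, 21.0, 100.0))
        b = logic_phenotype(make_corner_landscape(37.0, 57 * 37, 21 * 37, 3700.0))
        assert a.to_vector() == pytest.approx(b.to_vector(), rel=1e-12)

    def test_ideal_and_gate(self):
        ph = logic_phenotype(make_corner_landscape(1.0, 1.0, 1.0, 100.0))
        assert (ph.pi1, ph.pi2, ph.pi3) == (0.0, 0.0, 0.0)
        assert ph.synergy == pytest.approx(1 - (0.01 + 0.01 - 0.0001))

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateLandscapeError):
            logic_phenotype(make_corner_landscape(0, 0, 0, 0))

    def test_and_and_or_morphologies_from_model(self, example_params):
        base = example_params.to_dict()
        and_p = RegulatoryParams(**{**base, "b": 1e4, "d": 100.0, "a": 0.01,
                                    "eta": 1e3, "gamma": 1e-3})
        ph = logic_phenotype(predict_landscape(paper_grid(), and_p))
        assert max(ph.pi1, ph.pi2, ph.pi3) < 0.25
        iptg_only = RegulatoryParams(**{**base, "b": 5e3, "d": 0.0,
                                        "gamma": 1e-3})
        ph2 = logic_phenotype(predict_landscape(paper_grid(), iptg_only))
        assert ph2.pi2 == pytest.approx(1.0, abs=1e-9)


class TestLandscapeDistance:
    def test_identity_and_symmetry(self, rng, example_params):
        grid = paper_grid()
        p2 = random_params(rng)
        x = predict_landscape(grid, example_params, "x")
        y = predict_landscape(grid, p2, "y")
        assert landscape_distance(x, x) == 0.0
        assert landscape_distance(x, y) == landscape_distance(y, x)

    def test_hand_value(self):
        grid = InducerGrid((0.0, 1.0), (0.0, 1.0))
        x = ExpressionLandscape("x", grid, np.array([[0.0, 0.0], [0.0, 1.0]]))
        y = ExpressionLandscape("y", grid, np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert landscape_distance(x, y) == pytest.approx(1.0)

    def test_grid_mismatch(self, example_params):
        a = predict_landscape(paper_grid(), example_params)
        b = predict_landscape(paper_grid(iptg_levels=6), example_params)
        with pytest.raises(GridMismatchError):
            landscape_distance(a, b)

    def test_metric_axioms_on_random_triples(self, rng):
        grid = paper_grid()
        for _ in range(10):
            ls = [predict_landscape(grid, random_params(rng), str(i))
                  for i in range(3)]
            d01 = landscape_distance(ls[0], ls[1])
            d02 = landscape_distance(ls[0], ls[2])
            d12 = landscape_distance(ls[1], ls[2])
            assert d01 >= 0 and d02 >= 0 and d12 >= 0
            assert d02 <= d01 + d12 + 1e-12
            assert d01 <= d02 + d12 + 1e-12


class TestClustering:
    def test_hybrid_clusters_with_recipient(self, example_params):
        grid = paper_grid()
        donor = RegulatoryParams(**{**example_params.to_dict(), "b": 2.0,
                                    "d": 0.5})
        recipient = example_params
        hybrid = RegulatoryParams(**{**example_params.to_dict(),
                                     "alpha": 21000.0})
        ls = [predict_landscape(grid, donor, "donor"),
              predict_landscape(grid, recipient, "recipient"),
              predict_landscape(grid, hybrid, "hybrid")]
        dend = cluster_landscapes(ls)
        assert dend.first_merge_pair() == {"recipient", "hybrid"}
        # merge order agrees with the pairwise-distance oracle
        dm = dend.distance_matrix
        pairs = {frozenset({dend.labels[i], dend.labels[j]}): dm[i, j]
                 for i in range(3) for j in range(i + 1, 3)}
        assert dend.first_merge_pair() == min(pairs, key=pairs.get)

    def test_identical_pair_merges_at_zero(self, example_params):
        grid = paper_grid()
        a = predict_landscape(grid, example_params, "a")
        b = predict_landscape(grid, example_params, "b")
        c_p = RegulatoryParams(**{**example_params.to_dict(), "b": 1.0})
        c = predict_landscape(grid, c_p, "c")
        dend = cluster_landscapes([a, b, c])
        assert dend.first_merge_pair() == {"a", "b"}
        assert dend.merge_heights[0] == 0.0

    def test_merge_heights_non_decreasing(self, rng):
        grid = paper_grid()
        ls = [predict_landscape(grid, random_params(rng), str(i))
              for i in range(3)]
        h = cluster_landscapes(ls).merge_heights
        assert np.all(np.diff(h) >= -1e-12)

    def test_needs_two_landscapes(self, example_params):
        with pytest.raises(ModelError):
            cluster_landscapes([predict_landscape(paper_grid(),
                                                  example_params)])
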