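import numpy as np
import pytest

import zdgames as z
from zdgames.markov import TupleDistribution
from zdgames.zd import RelationCoefficients

from conftest import PAYOFF_GRID, ZD_CATALOG, catalog_strategy, stationary_per_class
from _oracles import brute_force_basis, closed_form_pd


def canonical(alpha_matrix):
    return RelationCoefficients(order=2, n_players=2,
                                alpha=np.asarray(alpha_matrix, float)).canonical()


class TestPDMatrix:
    def test_etft_printed_entries(self):
        m = z.pd_matrix(z.etft(), 1).values.reshape(4, 4)
        expect = np.array([
            [0, 0, 0, 0],
            [-0.5, -1, 0, -0.5],
            [0.5, 1, 0, 0.5],
            [0, 0, 0, 0],
        ])
        assert np.array_equal(m, expect)

    def test_repeat_pd_is_zero(self):
        assert np.all(z.pd_matrix(z.fixed_catalog("repeat"), 1).values == 0)
        assert np.all(z.pd_matrix(z.fixed_catalog("repeat"), 2).values == 0)

    def test_ftft_row2(self, pd_game):
        m = z.pd_matrix(z.ftft(pd_game), 1).values.reshape(4, 4)
        assert np.allclose(m[1], [-1, -5 / 6, -5 / 6, -1 / 3], atol=1e-15)

    def test_action_slices_sum_to_zero(self, pd_game):
        """Normalization makes the PD slices cancel exactly, per history."""
        for name in ZD_CATALOG + ["tft", "tft_atft", "alld", "repeat"]:
            s = catalog_strategy(name, pd_game)
            total = z.pd_matrix(s, 1).values + z.pd_matrix(s, 2).values
            assert np.max(np.abs(total)) <= 1e-15  # a few ulp at most

    def test_bad_action(self):
        with pytest.raises(ValueError):
            z.pd_matrix(z.etft(), 3)


class TestAkinLemma:
    @pytest.mark.parametrize("name", ZD_CATALOG + ["tft", "tft_atft", "alld"])
    @pytest.mark.parametrize("q", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_mean_zero_under_stationarity(self, pd_game, name, q):
        """The PD contraction vanishes for every recurrent class and every
        own action."""
        s = catalog_strategy(name, pd_game)
        _, dists = stationary_per_class(s, z.probe(q), pd_game)
        for action in (1, 2):
            pd = z.pd_matrix(s, action)
            for _, dist in dists:
                assert abs(z.akin_residual(pd, dist)) <= 1e-10

    def test_nonstationary_distribution_nonzero(self, pd_game):
        """The check is not vacuous: a uniform (non-stationary) distribution
        gives a nonzero contraction."""
        probs = np.zeros(16)
        probs[4:8] = 0.25  # all mass on last round (1,2): not stationary
        skewed = TupleDistribution(order=2, n_players=2, n_actions=2,
                                   probs=probs)
        val = z.akin_residual(z.pd_matrix(z.etft(), 1), skewed)
        assert abs(val) > 1e-3

    def test_dimension_mismatch(self, pd_game):
        dist = TupleDistribution(order=1, n_players=2, n_actions=2,
                                 probs=np.full(4, 0.25))
        with pytest.raises(ValueError):
            z.akin_residual(z.pd_matrix(z.etft(), 1), dist)


class TestPayoffBasis:
    def test_shape_and_constant_vector(self, pd_game):
        basis = z.payoff_basis(pd_game, 2)
        assert basis.vectors.shape == (9, 16)
        assert basis.index_tuples[0] == (0, 0)
        assert np.array_equal(basis.vectors[0], np.ones(16))

    def test_printed_product_entry(self, pd_game):
        basis = z.payoff_basis(pd_game, 2)
        i = basis.index_tuples.index((2, 1))
        h = z.profile_flatten((1, 2), 2) * 4 + z.profile_flatten((2, 1), 2)
        # s_2(1,2) * s_1(2,1) = T * T = 25
        assert basis.vectors[i, h] == 25.0

    def test_rank_generic(self, pd_game):
        assert z.payoff_basis(pd_game, 2).rank == 9

    def test_matches_brute_force(self, pd_game):
        assert np.array_equal(z.payoff_basis(pd_game, 2).vectors,
                              brute_force_basis(pd_game))


EXPECTED_ALPHA = {
    "example1": lambda R, S, T, P: {(2, 1): 1, (2, 0): -S, (0, 1): -P,
                                    (0, 0): P * S},
    "etft": lambda R, S, T, P: {(1, 2): 1, (2, 1): 1, (1, 1): -1, (2, 2): -1,
                                (1, 0): T - S, (2, 0): -(T - S)},
    "etft2": lambda R, S, T, P: {(1, 2): 1, (2, 1): 1, (1, 1): -1, (2, 2): -1,
                                 (1, 0): -(T - S), (2, 0): T - S},
    "ftft": lambda R, S, T, P: {(1, 2): 1, (2, 1): -1, (1, 1): 1, (2, 2): -1},
    "zss": lambda R, S, T, P: {(1, 0): 1, (2, 0): 1, (0, 0): -(T + S)},
    "ezss": lambda R, S, T, P: {(1, 1): 1, (1, 2): 1, (2, 1): 1, (2, 2): 1,
                                (0, 1): -(T + S), (0, 2): -(T + S)},
}


class TestDetection:
    @pytest.mark.parametrize("name", ZD_CATALOG)
    def test_catalog_strategies_detected_with_printed_alpha(
        self, pd_game, name
    ):
        """Detection recovers each strategy's printed coefficient structure
        up to the canonical scaling."""
        res = z.detect_zd(catalog_strategy(name, pd_game), pd_game)
        assert res.is_zd
        assert res.residual <= 1e-10
        expect = np.zeros((3, 3))
        for idx, v in EXPECTED_ALPHA[name](3, 0, 5, 1).items():
            expect[idx] = v
        assert np.allclose(res.alpha.alpha, canonical(expect).alpha, atol=1e-9)

    def test_repeat_degenerate(self, pd_game):
        res = z.detect_zd(z.fixed_catalog("repeat"), pd_game)
        assert res.degenerate
        assert not res.is_zd

    def test_plain_tft_detected(self, pd_game):
        res = z.detect_zd(z.fixed_catalog("tft"), pd_game)
        assert res.is_zd
        expect = np.zeros((3, 3))
        expect[1, 0], expect[2, 0] = 1, -1
        assert np.allclose(res.alpha.alpha, canonical(expect).alpha, atol=1e-9)

    def test_non_zd_strategy_rejected(self, pd_game):
        coop = np.full(16, 0.5)
        coop[3] = 0.9
        s = z.StrategyTable.from_coop(coop, memory=2)
        res = z.detect_zd(s, pd_game)
        assert not res.is_zd
        assert res.residual > 1e-6

    @pytest.mark.parametrize("payoffs", PAYOFF_GRID)
    @pytest.mark.parametrize("name", ZD_CATALOG)
    def test_residual_machine_epsilon_on_grid(self, payoffs, name):
        game = z.make_pd_game(*payoffs)
        res = z.detect_zd(catalog_strategy(name, game), game)
        assert res.is_zd and res.residual <= 1e-12

    @pytest.mark.parametrize("name", ZD_CATALOG)
    def test_agrees_with_brute_force_least_squares(self, pd_game, name):
        """Independent dense least squares over the brute-force basis gives
        the same projection residual."""
        s = catalog_strategy(name, pd_game)
        t_hat = s.probs[0] - np.array([1.0] * 8 + [0.0] * 8)
        B = brute_force_basis(pd_game)
        coeffs, *_ = np.linalg.lstsq(B.T, t_hat, rcond=None)
        resid = np.linalg.norm(B.T @ coeffs - t_hat) / np.linalg.norm(t_hat)
        res = z.detect_zd(s, pd_game)
        assert abs(resid - res.residual) <= 1e-10

    def test_tft_atft_membership_reported_not_asserted(self, pd_game):
        """The detector gives a definite answer for TFT-ATFT; no external
        ground truth pins it, so only the result's internal consistency is
        checked here."""
        res = z.detect_zd(z.fixed_catalog("tft_atft"), pd_game)
        assert res.is_zd == (res.residual <= 1e-10 and not res.degenerate)


class TestEvaluateRelation:
    def test_constant_relation(self, pd_game):
        alpha = np.zeros((3, 3))
        alpha[0, 0] = 1
        rc = RelationCoefficients(order=2, n_players=2, alpha=alpha)
        dist = TupleDistribution(order=2, n_players=2, n_actions=2,
                                 probs=np.full(16, 1 / 16))
        assert z.evaluate_relation(rc, dist, pd_game) == pytest.approx(1.0)

    @pytest.mark.parametrize("name", ZD_CATALOG)
    @pytest.mark.parametrize("q", [round(0.1 * i, 1) for i in range(11)])
    def test_enforced_relations_vanish(self, pd_game, name, q):
        """Each catalog ZD strategy's relation evaluates to zero under every
        recurrent class of every probe pairing."""
        s = catalog_strategy(name, pd_game)
        alpha = z.enforced_relation(name, pd_game)
        _, dists = stationary_per_class(s, z.probe(q), pd_game)
        for _, dist in dists:
            assert abs(z.evaluate_relation(alpha, dist, pd_game)) <= 1e-10

    def test_detected_alpha_also_vanishes(self, pd_game):
        s = z.example1(pd_game)
        alpha = z.detect_zd(s, pd_game).alpha
        _, dists = stationary_per_class(s, z.probe(0.7), pd_game)
        for _, dist in dists:
            assert abs(z.evaluate_relation(alpha, dist, pd_game)) <= 1e-10

    def test_order_mismatch(self, pd_game):
        rc = RelationCoefficients(order=1, n_players=2, alpha=np.array([0, 1, 0.]))
        dist = TupleDistribution(order=2, n_players=2, n_actions=2,
                                 probs=np.full(16, 1 / 16))
        with pytest.raises(ValueError, match="order"):
            z.evaluate_relation(rc, dist, pd_game)


class TestConstruction:
    @pytest.mark.parametrize("name", ZD_CATALOG)
    def test_roundtrip_recovers_catalog_tables(self, pd_game, name):
        """construct(detect(s)) reproduces each catalog ZD strategy: the PD
        matrices are collinear and here the tables are exactly recovered."""
        s = catalog_strategy(name, pd_game)
        res = z.construct_from_alpha(z.detect_zd(s, pd_game).alpha, pd_game, 1)
        assert res.feasible
        v1 = z.pd_matrix(s, 1).values
        v2 = z.pd_matrix(res.strategy, 1).values
        cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert cos >= 1 - 1e-10
        assert np.allclose(res.strategy.probs, s.probs, atol=1e-9)

    def test_example1_from_printed_relation(self, pd_game):
        alpha = z.enforced_relation("example1", pd_game)
        res = z.construct_from_alpha(alpha, pd_game, 1)
        assert res.feasible
        assert res.w == pytest.approx(-1 / 20)  # -1/((T-P)(T-S))
        assert np.allclose(res.strategy.probs, z.example1(pd_game).probs,
                           atol=1e-12)

    @pytest.mark.parametrize("payoffs", PAYOFF_GRID)
    def test_mirrored_target_infeasible(self, payoffs):
        """Swapping the payoff roles in the correlation-enforcing relation
        pins the scale interval to zero: no strategy table can enforce it."""
        game = z.make_pd_game(*payoffs)
        R, S, T, P = payoffs
        alpha = np.zeros((3, 3))
        alpha[1, 2] = 1
        alpha[1, 0] = -S
        alpha[0, 2] = -P
        alpha[0, 0] = P * S
        rc = RelationCoefficients(order=2, n_players=2, alpha=alpha)
        res = z.construct_from_alpha(rc, game, 1)
        assert not res.feasible
        assert res.w_interval[0] == 0 == res.w_interval[1]
        assert len(res.violations) > 0

    def test_degenerate_alpha_rejected(self, pd_game):
        rc = RelationCoefficients(order=2, n_players=2, alpha=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            z.construct_from_alpha(rc, pd_game, 1)

    def test_constructed_table_enforces_relation(self, pd_game):
        """A freshly constructed strategy actually enforces its target
        relation against a probe opponent."""
        alpha = z.enforced_relation("ftft", pd_game)
        res = z.construct_from_alpha(alpha, pd_game, 1)
        _, dists = stationary_per_class(res.strategy, z.probe(0.4), pd_game)
        for _, dist in dists:
            assert abs(z.evaluate_relation(alpha, dist, pd_game)) <= 1e-10


class TestCanonicalScaling:
    def test_scale_and_sign(self):
        alpha = np.zeros((3, 3))
        alpha[1, 0] = -2.0
        alpha[2, 1] = 4.0
        c = canonical(alpha).alpha
        assert np.max(np.abs(c)) == 1.0
        flat = c.ravel()
        first = flat[np.abs(flat) > 1e-12][0]
        assert first > 0

    def test_degenerate_flags(self):
        only_const = np.zeros((3, 3))
        only_const[0, 0] = 2.0
        assert RelationCoefficients(order=2, n_players=2,
                                    alpha=only_const).degenerate
        assert RelationCoefficients(order=2, n_players=2,
                                    alpha=np.zeros((3, 3))).degenerate
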