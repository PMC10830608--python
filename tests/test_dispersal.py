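"""Stepwise movement mechanics and settlement rules."""

import numpy as np
import pytest
from scipy import stats

from matewave.dispersal import (
    DisperserState,
    MovementParams,
    SettlementRule,
    check_settlement,
    directional_weight,
    disperse_cohort,
    effective_cost,
    effective_cost_grid,
    emigrate,
    settlement_prob_dd,
    step,
    step_probabilities,
)
from matewave.io import landscape_from_mask
from matewave.landscape import generate_landscape


def _uniform_landscape(n_rows=21, n_cols=21, habitat=False):
    mask = np.full((n_rows, n_cols), habitat, dtype=bool)
    return landscape_from_mask(mask)


class TestDirectionalWeight:
    @pytest.mark.parametrize(
        "turn,expected", [(0, 1.0), (1, 1 / 3), (2, 1 / 9), (3, 1 / 27), (4, 1 / 81)]
    )
    def test_persistence_three_turn_penalties(self, turn, expected):
        assert directional_weight(turn, 3.0) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            directional_weight(5, 3.0)
        with pytest.raises(ValueError):
            directional_weight(1, 0.5)


class TestEffectiveCost:
    def test_homogeneous_matrix_cost_everywhere(self):
        land = _uniform_landscape(habitat=False)
        params = MovementParams()
        for heading in range(8):
            assert effective_cost((10, 10), heading, land, params) == 10.0

    def test_homogeneous_habitat_cost_one(self):
        land = _uniform_landscape(habitat=True)
        params = MovementParams()
        for heading in range(8):
            assert effective_cost((10, 10), heading, land, params) == 1.0

    def test_line_aggregation_hand_value(self, strip_costs):
        # costs (1,10,10,10,10) along the ray -> mean 8.2
        land = strip_costs["landscape"]
        params = MovementParams(pr_aggregation="line")
        r, c = strip_costs["cell"]
        assert effective_cost((r, c), 4, land, params) == pytest.approx(
            strip_costs["expected_mean_cost"]
        )

    @pytest.mark.parametrize("aggregation", ["line", "sector"])
    def test_grid_matches_pointwise_reference(self, aggregation):
        land = generate_landscape(10, 15, 0.2, seed=5)
        params = MovementParams(pr_aggregation=aggregation)
        grid = effective_cost_grid(land, params)
        rng = np.random.default_rng(0)
        for _ in range(30):
            r = int(rng.integers(15))
            c = int(rng.integers(10))
            d = int(rng.integers(8))
            assert grid[r, c, d] == pytest.approx(
                effective_cost((r, c), d, land, params)
            )

    def test_bounded_by_extreme_costs(self):
        land = generate_landscape(20, 50, 0.3, seed=2)
        params = MovementParams()
        grid = effective_cost_grid(land, params)
        assert grid.min() >= params.cost_habitat
        assert grid.max() <= params.cost_matrix


class TestStepChoice:
    def test_no_heading_uniform_on_homogeneous_interior(self):
        land = _uniform_landscape()
        grid = effective_cost_grid(land, MovementParams())
        probs = step_probabilities(10, 10, -1, grid, 3.0)
        assert probs == pytest.approx(np.full(8, 1 / 8))

    def test_corner_cell_uniform_over_ongrid_neighbours(self):
        land = _uniform_landscape()
        grid = effective_cost_grid(land, MovementParams())
        probs = step_probabilities(0, 0, -1, grid, 3.0)
        assert probs.sum() == pytest.approx(1.0)
        assert (probs > 0).sum() == 3  # E, SE, S only

    def test_turn_ratios_on_homogeneous_ground(self):
        land = _uniform_landscape()
        grid = effective_cost_grid(land, MovementParams())
        heading = 2  # travelling east
        probs = step_probabilities(10, 10, heading, grid, 3.0)
        assert probs[2] / probs[0] == pytest.approx(9.0)  # straight vs 90-deg
        assert probs[2] / probs[6] == pytest.approx(81.0)  # straight vs reversal
        assert probs.sum() == pytest.approx(1.0)

    def test_cheaper_direction_preferred(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 12:17] = True  # habitat ribbon east of the disperser
        land = landscape_from_mask(mask)
        grid = effective_cost_grid(land, MovementParams())
        probs = step_probabilities(10, 10, -1, grid, 3.0)
        assert probs[2] > probs[6]  # east beats west

    def test_reference_step_moves_to_neighbour(self, rng):
        land = _uniform_landscape()
        state = DisperserState(row=10, col=10, natal_patch=-2)
        params = MovementParams(step_mortality=0.0)
        new = step(state, land, params, rng)
        assert max(abs(new.row - 10), abs(new.col - 10)) == 1
        assert new.steps == 1 and new.heading >= 0

    def test_step_mortality_one_always_dies(self, rng):
        land = _uniform_landscape()
        state = DisperserState(row=10, col=10, natal_patch=-2)
        new = step(state, land, MovementParams(step_mortality=0.999999), rng)
        assert new.status == "dead"

    def test_step_requires_moving_status(self, rng):
        state = DisperserState(row=1, col=1, natal_patch=0, status="settled")
        with pytest.raises(ValueError):
            step(state, _uniform_landscape(), MovementParams(), rng)


class TestEmigrate:
    def test_boundary_probabilities(self, rng):
        assert emigrate(0, 0.0, rng) is False
        assert emigrate(0, 1.0, rng) is True

    def test_adults_cannot_emigrate(self, rng):
        with pytest.raises(ValueError):
            emigrate(1, 0.5, rng)

    def test_binomial_rate(self, rng):
        draws = sum(emigrate(0, 0.5, rng) for _ in range(10_000))
        assert abs(draws - 5000) < 3 * np.sqrt(10_000 * 0.25)


class TestSettlementRules:
    def test_logistic_hand_values(self):
        assert settlement_prob_dd(7.5, b=0.1) == pytest.approx(0.5)
        assert settlement_prob_dd(0, b=0.1) == pytest.approx(
            1 / (1 + np.exp(-7.5)), rel=1e-9
        )
        assert settlement_prob_dd(15, b=0.1) == pytest.approx(
            1 / (1 + np.exp(7.5)), rel=1e-9
        )

    def test_logistic_decreasing_in_density(self):
        ps = settlement_prob_dd(np.arange(30), b=0.1)
        assert (np.diff(ps) < 0).all()

    def test_habitat_only_settles_anywhere_but_natal(self, rng):
        rule = SettlementRule(strategy="habitat_only")
        assert check_settlement(0, 3, 5, 0, 0, rule, 0.1, rng)
        assert not check_settlement(0, 5, 5, 0, 0, rule, 0.1, rng)

    def test_mate_search_needs_opposite_sex(self, rng):
        rule = SettlementRule(strategy="mate_search")
        # male entering a patch with one female resident settles
        assert check_settlement(1, 3, 5, 1, 0, rule, 0.1, rng)
        # female entering an empty patch keeps moving
        assert not check_settlement(0, 3, 5, 0, 0, rule, 0.1, rng)

    def test_density_measures(self, rng):
        rng0 = np.random.default_rng(0)
        all_rule = SettlementRule(strategy="density_dependent", density_measure="all")
        fem_rule = SettlementRule(
            strategy="density_dependent", density_measure="females"
        )
        # at n_f=4, n_m=4, b=0.1: females-only sees bN=0.4 (P~0.97),
        # all sees bN=0.8 (P~0.38)
        n_all = sum(
            check_settlement(0, 3, 5, 4, 4, all_rule, 0.1, rng0) for _ in range(2000)
        )
        n_fem = sum(
            check_settlement(0, 3, 5, 4, 4, fem_rule, 0.1, rng0) for _ in range(2000)
        )
        assert n_fem > n_all
        assert abs(n_all / 2000 - settlement_prob_dd(8, 0.1)) < 0.05
        assert abs(n_fem / 2000 - settlement_prob_dd(4, 0.1)) < 0.05

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            SettlementRule(strategy="teleport")
        with pytest.raises(ValueError):
            SettlementRule(density_measure="males")


class TestDisperseCohort:
    def test_zero_emigrants_empty_records(self):
        land = generate_landscape(10, 20, 0.1, seed=1)
        out = disperse_cohort(
            np.empty(0, np.int64),
            np.empty(0, np.int8),
            land,
            MovementParams(),
            SettlementRule(),
            np.zeros(land.n_patches, np.int64),
            np.zeros(land.n_patches, np.int64),
            0.1,
            seed=0,
        )
        assert out["steps"].size == 0

    def test_first_step_directions_uniform(self):
        # all-habitat world: every first step lands on non-natal habitat and
        # settles, so settled rows recover the step-direction distribution
        mask = np.ones((15, 15), dtype=bool)
        land = landscape_from_mask(mask)
        centre = land.patch_id[7, 7]
        n = 8000
        natal = np.full(n, centre, dtype=np.int64)
        sex = np.zeros(n, np.int8)
        out = disperse_cohort(
            natal,
            sex,
            land,
            MovementParams(step_mortality=0.0),
            SettlementRule(strategy="habitat_only"),
            np.zeros(land.n_patches, np.int64),
            np.zeros(land.n_patches, np.int64),
            0.1,
            seed=3,
        )
        assert (out["steps"] == 1).all()
        drow = out["settle_row"] - 7
        counts = [int((drow == k).sum()) for k in (-1, 0, 1)]
        expected = np.array([3 / 8, 2 / 8, 3 / 8]) * n
        chi2 = ((np.array(counts) - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, 2)

    def test_transit_survival_is_geometric_in_steps(self):
        # a lone natal patch in pure matrix: nobody can ever settle, so the
        # completed-step count at death follows Geometric(step mortality)
        mask = np.zeros((101, 101), dtype=bool)
        mask[50, 50] = True
        land = landscape_from_mask(mask)
        n = 4000
        out = disperse_cohort(
            np.zeros(n, np.int64),
            np.zeros(n, np.int8),
            land,
            MovementParams(step_mortality=0.005),
            SettlementRule(strategy="habitat_only"),
            np.zeros(1, np.int64),
            np.zeros(1, np.int64),
            0.1,
            seed=9,
        )
        assert (out["fate"] == "died_transit").all()
        steps = out["steps"]
        assert steps.mean() == pytest.approx(1 / 0.005, rel=0.1)
        ks = stats.kstest(steps, stats.geom(0.005, loc=-1).cdf)
        assert ks.pvalue > 0.001

    def test_settlers_on_habitat_never_natal(self):
        land = generate_landscape(20, 60, 0.1, seed=4)
        rng = np.random.default_rng(0)
        natal = rng.integers(0, land.n_patches, 500).astype(np.int64)
        sex = rng.integers(0, 2, 500).astype(np.int8)
        out = disperse_cohort(
            natal,
            sex,
            land,
            MovementParams(),
            SettlementRule(strategy="habitat_only"),
            np.zeros(land.n_patches, np.int64),
            np.zeros(land.n_patches, np.int64),
            0.1,
            seed=11,
        )
        settled = out["settle_patch"] >= 0
        assert settled.any()
        assert (out["settle_patch"][settled] != natal[settled]).all()
        rows = land.patch_rows[out["settle_patch"][settled]]
        assert (rows == out["settle_row"][settled]).all()

    def test_mate_search_founds_no_single_sex_patches(self):
        land = generate_landscape(20, 60, 0.1, seed=4)
        rng = np.random.default_rng(1)
        n = 400
        natal = rng.integers(0, 20, n).astype(np.int64)  # clustered origins
        sex = (np.arange(n) % 2).astype(np.int8)
        occ_f = np.zeros(land.n_patches, np.int64)
        occ_m = np.zeros(land.n_patches, np.int64)
        out = disperse_cohort(
            natal,
            sex,
            land,
            MovementParams(),
            SettlementRule(strategy="mate_search"),
            occ_f,
            occ_m,
            0.1,
            seed=21,
        )
        settled = out["settle_patch"] >= 0
        assert settled.any()  # simultaneous arrivals do found patches
        touched = (occ_f + occ_m) > 0
        assert (occ_f[touched] > 0).all() and (occ_m[touched] > 0).all()

    def test_deterministic_given_seed(self):
        land = generate_landscape(10, 30, 0.1, seed=2)
        natal = np.zeros(50, np.int64)
        sex = np.zeros(50, np.int8)
        kw = dict(
            landscape=land,
            params=MovementParams(),
            rule=SettlementRule(),
            b=0.1,
            seed=77,
        )
        a = disperse_cohort(
            natal, sex,
            occupant_f=np.zeros(land.n_patches, np.int64),
            occupant_m=np.zeros(land.n_patches, np.int64), **kw,
        )
        b_ = disperse_cohort(
            natal, sex,
            occupant_f=np.zeros(land.n_patches, np.int64),
            occupant_m=np.zeros(land.n_patches, np.int64), **kw,
        )
        assert np.array_equal(a["settle_patch"], b_["settle_patch"])
        assert np.array_equal(a["steps"], b_["steps"])

    def test_movement_param_validation(self):
        with pytest.raises(ValueError):
            MovementParams(emigration_prob=1.5)
        with pytest.raises(ValueError):
            MovementParams(directional_persistence=0.9)
        with pytest.raises(ValueError):
            MovementParams(step_mortality=1.0)
        with pytest.raises(ValueError):
            MovementParams(pr_aggregation="cone")
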