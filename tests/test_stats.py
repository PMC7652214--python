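"""Multi-aspect statistics: ANOVA, permutation tests, multiplicity,
ranking and ROI heat maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corneaquant import (
    adjust_multiplicity,
    multiway_anova,
    pairwise_population_tests,
    permutation_pairwise,
    rank_populations,
    roi_heatmap,
    shaffer_multipliers,
    tukey_posthoc,
)
from conftest import make_brightness_table


def enumeration_oracle(a, b, aspect="location", alternative="a_greater"):
    """Brute-force enumeration of all C(n, na) assignments."""
    if aspect == "location":
        pooled = np.concatenate([a, b])
        stat = lambda x, y: np.mean(x) - np.mean(y)
    else:
        pooled = np.concatenate([a - np.mean(a), b - np.mean(b)])
        stat = lambda x, y: np.var(x, ddof=1) - np.var(y, ddof=1)
    sign = 1.0 if alternative == "a_greater" else -1.0
    na, n = len(a), len(a) + len(b)
    obs = sign * stat(pooled[:na], pooled[na:])
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        rest = [i for i in range(n) if i not in idx]
        t = sign * stat(pooled[list(idx)], pooled[rest])
        count += t >= obs - 1e-9 * (1 + abs(obs))
        total += 1
    return count / total


class TestPermutationPairwise:
    def test_identical_samples_not_significant(self):
        a = [3.0, 1.0, 4.0, 1.5, 5.0]
        for alt in ("a_greater", "b_greater"):
            for aspect in ("location", "scatter"):
                res = permutation_pairwise(a, a, aspect=aspect,
                                           alternative=alt)
                assert res.p_raw >= 0.5

    def test_extreme_separation_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = permutation_pairwise(a, b, alternative="b_greater")
        assert res.exact and res.n_permutations == 20
        assert res.p_raw == pytest.approx(1.0 / 20.0)
        assert res.p_raw == pytest.approx(
            enumeration_oracle(a, b, alternative="b_greater"))
        res_a = permutation_pairwise(a, b, alternative="a_greater")
        assert res_a.p_raw == pytest.approx(
            enumeration_oracle(a, b, alternative="a_greater"))

    @pytest.mark.parametrize("na,nb", [(2, 8), (3, 7), (4, 6), (5, 5), (3, 3)])
    @pytest.mark.parametrize("aspect", ["location", "scatter"])
    def test_implementation_equals_enumeration_oracle(self, na, nb, aspect,
                                                      rng):
        a = rng.normal(0, 1, na)
        b = rng.normal(0.5, 1.2, nb)
        res = permutation_pairwise(a, b, aspect=aspect, method="exact")
        assert res.p_raw == pytest.approx(
            enumeration_oracle(a, b, aspect=aspect))

    def test_monte_carlo_converges_to_enumeration(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 5)
        for aspect in ("location", "scatter"):
            exact = permutation_pairwise(a, b, aspect=aspect,
                                         method="exact").p_raw
            mc = permutation_pairwise(a, b, aspect=aspect,
                                      method="montecarlo",
                                      n_permutations=4000, seed=1).p_raw
            se = np.sqrt(exact * (1 - exact) / 4000)
            assert abs(mc - exact) <= 3 * se + 1 / 4001

    def test_type_one_error_calibrated_under_null(self, rng):
        hits = {"location": 0, "scatter": 0}
        n_rep = 1000
        for aspect in hits:
            for i in range(n_rep):
                a = rng.normal(0, 1, 20)
                b = rng.normal(0, 1, 20)
                p = permutation_pairwise(a, b, aspect=aspect,
                                         n_permutations=499, seed=i).p_raw
                hits[aspect] += p <= 0.05
            assert 0.03 <= hits[aspect] / n_rep <= 0.07, aspect

    def test_constant_pooled_sample_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            res = permutation_pairwise([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_raw == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            permutation_pairwise([1.0], [2.0, 3.0])

    def test_p_floor_respected(self, rng):
        a = rng.normal(10, 0.1, 30)
        b = rng.normal(0, 0.1, 30)
        res = permutation_pairwise(a, b, n_permutations=999, seed=0)
        assert res.p_raw >= 1 / 1000


class TestMultiplicityAdjustment:
    def test_shaffer_multipliers_three_and_four_groups(self):
        assert shaffer_multipliers(3) == [3, 1, 1]
        assert shaffer_multipliers(4) == [6, 3, 3, 3, 2, 1]

    def test_stepdown_worked_example_three_populations(self):
        adjusted = adjust_multiplicity([0.001, 0.001, 0.931], n_groups=3)
        assert np.allclose(sorted(adjusted), [0.003, 0.003, 0.931])

    def test_all_ones_stay_one(self):
        assert np.allclose(adjust_multiplicity([1.0, 1.0, 1.0], n_groups=3),
                           1.0)

    def test_single_hypothesis_unchanged(self):
        assert adjust_multiplicity([0.031])[0] == pytest.approx(0.031)

    def test_plain_holm_without_group_structure(self):
        adj = adjust_multiplicity([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adjusted_never_below_raw_never_above_one(self, ps):
        adj = adjust_multiplicity(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_multiplicity([0.0, 0.5])

    def test_familywise_error_controlled_in_all_null_simulation(self, rng):
        from scipy.stats import ttest_ind

        n_rep, fwer = 2000, 0
        for _ in range(n_rep):
            g = [rng.normal(0, 1, 12) for _ in range(3)]
            ps = [ttest_ind(g[i], g[j]).pvalue
                  for i, j in itertools.combinations(range(3), 2)]
            adj = adjust_multiplicity(ps, n_groups=3)
            fwer += (adj <= 0.05).any()
        assert fwer / n_rep <= 0.05 + 0.015


class TestMultiwayAnova:
    def test_matches_independent_least_squares_f(self, rng):
        table = make_brightness_table(rng, offsets=(0, 4), sds=(8, 8),
                                      n_per_cell=3)
        res = multiway_anova(table, include_interactions=False)

        # independent oracle: numpy OLS, extra-sum-of-squares F test
        def design(df, drop=None):
            cols = [np.ones(len(df))]
            for fac in ("population", "frame", "layer"):
                if fac == drop:
                    continue
                levels = sorted(df[fac].unique())
                for lev in levels[:-1]:  # sum coding
                    v = np.where(df[fac] == lev, 1.0, 0.0)
                    v -= np.where(df[fac] == levels[-1], 1.0, 0.0)
                    cols.append(v)
            return np.column_stack(cols)

        y = table.brightness.to_numpy()
        X_full = design(table)
        sse_full = np.sum((y - X_full @ np.linalg.lstsq(X_full, y,
                                                        rcond=None)[0]) ** 2)
        X_red = design(table, drop="population")
        sse_red = np.sum((y - X_red @ np.linalg.lstsq(X_red, y,
                                                      rcond=None)[0]) ** 2)
        df_num = X_full.shape[1] - X_red.shape[1]
        df_den = len(y) - X_full.shape[1]
        f_oracle = ((sse_red - sse_full) / df_num) / (sse_full / df_den)
        assert res.f_value("population") == pytest.approx(f_oracle, rel=1e-9)

    def test_null_population_rejection_rate_nominal(self, rng):
        n_rep, hits = 400, 0
        for _ in range(n_rep):
            table = make_brightness_table(rng, offsets=(0, 0), sds=(10, 10),
                                          n_per_cell=2)
            res = multiway_anova(table, include_interactions=False)
            hits += res.p_value("population") <= 0.05
        assert 0.05 - 0.025 <= hits / n_rep <= 0.05 + 0.025

    def test_power_at_cohort_scale_effect(self, rng):
        table = make_brightness_table(rng, offsets=(0, 5, 0), sds=(12, 12, 12),
                                      pops=("healthy", "injured", "treated"),
                                      n_per_cell=40)
        res = multiway_anova(table)
        assert res.p_value("population") < 0.001

    def test_layer_effect_detected_frame_null(self, rng):
        table = make_brightness_table(rng, offsets=(0, 0), sds=(8, 8),
                                      n_per_cell=8,
                                      layer_gain=(0, 10, 10, 0))
        res = multiway_anova(table)
        assert res.p_value("layer") < 0.001
        assert res.p_value("frame") > 0.05

    def test_empty_cell_drops_interaction(self, rng, caplog):
        table = make_brightness_table(rng, n_per_cell=2)
        table = table[~((table.population == "a") & (table.frame == 6))]
        with caplog.at_level("WARNING"):
            res = multiway_anova(table)
        names = [t[0] for t in res.terms]
        assert "population:frame" not in names
        assert "population:layer" in names

    def test_single_level_factor_rejected(self, rng):
        table = make_brightness_table(rng)
        with pytest.raises(ValueError):
            multiway_anova(table[table.population == "a"])


class TestTukey:
    def test_two_groups_equals_t_test(self, rng):
        from scipy.stats import ttest_ind

        table = make_brightness_table(rng, offsets=(0, 3), sds=(8, 8),
                                      n_per_cell=2)
        res = tukey_posthoc(table)
        a = table[table.population == "a"].brightness
        b = table[table.population == "b"].brightness
        t_p = ttest_ind(a, b).pvalue
        assert res.p_adjusted.iloc[0] == pytest.approx(t_p, abs=1e-3)

    def test_confidence_interval_coverage(self, rng):
        n_rep, covered = 600, 0
        for _ in range(n_rep):
            df = pd.DataFrame(
                {
                    "population": ["a"] * 30 + ["b"] * 30,
                    "brightness": rng.normal(150, 10, 60),
                }
            )
            row = tukey_posthoc(df).iloc[0]
            covered += row.ci_low <= 0 <= row.ci_high
        assert 0.93 <= covered / n_rep <= 0.97

    def test_cohort_scale_significance_pattern(self, rng):
        table = make_brightness_table(rng, offsets=(0, 5, 0), sds=(12, 12, 12),
                                      pops=("healthy", "injured", "treated"),
                                      n_per_cell=40)
        res = tukey_posthoc(table).set_index(["population_a", "population_b"])
        assert res.loc[("healthy", "injured"), "p_adjusted"] < 0.05
        assert res.loc[("injured", "treated"), "p_adjusted"] < 0.05
        assert res.loc[("healthy", "treated"), "p_adjusted"] > 0.05

    def test_single_population_rejected(self, rng):
        table = make_brightness_table(rng)
        with pytest.raises(ValueError):
            tukey_posthoc(table[table.population == "a"])


class TestRanking:
    def test_reported_location_pattern_reproduced(self):
        """Dominance counting on the published-style location matrix:
        injured dominates both others; healthy and treated tie at rank 2."""
        p = {
            ("injured", "healthy"): 0.001,
            ("injured", "treated"): 0.001,
            ("healthy", "injured"): 1.0,
            ("healthy", "treated"): 0.070,
            ("treated", "healthy"): 0.931,
            ("treated", "injured"): 1.0,
        }
        ranks = rank_populations(p, alpha=0.05).ranks
        assert ranks == {"healthy": 2, "injured": 1, "treated": 2}

    def test_no_dominance_all_rank_one(self):
        p = {(a, b): 1.0
             for a, b in itertools.permutations("xyz", 2)}
        assert set(rank_populations(p).ranks.values()) == {1}

    def test_two_populations_clear_order(self):
        p = {("a", "b"): 0.01, ("b", "a"): 0.99}
        assert rank_populations(p).ranks == {"a": 1, "b": 2}

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError):
            rank_populations({("a", "b"): 0.5})


class TestRoiHeatmap:
    @staticmethod
    def _cell_table(rng, n_per_cell, pops=("a", "b"), sds=None):
        rows = []
        for p_idx, pop in enumerate(pops):
            for layer in range(1, 5):
                for frame in range(1, 7):
                    sd = 8.0
                    if sds is not None:
                        sd = sds(pop, layer, frame)
                    vals = rng.normal(150, sd, n_per_cell)
                    for v in vals:
                        rows.append({"population": pop, "layer": layer,
                                     "frame": frame, "brightness": v})
        return pd.DataFrame(rows)

    def test_null_calibration_expected_significant_cells(self, rng):
        counts_loc, counts_sca = [], []
        for rep in range(150):
            table = self._cell_table(rng, n_per_cell=10)
            hm = roi_heatmap(table, ("a", "b"), n_permutations=299, seed=rep)
            counts_loc.append(hm.significant_location.sum())
            counts_sca.append(hm.significant_scatter.sum())
        assert 0.7 <= np.mean(counts_loc) <= 1.7  # expected 24 x 0.05 = 1.2
        assert 0.7 <= np.mean(counts_sca) <= 1.7

    def test_targeted_scatter_effect_localized(self, rng):
        def sds(pop, layer, frame):
            return 20.0 if (pop == "b" and layer == 4 and frame == 4) else 8.0

        table = self._cell_table(rng, n_per_cell=30, sds=sds)
        hm = roi_heatmap(table, ("b", "a"), n_permutations=999, seed=3)
        r, c = np.unravel_index(np.nanargmin(hm.p_scatter),
                                hm.p_scatter.shape)
        assert (r + 1, c + 1) == (4, 4)

    def test_identical_tables_nothing_significant(self, rng):
        half = self._cell_table(rng, n_per_cell=8, pops=("a",))
        other = half.copy()
        other["population"] = "b"
        table = pd.concat([half, other], ignore_index=True)
        hm = roi_heatmap(table, ("a", "b"), n_permutations=299, seed=0)
        assert hm.significant_location.sum() == 0
        assert hm.significant_scatter.sum() == 0

    def test_insufficient_cells_flagged_not_dropped(self, rng, caplog):
        table = self._cell_table(rng, n_per_cell=5)
        table = table[~((table.population == "a") & (table.layer == 1)
                        & (table.frame == 1))]
        with caplog.at_level("WARNING"):
            hm = roi_heatmap(table, ("a", "b"), n_permutations=99, seed=0)
        assert hm.flagged[0, 0]
        assert np.isnan(hm.p_location[0, 0])
        assert hm.flagged.sum() == 1


class TestPairwiseBattery:
    def test_adjusted_never_below_raw(self, rng):
        table = make_brightness_table(rng, offsets=(0, 4), sds=(9, 12),
                                      n_per_cell=4)
        out = pairwise_population_tests(table, n_permutations=499, seed=2)
        r = out["results"]
        assert (r.p_adjusted >= r.p_raw - 1e-12).all()
        assert (r.p_adjusted <= 1.0).all()

    def test_detects_planted_location_difference(self, rng):
        table = make_brightness_table(rng, offsets=(0, 6), sds=(8, 8),
                                      n_per_cell=6)
        out = pairwise_population_tests(table, n_permutations=999, seed=2)
        r = out["results"].set_index(["aspect", "population_a",
                                      "population_b"])
        assert r.loc[("location", "b", "a"), "p_adjusted"] < 0.01
        assert out["rankings"]["location"].ranks == {"a": 2, "b": 1}
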