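"""Permutation machinery vs. brute-force oracles; invariances; calibration."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from cytomorph.mastats import (Dataset, TestConfig, _significance_levels,
                               adjust_matrix, animal_summaries,
                               estimate_effects, minp_stepdown,
                               multi_aspect_analysis, npc_combine,
                               pairwise_partial_tests, sign_flip_test)
from cytomorph.records import DESCRIPTORS, DOMAINS
from cytomorph.synthetic import PopulationEffectSpec, generate_cell_table


def _table(effects=None, seed=0, animals=4, cells=40, **kw):
    if effects:
        spec = PopulationEffectSpec.from_sd_effects(
            effects, animals_per_population=animals, cells_per_animal=cells,
            **kw)
    else:
        spec = PopulationEffectSpec(animals_per_population=animals,
                                    cells_per_animal=cells)
    return generate_cell_table(spec, seed=seed)


# ---------------------------------------------------------------------------
# Block sign-flip test
# ---------------------------------------------------------------------------

class TestSignFlip:
    def test_exhaustive_matches_itertools_oracle(self, rng):
        """2^n enumeration equals a direct itertools.product oracle."""
        v = rng.normal(0.3, 1.0, 7)
        res = sign_flip_test(v, B=300)
        assert res.exhaustive and res.n_flips == 2**7
        t_obs = abs(v.mean())
        count = sum(abs(np.dot(s, v) / len(v)) >= t_obs - 1e-12
                    for s in product([1.0, -1.0], repeat=len(v)))
        assert res.p_value == pytest.approx(count / 2**7)

    def test_p_is_one_for_symmetric_pattern(self):
        """Every flip of (+a, -a) gives the same |mean|, so p = 1."""
        res = sign_flip_test(np.array([2.0, -2.0]), B=300)
        assert res.p_value == 1.0

    def test_extreme_shift_gives_min_p(self):
        v = np.full(8, 5.0) + np.arange(8) * 0.01  # all same sign
        res = sign_flip_test(v, B=300)
        # only the two all-plus / all-minus patterns reach |T|
        assert res.p_value == pytest.approx(2 / 256)
        assert res.direction == 1

    def test_monte_carlo_p_never_below_one_over_b_plus_one(self, rng):
        v = np.full(40, 3.0) + rng.normal(0, 0.1, 40)  # 2^40 >> B
        res = sign_flip_test(v, B=199, seed=1)
        assert not res.exhaustive
        assert res.n_flips == 200
        assert res.p_value >= 1 / 200

    def test_null_uniformity(self, rng):
        """Under symmetry the p-value is stochastically uniform: the
        rejection rate at alpha = 0.1 stays near 0.1 over 300 replicates."""
        hits = sum(sign_flip_test(rng.normal(0, 1, 8), B=300).p_value <= 0.1
                   for _ in range(300))
        # binomial(300, 0.1): 3-sigma band is about ±16
        assert 10 <= hits <= 50

    def test_b_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 99"):
            sign_flip_test(np.ones(4), B=10)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            sign_flip_test(np.array([1.0]), B=300)


# ---------------------------------------------------------------------------
# Animal summaries
# ---------------------------------------------------------------------------

class TestAnimalSummaries:
    def test_location_is_group_mean(self, null_table):
        S, labels = animal_summaries(null_table, "location")
        one = null_table[null_table.animal_id == S.index[0]]
        assert S.iloc[0]["area_um2"] == pytest.approx(one["area_um2"].mean())
        assert set(labels.unique()) == {"F", "FM", "M"}

    def test_scatter_shift_invariance_is_bit_exact(self, null_table):
        """A constant shift leaves the scatter summary bit-identical.

        Bit-level identity is only well defined when the shifted values are
        exact: data quantized to multiples of 2^-26 plus a shift that is
        itself such a multiple make every addition, median and deviation
        exactly representable, so any remaining difference would expose a
        location leak in the statistic rather than IEEE rounding."""
        q = 2.0**26
        base = null_table.copy()
        base[DESCRIPTORS] = np.round(base[DESCRIPTORS] * q) / q
        shifted = base.copy()
        shifted["area_um2"] = shifted["area_um2"] + 123.25
        S0, _ = animal_summaries(base, "scatter")
        S1, _ = animal_summaries(shifted, "scatter")
        assert np.array_equal(S0.to_numpy(), S1.to_numpy())

    def test_scatter_scales_linearly(self, null_table):
        doubled = null_table.copy()
        doubled[DESCRIPTORS] = doubled[DESCRIPTORS] * 2.0
        S0, _ = animal_summaries(null_table, "scatter")
        S1, _ = animal_summaries(doubled, "scatter")
        assert np.allclose(S1.to_numpy(), 2.0 * S0.to_numpy())

    def test_unknown_aspect_raises(self, null_table):
        with pytest.raises(ValueError, match="aspect"):
            animal_summaries(null_table, "shape")


# ---------------------------------------------------------------------------
# Pairwise partial tests
# ---------------------------------------------------------------------------

class TestPairwise:
    def test_exhaustive_matches_combinations_oracle(self):
        """C(4+4, 4) = 70 relabelings equal a direct itertools oracle."""
        table = _table(seed=3)
        res = pairwise_partial_tests(table, "location", "F", "M", B=300,
                                     descriptors=["area_um2"])
        assert res.exhaustive and res.n_perm == 70

        S, labels = animal_summaries(
            table[table.population.isin(["F", "M"])], "location", ["area_um2"])
        v = S["area_um2"].to_numpy()
        is_f = (labels == "F").to_numpy()
        v = np.concatenate([v[is_f], v[~is_f]])
        t_obs = v[:4].mean() - v[4:].mean()
        stats = []
        for idx in combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(idx)] = True
            stats.append(v[sel].mean() - v[~sel].mean())
        oracle_p = np.mean(np.array(stats) >= t_obs - 1e-12)
        assert res.partial_p[0] == pytest.approx(oracle_p)

    def test_direction_reversal_complements(self):
        """With distinct statistics, p(greater) + p(less) = 1 + 1/n_perm."""
        table = _table({"F": 1.0, "M": -1.0, "FM": 0.0},
                       descriptors=["area_um2"], seed=5)
        g = pairwise_partial_tests(table, "location", "F", "M",
                                   direction="greater", B=300,
                                   descriptors=["area_um2"])
        l = pairwise_partial_tests(table, "location", "F", "M",
                                   direction="less", B=300,
                                   descriptors=["area_um2"])
        assert g.partial_p[0] + l.partial_p[0] == pytest.approx(1 + 1 / g.n_perm)

    def test_detects_planted_shift(self):
        table = _table({"F": 2.0, "M": -2.0, "FM": 0.0},
                       descriptors=["area_um2"], seed=7)
        res = pairwise_partial_tests(table, "location", "F", "M", B=300,
                                     descriptors=["area_um2"])
        assert res.partial_p[0] == pytest.approx(1 / 70)

    def test_cell_level_exchange_runs_but_only_for_location(self, null_table):
        res = pairwise_partial_tests(null_table, "location", "F", "M", B=199,
                                     exchange_unit="cell",
                                     descriptors=["area_um2"])
        assert res.n_perm == 200
        with pytest.raises(ValueError, match="location"):
            pairwise_partial_tests(null_table, "scatter", "F", "M", B=199,
                                   exchange_unit="cell")

    def test_same_population_twice_rejected(self, null_table):
        with pytest.raises(ValueError, match="differ"):
            pairwise_partial_tests(null_table, "location", "F", "F", B=199)

    def test_observed_row_is_first(self, null_table):
        res = pairwise_partial_tests(null_table, "location", "F", "M", B=300,
                                     descriptors=["area_um2", "solidity"])
        S, labels = animal_summaries(
            null_table[null_table.population.isin(["F", "M"])], "location",
            ["area_um2", "solidity"])
        obs = (S[labels == "F"].mean() - S[labels == "M"].mean()).to_numpy()
        assert np.allclose(res.stat_null[0], obs)


# ---------------------------------------------------------------------------
# NPC combination and min-p step-down
# ---------------------------------------------------------------------------

class TestNPC:
    def test_significance_levels_against_oracle(self, rng):
        stat = rng.normal(size=(50, 3))
        L = _significance_levels(stat)
        for b in range(50):
            for k in range(3):
                oracle = np.mean(stat[:, k] >= stat[b, k] - 1e-12)
                assert L[b, k] == pytest.approx(oracle)

    def test_single_partial_combination_is_identity(self, rng):
        """With one partial test, NPC must reproduce its raw p (both
        combiners are monotone transforms of a single level)."""
        stat = rng.normal(size=(100, 1))
        raw = np.mean(stat[:, 0] >= stat[0, 0] - 1e-12)
        for comb in ("fisher", "tippett"):
            p, levels = npc_combine(stat, comb)
            assert p == pytest.approx(raw)
            assert levels[0] == pytest.approx(p)

    def test_fisher_oracle_by_double_enumeration(self, rng):
        """Tiny case: recompute Fisher combination by explicit loops."""
        stat = rng.normal(size=(20, 2))
        n = len(stat)
        L = np.array([[np.mean(stat[:, k] >= stat[b, k] - 1e-12)
                       for k in range(2)] for b in range(n)])
        psi = -2 * np.log(L).sum(axis=1)
        oracle = np.mean(psi >= psi[0] - 1e-12)
        p, _ = npc_combine(stat, "fisher")
        assert p == pytest.approx(oracle)

    def test_combined_p_not_worse_than_best_partial_by_much(self):
        """A strong signal in every partial test keeps the combined p at
        the permutation floor."""
        stat = np.vstack([np.full((1, 3), 10.0),
                          np.random.default_rng(0).normal(size=(99, 3))])
        p, _ = npc_combine(stat, "fisher")
        assert p == pytest.approx(1 / 100)

    def test_unknown_combiner_rejected(self, rng):
        with pytest.raises(ValueError, match="combining"):
            npc_combine(rng.normal(size=(10, 2)), "stouffer")


class TestMinP:
    def test_single_hypothesis_unchanged(self, rng):
        levels = _significance_levels(rng.normal(size=(50, 1)))
        adj = minp_stepdown(levels)
        assert adj[0] == pytest.approx(levels[0, 0])

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        stat = rng.normal(size=(200, 5))
        levels = _significance_levels(stat)
        adj = minp_stepdown(levels)
        raw = levels[0]
        assert (adj + 1e-12 >= raw).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_perfectly_dependent_hypotheses_pay_no_penalty(self, rng):
        """Duplicated columns (the same test twice) must not be adjusted
        upward: the min over duplicates equals either one alone."""
        col = rng.normal(size=(100, 1))
        levels = _significance_levels(np.hstack([col, col]))
        adj = minp_stepdown(levels)
        assert adj[0] == pytest.approx(levels[0, 0])
        assert adj[1] == pytest.approx(levels[0, 1])

    def test_holm_fallback_matches_manual_holm(self):
        raw = {"a": 0.01, "b": 0.04, "c": 0.03}
        adj = adjust_matrix(raw)
        assert adj["a"] == pytest.approx(0.03)   # 3 × 0.01
        assert adj["c"] == pytest.approx(0.06)   # max(0.03, 2 × 0.03)
        assert adj["b"] == pytest.approx(0.06)   # max(0.06, 1 × 0.04)


# ---------------------------------------------------------------------------
# Effect estimation
# ---------------------------------------------------------------------------

class TestEstimateEffects:
    def test_tau_sums_to_zero_with_equal_counts(self, null_table):
        eff = estimate_effects(null_table, B=99)
        assert np.allclose(eff.tau.sum(axis=0), 0.0, atol=1e-9)

    def test_arrows_null_mostly_empty(self, null_table):
        eff = estimate_effects(null_table, B=199, alpha=0.01)
        assert (eff.arrows != 0).to_numpy().mean() < 0.2

    def test_strong_shift_yields_signed_arrows(self):
        table = _table({"F": 3.0, "M": -3.0, "FM": 0.0},
                       descriptors=["area_um2"], animals=8, cells=100, seed=11)
        eff = estimate_effects(table, B=300, alpha=0.05)
        assert eff.arrows.loc["F", "area_um2"] == 1
        assert eff.arrows.loc["M", "area_um2"] == -1

    def test_scale_inflation_shows_in_sigma2(self):
        spec = PopulationEffectSpec.from_sd_effects(
            {"F": 2.0}, descriptors=["area_um2"], aspect="scatter",
            animals_per_population=8, cells_per_animal=100)
        table = generate_cell_table(spec, seed=13)
        eff = estimate_effects(table, B=99)
        assert eff.sigma2.loc["F", "area_um2"] > 2.5 * eff.sigma2.loc["M", "area_um2"]


# ---------------------------------------------------------------------------
# Full multi-aspect analysis
# ---------------------------------------------------------------------------

class TestMultiAspect:
    @pytest.fixture(scope="class")
    def shifted_result(self):
        table = _table({"F": 2.0, "M": -2.0, "FM": 0.0},
                       descriptors=list(DOMAINS["size"]),
                       animals=8, cells=60, seed=17)
        return multi_aspect_analysis(table, TestConfig(B=199, seed=1)), table

    def test_matrix_inventory(self, shifted_result):
        result, _ = shifted_result
        assert set(result.matrices) == {(a, d) for a in ("location", "scatter")
                                        for d in DOMAINS}
        for m in result.matrices.values():
            assert m.raw.shape == (3, 3)
            assert np.isnan(np.diag(m.raw)).all()

    def test_location_size_signal_found_and_directional(self, shifted_result):
        result, _ = shifted_result
        m = result.matrices[("location", "size")]
        assert m.adjusted.loc["F", "M"] <= 0.05
        assert m.raw.loc["M", "F"] > 0.5  # wrong direction is far from small

    def test_adjusted_never_below_raw(self, shifted_result):
        result, _ = shifted_result
        for m in result.matrices.values():
            off = ~np.eye(3, dtype=bool)
            assert (m.adjusted.to_numpy()[off] + 1e-9
                    >= m.raw.to_numpy()[off]).all()

    def test_determinism(self, shifted_result):
        result, table = shifted_result
        again = multi_aspect_analysis(table, TestConfig(B=199, seed=1))
        for key, m in result.matrices.items():
            assert m.raw.equals(again.matrices[key].raw)
            assert m.adjusted.equals(again.matrices[key].adjusted)

    def test_dataset_rejects_mixed_cell_types(self, null_table):
        bad = null_table.copy()
        bad.loc[bad.index[:10], "cell_type"] = "golgi"
        with pytest.raises(ValueError, match="one cell type"):
            Dataset(bad)

    def test_dataset_rejects_single_animal_population(self, null_table):
        bad = null_table[~((null_table.population == "F") &
                           (null_table.animal_id != "F00"))]
        with pytest.raises(ValueError, match="fewer than 2"):
            Dataset(bad)
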