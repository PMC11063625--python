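"""Factorial ANOVA selectivity, bootstrap census, pairwise and stratified."""

import numpy as np
import pytest

from emomem.census import (
    UnitCounts,
    anova_selectivity,
    build_unit_categories,
    build_unit_counts,
    census_all,
    census_bootstrap,
    pairwise_census,
    stratified_census,
)
from emomem.synth import UnitProfile, simulate_unit

from conftest import make_trials


def _unit_counts(y, emotion, memory, n_mem=2, unit_id="u", patient="p",
                 region="HIP"):
    return UnitCounts(
        unit_id=unit_id, patient_id=patient, region=region,
        y=np.asarray(y, dtype=float), emotion=np.asarray(emotion),
        memory=np.asarray(memory), n_memory_levels=n_mem,
    )


def _balanced_2x2(cell_means, sd, rng, n_per=10):
    """Counts for a balanced 2x2 design with the given cell means."""
    y, e, m = [], [], []
    for ei in range(2):
        for mi in range(2):
            y.extend(rng.normal(cell_means[ei][mi], sd, n_per))
            e.extend([ei] * n_per)
            m.extend([mi] * n_per)
    return _unit_counts(y, e, m)


class TestAnovaSelectivity:
    def test_identical_counts_label_ns(self):
        u = _unit_counts([5.0] * 40, [0, 1] * 20, [0] * 20 + [1] * 20)
        res = anova_selectivity(u)
        assert res.label == "ns"
        assert res.p_emotion == 1.0

    def test_strong_emotion_main_effect(self, rng):
        # same noise vector in every cell: interaction and memory sums of
        # squares are exactly zero, emotion carries the full 8-unit gap
        noise = rng.normal(0, 1.0, 10)
        y = np.concatenate([10 + noise, 10 + noise, 2 + noise, 2 + noise])
        e = np.repeat([0, 0, 1, 1], 10)
        m = np.tile(np.repeat([0, 1], 10), 2)
        res = anova_selectivity(_unit_counts(y, e, m))
        assert res.p_emotion < 0.001 and res.label == "E"
        assert res.p_interaction == 1.0

    def test_matches_closed_form_sums_of_squares(self, rng):
        """Balanced design: F from explicit SS decomposition."""
        u = _balanced_2x2([[6, 4], [3, 5]], 1.5, rng, n_per=8)
        res = anova_selectivity(u)
        # independent oracle: statsmodels OLS ANOVA (type II)
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": u.y, "e": u.emotion, "m": u.memory})
        fit = smf.ols("y ~ C(e) * C(m)", df).fit()
        tbl = sm.stats.anova_lm(fit, typ=2)
        assert res.p_emotion == pytest.approx(tbl.loc["C(e)", "PR(>F)"])
        assert res.p_memory == pytest.approx(tbl.loc["C(m)", "PR(>F)"])
        assert res.p_interaction == pytest.approx(
            tbl.loc["C(e):C(m)", "PR(>F)"]
        )

    def test_interaction_precedence_discards_mains(self, rng):
        # crossing pattern: huge interaction plus emotion main effect
        u = _balanced_2x2([[12, 2], [1, 5]], 1.0, rng)
        res = anova_selectivity(u)
        assert res.p_interaction < 0.05
        assert res.label == "X"

    def test_unbalanced_2x3_recognition_design(self, rng):
        y = rng.poisson(4, 90).astype(float)
        e = rng.integers(0, 2, 90)
        m = rng.integers(0, 3, 90)
        u = _unit_counts(y, e, m, n_mem=3)
        res = anova_selectivity(u)
        assert 0 < res.p_emotion <= 1 and 0 < res.p_interaction <= 1


class TestBuildUnitCounts:
    def test_empty_cell_marks_unanalyzable(self):
        trials = make_trials(
            "encoding",
            [("emotional", "eR")] * 10 + [("neutral", "nR")] * 10
            + [("neutral", "nF")] * 10,   # no eF at all
        )
        u = simulate_unit(UnitProfile(baseline_rate=5.0), trials, 0,
                          unit_id="u0")
        data, excluded = build_unit_counts([u], trials, "encoding")
        assert excluded == ["u0"] and not data


class TestCensusBootstrap:
    def _null_units(self, rng, n_units=20, n_trials=60):
        units = []
        for i in range(n_units):
            y = rng.poisson(5, n_trials).astype(float)
            e = np.repeat([0, 1], n_trials // 2)
            m = np.tile([0] * (n_trials // 4) + [1] * (n_trials // 4), 2)
            units.append(_unit_counts(y, e, m, unit_id=f"u{i}",
                                      patient=f"p{i % 3}",
                                      region=["HIP", "AMY", "EC"][i % 3]))
        return units

    def _planted_units(self, rng, n_units=20, frac=0.5, delta=4.0):
        units = self._null_units(rng, n_units)
        for u in units[: int(n_units * frac)]:
            u.y = u.y + delta * (u.emotion == 0)
        return units

    def test_observed_zero_gives_p_one(self, rng):
        # no unit selective for X in a tiny null cohort is very likely,
        # but force it by construction: constant counts are never selective
        units = [
            _unit_counts([5.0] * 40, [0, 1] * 20, [0] * 20 + [1] * 20,
                         unit_id=f"u{i}")
            for i in range(5)
        ]
        res = census_bootstrap(units, "X", B=50, seed=0)
        assert res.observed_count == 0 and res.p == 1.0

    def test_floor_when_observed_exceeds_every_null(self, rng):
        units = self._planted_units(rng, n_units=24, frac=0.75, delta=8.0)
        res = census_bootstrap(units, "E", B=100, alpha=0.05, seed=1)
        assert res.observed_count >= 15
        assert res.p == 1 / 100

    def test_p_is_direct_proportion_of_null_exceedances(self, rng):
        units = self._planted_units(rng, n_units=20, frac=0.25, delta=1.2)
        res = census_bootstrap(units, "E", B=400, seed=2)
        ge = int(np.count_nonzero(res.null_counts >= res.observed_count))
        assert res.p == (ge / 400 if ge else 1 / 400)

    def test_null_distribution_invariant_to_unit_relabeling(self, rng):
        units = self._null_units(rng, n_units=8)
        res_a = census_all(units, B=200, seed=5)
        for u in units:
            u.unit_id = "renamed_" + u.unit_id
        res_b = census_all(units, B=200, seed=5)
        for k in res_a:
            np.testing.assert_array_equal(
                res_a[k].null_counts, res_b[k].null_counts
            )

    def test_power_monotone_in_prevalence(self, rng):
        """Census p (replicate-averaged) non-increasing in planted prevalence."""
        mean_p = []
        for frac in (0.0, 0.25, 0.5):
            ps = []
            for rep in range(5):
                r = np.random.default_rng(1000 + rep)
                units = self._planted_units(r, n_units=20, frac=frac,
                                            delta=2.5)
                ps.append(census_bootstrap(units, "E", B=100,
                                           seed=rep).p)
            mean_p.append(np.mean(ps))
        assert mean_p[0] >= mean_p[1] >= mean_p[2]

    def test_invalid_effect_and_B(self):
        with pytest.raises(ValueError):
            census_bootstrap([], "Q", B=10)
        with pytest.raises(ValueError):
            census_all([], B=0)


class TestPairwiseCensus:
    def _category_units(self, rng, n_units=12, rhit_factor=1.0):
        from emomem.census import UnitCategories

        units = []
        for i in range(n_units):
            cats = np.repeat([0, 1, 2, 3], [30, 8, 20, 30])
            lam = np.where(cats == 0, 4.0 * rhit_factor, 4.0)
            y = rng.poisson(lam).astype(float)
            units.append(
                UnitCategories(unit_id=f"u{i}", patient_id="p0", region="HIP",
                               y=y, category=cats)
            )
        return units

    def test_null_pairwise_p_not_extreme(self, rng):
        units = self._category_units(rng)
        res = pairwise_census(units, B=100, seed=0)
        assert len(res) == 6
        small = sum(r.p < 0.05 for r in res.values())
        assert small <= 2

    def test_planted_rhit_pattern(self, rng):
        """RHit rate doubled in half the units: RHit pairs pop, Miss-CR not."""
        units = self._category_units(rng, rhit_factor=1.0)
        boosted = self._category_units(rng, rhit_factor=2.0)[:6]
        res = pairwise_census(units[:6] + boosted, B=200, seed=1)
        assert res[("RHit", "Miss")].p < 0.05
        assert res[("RHit", "CR")].p < 0.05
        assert res[("Miss", "CR")].p > 0.05

    def test_single_pair_observed_zero(self, rng):
        from emomem.census import UnitCategories

        units = [
            UnitCategories(unit_id="u", patient_id="p", region="HIP",
                           y=np.full(40, 3.0),
                           category=np.repeat([2, 3], 20))
        ]
        res = pairwise_census(units, pairs=[("Miss", "CR")], B=50, seed=0)
        assert res[("Miss", "CR")].observed_count == 0
        assert res[("Miss", "CR")].p == 1.0

    def test_categories_built_from_recognition_trials(self):
        trials = make_trials(
            "recognition",
            [("emotional", "eRHit")] * 4 + [("neutral", "nMiss")] * 3
            + [("neutral", "nCR")] * 3,
        )
        u = simulate_unit(UnitProfile(baseline_rate=5.0), trials, 0)
        cats = build_unit_categories([u], trials)
        assert len(cats) == 1
        # RHit=0, Miss=2, CR=3 in category order
        assert np.bincount(cats[0].category, minlength=4).tolist() == \
            [4, 0, 3, 3]


class TestStratifiedCensus:
    def _units_by_region(self, rng):
        units = []
        for i in range(30):
            region = ["HIP", "AMY", "EC"][i % 3]
            y = rng.poisson(5, 60).astype(float)
            e = np.repeat([0, 1], 30)
            m = np.tile([0] * 15 + [1] * 15, 2)
            if region == "AMY":
                y = y + 5.0 * (e == 0)      # emotion effect only in AMY
            units.append(_unit_counts(y, e, m, unit_id=f"u{i}",
                                      patient=f"p{i % 5}", region=region))
        return units

    def test_emotion_planted_only_in_amygdala(self, rng):
        res = stratified_census(self._units_by_region(rng), by="region",
                                B=200, seed=0)
        assert res["AMY"]["E"].p < 0.05
        assert res["HIP"]["E"].p > 0.05
        assert res["EC"]["E"].p > 0.05

    def test_patient_stratification_returns_every_patient(self, rng):
        res = stratified_census(self._units_by_region(rng), by="patient",
                                B=50, seed=0)
        assert len(res) == 5

    def test_small_stratum_flagged_underpowered(self, rng):
        units = self._units_by_region(rng)[:4]
        res = stratified_census(units, by="region", B=50, seed=0,
                                min_units=10)
        assert all(r.underpowered for s in res.values() for r in s.values())

    def test_unknown_stratum_key(self, rng):
        with pytest.raises(ValueError):
            stratified_census([], by="hemisphere")
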