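"""Scenario engine: evaluation, comparison, ADI verdicts, breakdown table."""

import math
from dataclasses import replace

import numpy as np
import pytest

import nitrocalc as nc
from nitrocalc.errors import NitriteLookupError, ParameterError


def single_contributor_formulation():
    """200 mg tablet whose only nitrite-bearing ingredient is 5 % crospovidone."""
    return nc.Formulation(
        "single",
        200.0,
        (
            nc.Ingredient("API", 0.95, counts_nitrite=False),
            nc.Ingredient("Crospovidone", 0.05,
                          stats=nc.NitriteStats.constant("crospovidone", 6.5)),
        ),
    )


def result_with_total(total, params):
    return nc.EvaluationResult(
        formulation_label=f"total-{total}",
        per_excipient_ng={"x": total},
        total_ng_per_tablet=total,
        total_ng_per_day=total * params.tablets_per_day,
        parameters=params,
        statistic_used={"x": "mean"},
    )


class TestEvaluate:
    def test_crospovidone_only_tablet(self, wg_params):
        """5 % crospovidone at 6.5 ppm, 200 mg, MW 400, 29 %: ~163.9 ng."""
        res = nc.evaluate(single_contributor_formulation(), nc.NitriteDatabase(), wg_params)
        assert res.total_ng_per_tablet == pytest.approx(
            200 * 0.05 * 6.5 * 400 * 0.29 / 46.005, rel=1e-12
        )
        assert round(res.total_ng_per_tablet, 1) == 163.9
        assert res.per_excipient_ng["API"] == 0.0
        assert res.statistic_used["API"] is None

    def test_all_zero_nitrite_gives_zero_total(self, synthetic_pair, wg_params):
        form, _ = synthetic_pair
        zero_db = nc.NitriteDatabase()
        for ing in form.ingredients:
            zero_db.add(nc.NitriteStats.constant(ing.name, 0.0))
        assert nc.evaluate(form, zero_db, wg_params).total_ng_per_tablet == 0.0

    def test_tablets_per_day_scales_daily_total_only(self, synthetic_pair, wg_params):
        form, db = synthetic_pair
        one = nc.evaluate(form, db, wg_params)
        two = nc.evaluate(form, db, replace(wg_params, tablets_per_day=2))
        assert two.total_ng_per_day == pytest.approx(2 * one.total_ng_per_day, rel=1e-12)
        assert two.total_ng_per_tablet == one.total_ng_per_tablet

    def test_unresolved_ingredient_raises_lookup_error(self, wg_params):
        form = nc.Formulation("f", 200, (nc.Ingredient("mystery", 1.0),))
        with pytest.raises(NitriteLookupError, match="mystery"):
            nc.evaluate(form, nc.NitriteDatabase(), wg_params)

    def test_total_is_sum_of_contributions(self, synthetic_pair, wg_params):
        form, db = synthetic_pair
        res = nc.evaluate(form, db, wg_params)
        assert res.total_ng_per_tablet == pytest.approx(
            math.fsum(res.per_excipient_ng.values()), rel=1e-9
        )
        assert all(v >= 0 for v in res.per_excipient_ng.values())

    def test_additivity_zeroing_one_ingredient(self, synthetic_pair, wg_params):
        """Silencing one excipient's nitrite drops the total by exactly its
        contribution."""
        form, db = synthetic_pair
        full = nc.evaluate(form, db, wg_params)
        target = form.ingredients[2]
        silenced = form.replacing(
            target.name,
            replace(target, stats=nc.NitriteStats.constant(target.name, 0.0)),
        )
        part = nc.evaluate(silenced, db, wg_params)
        assert full.total_ng_per_tablet - part.total_ng_per_tablet == pytest.approx(
            full.per_excipient_ng[target.name], rel=1e-12
        )

    def test_scenario_monotonicity(self, synthetic_pair, wg_params):
        form, db = synthetic_pair
        totals = {}
        for stat in ("min", "mean", "max"):
            res = nc.evaluate(form, db, replace(wg_params, nitrite_statistic=stat))
            totals[stat] = res
        assert totals["min"].total_ng_per_tablet <= totals["mean"].total_ng_per_tablet
        assert totals["mean"].total_ng_per_tablet <= totals["max"].total_ng_per_tablet
        for name in totals["mean"].per_excipient_ng:
            assert (totals["min"].per_excipient_ng[name]
                    <= totals["mean"].per_excipient_ng[name]
                    <= totals["max"].per_excipient_ng[name])

    def test_per_ingredient_statistic_override(self, synthetic_pair, wg_params):
        """Switching one excipient's supplier scenario affects only that
        ingredient's contribution."""
        form, db = synthetic_pair
        name = form.ingredients[1].name
        base = nc.evaluate(form, db, wg_params)
        over = nc.evaluate(form, db, replace(wg_params,
                                             statistic_overrides={name: "min"}))
        for other in base.per_excipient_ng:
            if other != name:
                assert over.per_excipient_ng[other] == base.per_excipient_ng[other]
        assert over.per_excipient_ng[name] <= base.per_excipient_ng[name]


class TestCompare:
    def test_printed_totals_reduction(self, wg_params):
        cmp = nc.compare(result_with_total(422.0, wg_params),
                         result_with_total(45.0, wg_params))
        assert cmp.percent_change == pytest.approx(100 * (45 - 422) / 422, rel=1e-12)
        assert cmp.percent_change_display == "-89%"

    def test_identical_scenarios_zero_change(self, wg_params):
        cmp = nc.compare(result_with_total(100.0, wg_params),
                         result_with_total(100.0, wg_params))
        assert cmp.percent_change == 0.0

    def test_increase_arithmetic(self, wg_params):
        cmp = nc.compare(result_with_total(100.0, wg_params),
                         result_with_total(250.0, wg_params))
        assert cmp.percent_change == pytest.approx(150.0)
        assert cmp.percent_change_display == "+150%"

    def test_zero_baseline_reported_not_applicable(self, wg_params):
        cmp = nc.compare(result_with_total(0.0, wg_params),
                         result_with_total(10.0, wg_params))
        assert cmp.percent_change is None
        assert cmp.percent_change_display == "n/a"

    def test_mismatched_parameters_rejected(self, wg_params):
        other = replace(wg_params, nitrosamine_mw=102.0)
        with pytest.raises(ParameterError, match="nitrosamine_mw"):
            nc.compare(result_with_total(1.0, wg_params), result_with_total(1.0, other))

    def test_swap_matches_closed_form_on_random_fixtures(self, wg_params):
        """Percent change from swapping one ingredient's nitrite level equals
        the closed-form linear delta."""
        rng = np.random.default_rng(0)
        for seed in rng.integers(0, 2**31 - 1, size=20):
            spec = nc.FixtureSpec(seed=int(seed), n_ingredients=5)
            form, db = nc.generate_formulation(spec), nc.generate_nitrite_db(spec)
            base = nc.evaluate(form, db, wg_params)
            if base.total_ng_per_tablet == 0:
                continue
            target = form.ingredients[1]
            new_ppm = db.get(target.key).mean_ppm * 0.1
            alt_form = form.replacing(
                target.name,
                replace(target, stats=nc.NitriteStats.constant(target.name, new_ppm)),
            )
            cmp = nc.compare(base, nc.evaluate(alt_form, db, wg_params))
            k = (form.tablet_weight_mg * wg_params.nitrosamine_mw
                 * wg_params.conversion_fraction / wg_params.nitrite_mw)
            delta_nitrite = new_ppm - db.get(target.key).mean_ppm
            expected = 100 * target.fraction_ww * delta_nitrite * k / base.total_ng_per_tablet
            assert cmp.percent_change == pytest.approx(expected, rel=1e-9)


class TestAdi:
    def test_below_limit_compliant(self, wg_params):
        verdicts = nc.classify_adi(result_with_total(45.0, wg_params),
                                   [nc.adi_limit("ndsri-interim-ema-178")])
        assert verdicts[0].compliant and not verdicts[0].at_limit
        assert verdicts[0].margin_ng == pytest.approx(133.0)

    def test_zero_total_compliant_with_any_limit(self, wg_params):
        verdicts = nc.classify_adi(result_with_total(0.0, wg_params),
                                   [nc.AdiLimit("tiny", 1e-6)])
        assert verdicts[0].compliant

    def test_exactly_at_limit_is_compliant_and_flagged(self, wg_params):
        verdicts = nc.classify_adi(result_with_total(178.0, wg_params),
                                   [nc.adi_limit("ndsri-interim-ema-178")])
        assert verdicts[0].compliant and verdicts[0].at_limit

    def test_empty_limit_list_rejected(self, wg_params):
        with pytest.raises(ParameterError):
            nc.classify_adi(result_with_total(1.0, wg_params), [])


class TestContributionTable:
    def test_single_contributor_is_100_percent(self, wg_params):
        res = nc.evaluate(single_contributor_formulation(), nc.NitriteDatabase(), wg_params)
        df = nc.contribution_table(res)
        assert df.iloc[0]["ingredient"] == "Crospovidone"
        assert df.iloc[0]["percent_of_total"] == pytest.approx(100.0)
        assert df["percent_of_total"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_total_flagged_all_zero(self, wg_params):
        res = result_with_total(0.0, wg_params)
        df = nc.contribution_table(res)
        assert df.attrs["zero_total"] is True
        assert (df["percent_of_total"] == 0).all()

    def test_percentages_sum_to_100(self, synthetic_pair, wg_params):
        form, db = synthetic_pair
        df = nc.contribution_table(nc.evaluate(form, db, wg_params))
        assert df["percent_of_total"].sum() == pytest.approx(100.0, abs=1e-6)
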