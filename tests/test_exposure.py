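"""Monte Carlo exposure engine: scenario algebra and analytic median oracles."""

import numpy as np
import pytest

from botanical_rba import distributions as dist
from botanical_rba import exposure as exp
from botanical_rba.reference_data import UnitError
from botanical_rba.reporting import _conc_spec


def _bot(registry, sym, n, seed=1):
    el = registry.elements[sym]
    pattern = registry.consumption[
        "chronic_total_g_per_day" if el.is_essential else "chronic_g_per_kgbw_day"
    ]
    return exp.simulate_botanicals_edi(el, _conc_spec(registry, sym), pattern, n_iter=n, seed=seed)


class TestBotanicalsEDI:
    def test_potassium_median_matches_product_of_analytic_medians(self, registry, n_mc):
        # independent lognormal factors: the product's median is the product of medians
        draws = _bot(registry, "K", n_mc)
        conc_med = dist.analytic_median(_conc_spec(registry, "K"))
        cons = registry.consumption["chronic_total_g_per_day"].moments
        cons_med = dist.analytic_median(dist.lognormal_from_moments(cons.mean, cons.sd))
        assert np.median(draws.values) == pytest.approx(conc_med * cons_med / 1000, rel=0.03)
        assert draws.units == "mg day-1"

    def test_arsenic_median_per_bodyweight(self, registry, n_mc):
        draws = _bot(registry, "As", n_mc)
        assert draws.units == "ug kg_bw-1 day-1"
        assert np.median(draws.values) == pytest.approx(0.0209, rel=0.03)

    def test_degenerate_inputs_give_exact_arithmetic(self, registry):
        el = registry.elements["K"]
        conc = dist.lognormal_from_moments(1000.0, 1e-6)
        pattern = registry.consumption["chronic_total_g_per_day"]
        cons_pattern = type(pattern)(pattern.mode, type(pattern.moments)(
            mean=1.0, sd=1e-9, units=pattern.moments.units))
        draws = exp.simulate_botanicals_edi(el, conc, cons_pattern, n_iter=100, seed=0)
        assert np.allclose(draws.values, 1.0, rtol=1e-4)

    def test_wrong_consumption_pattern_rejected(self, registry):
        el = registry.elements["K"]
        with pytest.raises(UnitError):
            exp.simulate_botanicals_edi(
                el, _conc_spec(registry, "K"),
                registry.consumption["chronic_g_per_kgbw_day"], n_iter=10, seed=0,
            )

    def test_mean_exceeds_median_for_every_element(self, registry):
        # right-skewed products: Table-5-shaped asymmetry
        for sym in registry.elements:
            draws = _bot(registry, sym, 20_000)
            assert draws.values.mean() > np.median(draws.values)


class TestBaseline:
    def test_phosphorus_mean(self, registry, n_mc):
        draws = exp.simulate_baseline(registry.elements["P"], registry, n_iter=n_mc, seed=2)
        assert draws.values.mean() == pytest.approx(1269, rel=0.01)

    def test_lead_median_matches_analytic(self, registry, n_mc):
        draws = exp.simulate_baseline(registry.elements["Pb"], registry, n_iter=n_mc, seed=2)
        assert np.median(draws.values) == pytest.approx(0.1428, rel=0.02)

    def test_unknown_element_rejected(self, registry):
        from botanical_rba.reference_data import ElementSpec

        ghost = ElementSpec("Cd", "toxic", "ug kg-1", "ug kg_bw-1 day-1")
        with pytest.raises(KeyError):
            exp.simulate_baseline(ghost, registry, n_iter=10, seed=0)


class TestCombine:
    def test_linearity_and_share(self, registry):
        base = exp.simulate_baseline(registry.elements["Ca"], registry, n_iter=5000, seed=3)
        bot = _bot(registry, "Ca", 5000, seed=3)
        comb = exp.combine(base, bot)
        assert np.array_equal(comb.values, base.values + bot.values)
        assert comb.values.mean() == pytest.approx(base.values.mean() + bot.values.mean())
        share = comb.components["botanical_share"]
        assert np.all((share > 0) & (share < 1))

    def test_combined_dominates_baseline_pointwise(self, registry):
        base = exp.simulate_baseline(registry.elements["Zn"], registry, n_iter=5000, seed=4)
        bot = _bot(registry, "Zn", 5000, seed=4)
        assert np.all(exp.combine(base, bot).values > base.values)

    def test_calcium_combined_median(self, registry, n_mc):
        base = exp.simulate_baseline(registry.elements["Ca"], registry, n_iter=n_mc, seed=5)
        bot = _bot(registry, "Ca", n_mc, seed=5)
        assert np.median(exp.combine(base, bot).values) == pytest.approx(876, rel=0.05)

    def test_element_mismatch_rejected(self, registry):
        base = exp.simulate_baseline(registry.elements["Ca"], registry, n_iter=100, seed=0)
        bot = _bot(registry, "K", 100)
        with pytest.raises(ValueError):
            exp.combine(base, bot)


class TestWeeklyFromDaily:
    def test_constant_aluminium_dose(self, registry):
        daily = exp.ExposureDraws("Al", "baseline", "daily", "ug kg_bw-1 day-1",
                                  np.full(10, 58.2), seed=0, n_iter=10)
        weekly = exp.weekly_from_daily(daily)
        assert weekly.units == "mg kg_bw-1 week-1"
        assert np.allclose(weekly.values, 0.4074)
        assert weekly.n_iter == daily.n_iter

    def test_aluminium_botanicals_weekly_median(self, registry, n_mc):
        weekly = exp.weekly_from_daily(_bot(registry, "Al", n_mc))
        assert np.median(weekly.values) == pytest.approx(0.006, abs=0.002)

    def test_double_conversion_rejected(self, registry):
        daily = exp.ExposureDraws("Al", "baseline", "daily", "ug kg_bw-1 day-1",
                                  np.full(10, 58.2), seed=0, n_iter=10)
        with pytest.raises(UnitError):
            exp.weekly_from_daily(exp.weekly_from_daily(daily))


class TestAcute:
    def test_nickel_acute_median(self, registry, n_mc):
        draws = exp.simulate_acute(
            registry.elements["Ni"], _conc_spec(registry, "Ni"),
            registry.consumption["acute_g_per_kgbw"], n_iter=n_mc, seed=6,
        )
        assert draws.units == "ug kg_bw-1"
        # product of analytic medians: 760 ug/kg x 0.0743 g/kg / 1000
        assert np.median(draws.values) == pytest.approx(0.0565, rel=0.03)

    def test_acute_requires_acute_pattern(self, registry):
        with pytest.raises(UnitError):
            exp.simulate_acute(
                registry.elements["Ni"], _conc_spec(registry, "Ni"),
                registry.consumption["chronic_g_per_kgbw_day"], n_iter=10, seed=0,
            )

    def test_acute_essential_undefined(self, registry):
        with pytest.raises(UnitError):
            exp.simulate_acute(
                registry.elements["K"], _conc_spec(registry, "K"),
                registry.consumption["acute_g_per_kgbw"], n_iter=10, seed=0,
            )

    def test_seed_determinism(self, registry):
        kw = dict(n_iter=1000, seed=8)
        a = exp.simulate_acute(registry.elements["Ni"], _conc_spec(registry, "Ni"),
                               registry.consumption["acute_g_per_kgbw"], **kw)
        b = exp.simulate_acute(registry.elements["Ni"], _conc_spec(registry, "Ni"),
                               registry.consumption["acute_g_per_kgbw"], **kw)
        assert np.array_equal(a.values, b.values)
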