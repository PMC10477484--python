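"""Abundance extrapolation, growth reporting and effect summaries."""

import numpy as np
import pytest

import banddist as bd
from conftest import make_posterior

AREAS = bd.HabitatAreas({"hab_1": 1_000_000, "hab_2": 2_000_000, "hab_3": 3_000_000})


class TestFlindersAbundance:
    def test_constant_density_times_area(self):
        post = make_posterior(lambda0=0.5)
        est = bd.flinders_abundance(post, 1000.0, 2020)
        assert (est.median, est.ci_low, est.ci_high) == (500.0, 500.0, 500.0)
        assert est.area_ha == 1000.0

    def test_linear_in_area(self):
        rng = np.random.default_rng(0)
        post = make_posterior(lambda0=np.exp(rng.normal(-1, 0.3, (2, 50))))
        a = bd.flinders_abundance(post, 1000.0, 2020)
        b = bd.flinders_abundance(post, 2000.0, 2020)
        for f in ("median", "ci_low", "ci_high"):
            assert getattr(b, f) == pytest.approx(2 * getattr(a, f))

    def test_uses_realised_year_effect(self):
        post = make_posterior(lambda0=0.5, epsilon=(np.log(2.0), 0.0), years=(2019, 2020))
        est = bd.flinders_abundance(post, 100.0, 2019)
        assert est.median == pytest.approx(100.0)  # 0.5 * e^{eps} = 1.0 /ha

    def test_year_outside_span_rejected(self):
        post = make_posterior()
        with pytest.raises(ValueError, match="span"):
            bd.flinders_abundance(post, 100.0, 1990)

    def test_requires_flinders_fit(self):
        post = make_posterior(variant="mainland")
        with pytest.raises(ValueError):
            bd.flinders_abundance(post, 100.0, 2020)


class TestMainlandAbundance:
    def test_uniform_density_times_total_area(self):
        areas = bd.HabitatAreas({"hab_1": 3_000_000, "hab_2": 2_000_000, "hab_3": 1_561_553})
        post = make_posterior(variant="mainland", lambda0=0.1, beta=(0.0, 0.0, 0.0))
        est = bd.mainland_abundance(post, areas)
        assert est.median == pytest.approx(656_155.3)
        assert est.area_ha == pytest.approx(6_561_553)

    def test_zero_area_habitat_is_irrelevant(self):
        post = make_posterior(variant="mainland", lambda0=0.2, beta=(0.1, -0.2, 0.5))
        with_zero = bd.HabitatAreas({**AREAS.areas, "hab_3": 0.0})
        a = bd.mainland_abundance(post, with_zero)
        b = bd.conservative_abundance(post, with_zero, ["hab_3"])
        assert a.median == pytest.approx(b.median)

    def test_per_draw_matches_brute_force_loop(self):
        rng = np.random.default_rng(4)
        post = make_posterior(
            variant="mainland",
            lambda0=np.exp(rng.normal(-2, 0.5, (2, 50))),
            beta=rng.normal(0, 0.5, (2, 50, 3)),
        )
        got = bd.mainland_abundance_draws(post, AREAS)
        lam = post.pooled("lambda0")
        beta = post.pooled("beta")
        want = np.zeros_like(lam)
        for i in range(lam.size):
            acc = 0.0
            for k, h in enumerate(("hab_1", "hab_2", "hab_3")):
                acc += AREAS.areas[h] * np.exp(beta[i, k])
            want[i] = lam[i] * acc
        np.testing.assert_allclose(got, want, atol=1e-9, rtol=1e-12)

    def test_missing_area_is_an_error_extra_is_a_warning(self):
        post = make_posterior(variant="mainland")
        with pytest.raises(KeyError):
            bd.mainland_abundance(post, bd.HabitatAreas({"hab_1": 10.0}))
        extra = bd.HabitatAreas({**AREAS.areas, "unfitted": 5.0})
        with pytest.warns(UserWarning, match="unfitted"):
            bd.mainland_abundance(post, extra)


class TestConservativeAbundance:
    def test_no_exclusions_is_the_full_estimate(self):
        post = make_posterior(variant="mainland", lambda0=0.3, beta=(0.0, 0.4, -0.6))
        full = bd.mainland_abundance(post, AREAS)
        cons = bd.conservative_abundance(post, AREAS, [])
        assert cons.median == pytest.approx(full.median)
        assert cons.area_ha == full.area_ha

    def test_excluding_everything_gives_zero(self):
        post = make_posterior(variant="mainland")
        est = bd.conservative_abundance(post, AREAS, ["hab_1", "hab_2", "hab_3"])
        assert est.median == 0.0
        assert est.area_ha == 0.0

    def test_per_draw_additivity(self):
        rng = np.random.default_rng(8)
        post = make_posterior(
            variant="mainland",
            n_draw=80,
            lambda0=np.exp(rng.normal(-2, 0.6, (2, 80))),
            beta=rng.normal(0, 0.7, (2, 80, 3)),
        )
        excluded = ["hab_2"]
        full = bd.mainland_abundance_draws(post, AREAS)
        kept = bd.mainland_abundance_draws(post, AREAS, include=["hab_1", "hab_3"])
        dropped = bd.mainland_abundance_draws(post, AREAS, include=excluded)
        np.testing.assert_allclose(kept + dropped, full, atol=1e-9, rtol=1e-12)

    def test_unknown_excluded_label(self):
        post = make_posterior(variant="mainland")
        with pytest.raises(KeyError):
            bd.conservative_abundance(post, AREAS, ["atlantis"])


class TestGrowth:
    def test_zero_growth(self):
        post = make_posterior(r=0.0)
        assert bd.growth_percent(post)["median"] == 0.0

    def test_five_percent_multiplier(self):
        post = make_posterior(r=np.log(1.05))
        assert bd.growth_percent(post)["median"] == pytest.approx(5.0, abs=1e-9)

    def test_conventions_differ_by_under_five_hundredths(self):
        r = 0.029
        assert abs(100 * r - 100 * (np.exp(r) - 1)) < 0.05
        post = make_posterior(r=r)
        g = bd.growth_percent(post)
        assert g["median"] == pytest.approx(100 * (np.exp(r) - 1))
        assert g["median_100r"] == pytest.approx(2.9)

    def test_growth_ratio(self):
        assert round(bd.growth_ratio(2.90, 1.20), 1) == 2.4
        with pytest.raises(ZeroDivisionError):
            bd.growth_ratio(1.0, 0.0)


class TestAnnualSeries:
    def test_flat_series_without_trend_or_effects(self):
        post = make_posterior(lambda0=0.42, r=0.0, epsilon=(0.0, 0.0))
        series = bd.annual_density_series(post)
        np.testing.assert_allclose(series["median"], 0.42)

    def test_reference_year_equals_lambda(self):
        post = make_posterior(lambda0=0.42, r=0.1, epsilon=(0.3, 0.0))
        series = bd.annual_density_series(post, years=[2020])
        assert series.loc[2020, "median"] == pytest.approx(0.42)

    def test_mainland_needs_areas(self):
        post = make_posterior(variant="mainland")
        with pytest.raises(ValueError, match="area"):
            bd.annual_density_series(post)
        series = bd.annual_density_series(post, areas=AREAS)
        assert len(series) == 2


class TestEffectSummaries:
    def test_reference_habitat_equals_lambda_summary(self):
        rng = np.random.default_rng(11)
        lam = np.exp(rng.normal(-2, 0.4, (2, 60)))
        post = make_posterior(variant="mainland", n_draw=60, lambda0=lam, beta=(0.0, 0.4, -0.6))
        tables = bd.effect_summaries(post)
        lam_q = np.percentile(lam.reshape(-1), [50, 2.5, 97.5])
        row = tables["habitat"].loc["hab_1"]
        assert row["median_density"] == pytest.approx(lam_q[0])
        assert row["ci_low"] == pytest.approx(lam_q[1])

    def test_zero_betas_give_identical_rows(self):
        post = make_posterior(variant="mainland", lambda0=0.2, beta=(0.0, 0.0, 0.0))
        table = bd.effect_summaries(post)["habitat"]
        assert table["median_density"].nunique() == 1

    def test_flinders_fit_rejected(self):
        post = make_posterior(variant="flinders")
        with pytest.raises(ValueError):
            bd.effect_summaries(post)

    def test_region_multipliers_centre_on_one_under_the_prior(self):
        # with no data, the zero-mean region-effect prior implies exp(eta)
        # multipliers whose per-region geometric mean is 1
        design = bd.make_design("mainland", 8, [2020], n_habitats=3, n_regions=4, seed=3)
        ds, _ = bd.simulate(design, bd.default_truth("mainland"), seed=3)
        prior = bd.sample_prior(ds, "mainland", n=4000, seed=3)
        geo_mean = np.exp(np.mean(np.log(np.exp(prior["eta"])), axis=0))
        np.testing.assert_allclose(geo_mean, 1.0, atol=0.06)


def test_abundance_estimate_ordering_enforced():
    with pytest.raises(ValueError):
        bd.AbundanceEstimate(median=10, ci_low=20, ci_high=30, area_ha=1.0)
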