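"""Expected-density equations and the overdispersed count likelihood."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import banddist as bd


def _flat_dataset(variant="flinders", n_transects=2, years=(2019, 2020), seed=0):
    design = bd.make_design(variant, n_transects, years, n_habitats=3, n_regions=2, seed=seed)
    ds, truth = bd.simulate(design, bd.default_truth(variant), seed=seed)
    return ds, truth


class TestMeanDensity:
    def test_all_effects_zero_gives_lambda(self):
        ds, _ = _flat_dataset()
        params = bd.DensityParams(lambda0=0.7, growth=0.0, phi=0.0)
        for year in (2019, 2020):
            assert bd.mean_density(ds, "T1", year, params, "flinders") == pytest.approx(0.7)

    def test_mainland_with_zero_beta_reduces_to_flinders_plus_region(self):
        ds, _ = _flat_dataset("mainland")
        params = bd.DensityParams(
            lambda0=0.2, growth=0.03, phi=0.0,
            eta={"region_1": 0.4}, epsilon={2019: -0.1},
        )
        m = bd.mean_density(ds, "T1", 2019, params, "mainland")
        region = ds.transect("T1").region_id
        expected = 0.2 * np.exp(0.03 * (2019 - 2020) - 0.1 + params.eta.get(region, 0.0))
        assert m == pytest.approx(expected, rel=1e-12)

    def test_single_habitat_multiplier(self):
        bands = bd.DistanceBands()
        t = bd.TransectRecord("J", 10.0, "R", (1.0, 0.0))
        ds = bd.SurveyDataset(
            bands=bands, transects=[t], observations=[],
            habitat_names=("a", "b"), region_names=("R",), years=(2020,),
        )
        params = bd.DensityParams(lambda0=0.5, growth=0.0, phi=0.0, beta={"a": np.log(2)})
        assert bd.mean_density(ds, "J", 2020, params, "mainland") == pytest.approx(1.0)

    def test_log_linear_in_time(self):
        ds, _ = _flat_dataset(years=range(2015, 2021))
        params = bd.DensityParams(lambda0=0.4, growth=0.07, phi=0.0,
                                  delta={"T1": 0.2}, epsilon={})
        vals = [bd.mean_density(ds, "T1", y, params, "flinders") for y in range(2015, 2021)]
        diffs = np.diff(np.log(vals))
        np.testing.assert_allclose(diffs, 0.07, rtol=1e-10)


class TestExpectedCount:
    def test_zero_density_gives_zero(self):
        ds, truth = _flat_dataset()
        params = bd.DensityParams(lambda0=0.0, growth=0.0, phi=0.0)
        for b in range(6):
            assert bd.expected_count(ds, b, "T1", 2020, truth.detection, params, "flinders") == 0.0

    def test_perfect_detection_strip_area(self):
        # p=1 in every band, 10 km transect, 0.5/ha: strip is 2*100m*10km = 200 ha
        ds, _ = _flat_dataset()
        det = bd.FlindersDetectionParams(1e12, 1e12, 0.0, 0.0)
        params = bd.DensityParams(lambda0=0.5, growth=0.0, phi=0.0)
        total = sum(
            bd.expected_count(ds, b, "T1", 2020, det, params, "flinders") for b in range(6)
        )
        assert total == pytest.approx(100.0, rel=1e-6)

    def test_band_decomposition_telescopes_to_strip_integral(self):
        ds, truth = _flat_dataset()
        det = truth.detection
        params = bd.DensityParams(lambda0=0.31, growth=0.0, phi=0.0)
        total = sum(
            bd.expected_count(ds, b, "T1", 2020, det, params, "flinders") for b in range(6)
        )
        integral, _ = quad(lambda x: bd.detect_flinders(x, 2020, det), 0, 100,
                           epsabs=1e-12, limit=200)
        expected = 2.0 * integral * ds.transect("T1").length_m * 0.31 / 1e4
        assert total == pytest.approx(expected, abs=1e-8)

    def test_linear_in_density_and_length(self):
        ds, truth = _flat_dataset()
        p1 = bd.DensityParams(lambda0=0.2, growth=0.0, phi=0.0)
        p2 = bd.DensityParams(lambda0=0.6, growth=0.0, phi=0.0)
        a = bd.expected_count(ds, 2, "T1", 2020, truth.detection, p1, "flinders")
        b = bd.expected_count(ds, 2, "T1", 2020, truth.detection, p2, "flinders")
        assert b == pytest.approx(3 * a, rel=1e-12)


class TestCountLoglik:
    def test_zero_mean(self):
        assert bd.count_loglik(0, 0.0, 0.5) == 0.0
        assert bd.count_loglik(3, 0.0, 0.5) == -np.inf

    def test_poisson_limit(self):
        for mean in (0.1, 1.0, 10.0):
            for count in range(21):
                got = bd.count_loglik(count, mean, 0.0)
                assert got == pytest.approx(stats.poisson.logpmf(count, mean), abs=1e-12)

    def test_matches_scipy_negative_binomial(self):
        # mean m, variance m(1+phi m)  <=>  nbinom(n=1/phi, p=1/(1+phi m))
        rng = np.random.default_rng(5)
        for _ in range(50):
            m, phi = rng.uniform(0.1, 20), rng.uniform(0.05, 3)
            y = rng.integers(0, 30)
            assert bd.count_loglik(y, m, phi) == pytest.approx(
                stats.nbinom.logpmf(y, 1 / phi, 1 / (1 + phi * m)), rel=1e-12
            )

    def test_sampler_moments(self):
        # the matching sampler: mean 5, phi 0.4 -> variance 5*(1+2) = 15
        rng = np.random.default_rng(99)
        m, phi, n = 5.0, 0.4, 1_000_000
        rr = 1 / phi
        draws = rng.negative_binomial(rr, rr / (rr + m), n)
        var = m * (1 + phi * m)
        se_mean = np.sqrt(var / n)
        assert abs(draws.mean() - m) < 3 * se_mean
        # SE of the sample variance via the fourth central moment
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_var = np.sqrt((m4 - var**2) / n)
        assert abs(draws.var() - var) < 3 * se_var


class TestTotalLoglik:
    @staticmethod
    def _brute_force(ds, det, dens, variant):
        """Naive re-implementation: explicit loops and scipy only."""
        counts = {
            (o.transect_id, o.year, o.band_index): o.count for o in ds.observations
        }
        pairs = sorted({(o.transect_id, o.year) for o in ds.observations})
        ll = 0.0
        for tid, year in pairs:
            for b in range(ds.bands.n_bands):
                y = counts.get((tid, year, b), 0)
                lam = dens.lambda0 * np.exp(
                    dens.growth * (year - ds.reference_year)
                    + dens.delta.get(tid, 0.0)
                    + dens.epsilon.get(year, 0.0)
                )
                if variant == "mainland":
                    t = ds.transect(tid)
                    lam *= np.exp(dens.eta.get(t.region_id, 0.0))
                    lam *= sum(
                        p * np.exp(dens.beta.get(h, 0.0))
                        for h, p in zip(ds.habitat_names, t.habitat_props)
                    )
                    j = ds.transect_ids.index(tid)
                    p_b = bd.band_prob_mainland(b, ds.bands, det.kappa, det.alpha[j])
                else:
                    p_b = bd.band_prob_flinders(b, year, ds.bands, det)
                w = ds.bands.widths[b]
                m = p_b * 2 * w * ds.transect(tid).length_m * lam / 1e4
                if dens.phi == 0:
                    ll += stats.poisson.logpmf(y, m)
                else:
                    rr = 1 / dens.phi
                    ll += stats.nbinom.logpmf(y, rr, rr / (rr + m))
        for tid in ds.transect_ids:
            ll += stats.norm.logpdf(dens.delta.get(tid, 0.0), scale=dens.sigma_transect)
        for year in ds.year_list:
            ll += stats.norm.logpdf(dens.epsilon.get(year, 0.0), scale=dens.sigma_year)
        if variant == "mainland":
            for reg in ds.region_names:
                ll += stats.norm.logpdf(dens.eta.get(reg, 0.0), scale=dens.sigma_region)
            la = np.log(np.asarray(det.alpha))
            ll += stats.norm.logpdf(la, loc=det.mu_alpha, scale=det.sigma_alpha).sum()
        return float(ll)

    @pytest.mark.parametrize("variant", ["flinders", "mainland"])
    def test_matches_brute_force(self, variant):
        design = bd.make_design(variant, 5, range(2018, 2021), n_habitats=3,
                                n_regions=2, seed=3)
        ds, truth = bd.simulate(design, bd.default_truth(variant), seed=3)
        got = bd.total_loglik(ds, truth.detection, truth.density, variant)
        want = self._brute_force(ds, truth.detection, truth.density, variant)
        assert got == pytest.approx(want, abs=1e-9)

    def test_permutation_invariant(self, flinders_sim):
        ds, truth = flinders_sim
        base = bd.total_loglik(ds, truth.detection, truth.density, "flinders")
        shuffled = bd.SurveyDataset(
            bands=ds.bands,
            transects=list(ds.transects),
            observations=list(reversed(ds.observations)),
            reference_year=ds.reference_year,
            habitat_names=ds.habitat_names,
            region_names=ds.region_names,
        )
        assert bd.total_loglik(shuffled, truth.detection, truth.density, "flinders") == base

    def test_lambda_beta_rescaling_leaves_likelihood_unchanged(self, mainland_sim):
        # multiplying every exp(beta) by c and dividing lambda by c is a
        # likelihood invariance; the reference-habitat constraint in the fit
        # removes exactly this flat direction
        ds, truth = mainland_sim
        dens = truth.density
        c = 1.7
        import dataclasses

        scaled = dataclasses.replace(
            dens,
            lambda0=dens.lambda0 / c,
            beta={h: b + np.log(c) for h, b in dens.beta.items()},
        )
        counts_only = lambda d: sum(
            bd.count_loglik(
                o.count,
                bd.expected_count(ds, o.band_index, o.transect_id, o.year,
                                  truth.detection, d, "mainland"),
                d.phi,
            )
            for o in ds.observations
        )
        assert counts_only(scaled) == pytest.approx(counts_only(dens), rel=1e-10)
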