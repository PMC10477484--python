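"""Hierarchical expected-density equations and the overdispersed count likelihood.

Density on transect j in year t is log-linear in time with zero-mean normal
random effects:

* flinders variant: ``lambda_bar = lambda0 * exp(r (t-T) + delta_j + eps_t)``
* mainland variant: ``lambda_bar = lambda0 * exp(r (t-T) + delta_j + eps_t + eta_m)
  * sum_i p_ij exp(beta_i)`` — a transect is an area-weighted mixture of
  habitat-specific densities, with one reference habitat's beta fixed at 0
  so (lambda0, beta) is identified.

The expected banded count multiplies the mean detection probability over the
band, the band area on both road sides, and the density:

    ``nbar_{i,j,t} = p_{i,t} * 2 (x_i - x_{i-1}) * l_j * lambda_bar_{j,t}``

with the single ha <-> m^2 conversion (1e-4) applied here and nowhere else.
Counts are negative-binomial with mean ``nbar`` and variance
``nbar (1 + phi * nbar)``; ``phi = 0`` is the Poisson limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .detection import (
    FlindersDetectionParams,
    MainlandDetectionParams,
    band_prob_flinders,
    band_prob_mainland,
)
from .survey_data import SurveyDataset

__all__ = [
    "DensityParams",
    "mean_density",
    "expected_count",
    "count_loglik",
    "total_loglik",
]

M2_PER_HA = 10_000.0


@dataclass
class DensityParams:
    """Density-model parameters with labelled random effects.

    Effects are dictionaries keyed by the identifiers they modify
    (transect id, calendar year, region id, habitat name); absent keys are
    treated as zero.  ``beta`` must assign exactly 0 to the reference
    habitat of a mainland fit.
    """

    lambda0: float
    growth: float
    phi: float
    delta: dict[str, float] = field(default_factory=dict)
    epsilon: dict[int, float] = field(default_factory=dict)
    eta: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    sigma_transect: float = 0.0
    sigma_year: float = 0.0
    sigma_region: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be non-negative")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        for name in ("sigma_transect", "sigma_year", "sigma_region"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def mean_density(
    dataset: SurveyDataset,
    transect_id: str,
    year: int,
    params: DensityParams,
    variant: str,
) -> float:
    """Expected density lambda_bar_{j,t} in individuals per hectare."""
    transect = dataset.transect(transect_id)
    log_term = (
        params.growth * (year - dataset.reference_year)
        + params.delta.get(transect_id, 0.0)
        + params.epsilon.get(year, 0.0)
    )
    if variant == "flinders":
        return params.lambda0 * float(np.exp(log_term))
    if variant == "mainland":
        if transect.region_id is not None:
            log_term += params.eta.get(transect.region_id, 0.0)
        if transect.habitat_props is None:
            raise ValueError(f"transect {transect_id!r} has no habitat proportions")
        habitat_mult = sum(
            p * np.exp(params.beta.get(name, 0.0))
            for name, p in zip(dataset.habitat_names, transect.habitat_props)
        )
        return params.lambda0 * float(np.exp(log_term)) * float(habitat_mult)
    raise ValueError(f"unknown variant {variant!r}")


def expected_count(
    dataset: SurveyDataset,
    band_index: int,
    transect_id: str,
    year: int,
    det_params,
    dens_params: DensityParams,
    variant: str,
) -> float:
    """Expected number of animals counted in one band of one transect-year."""
    bands = dataset.bands
    if variant == "flinders":
        if not isinstance(det_params, FlindersDetectionParams):
            raise TypeError("flinders variant needs FlindersDetectionParams")
        p = band_prob_flinders(band_index, year, bands, det_params)
    elif variant == "mainland":
        if not isinstance(det_params, MainlandDetectionParams):
            raise TypeError("mainland variant needs MainlandDetectionParams")
        j = dataset.transect_ids.index(transect_id)
        p = band_prob_mainland(band_index, bands, det_params.kappa, det_params.alpha[j])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    width_m = bands.widths[band_index]
    lam = mean_density(dataset, transect_id, year, dens_params, variant)
    length_m = dataset.transect(transect_id).length_m
    # both road sides surveyed; density per ha -> per m^2
    return float(p * 2.0 * width_m * length_m * lam / M2_PER_HA)


def count_loglik(count, mean, phi):
    """Log-probability of a banded count under the overdispersed model.

    Negative binomial with mean ``m`` and variance ``m (1 + phi m)``;
    ``phi = 0`` evaluates the exact Poisson limit; ``m = 0`` returns 0 for a
    zero count and -inf otherwise.  Broadcasts over array inputs.
    """
    y = np.asarray(count)
    m = np.asarray(mean, dtype=float)
    if np.any(y < 0) or np.any(np.asarray(y) != np.floor(y)):
        raise ValueError("count must be a non-negative integer")
    if np.any(m < 0):
        raise ValueError("mean must be >= 0")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    y = y.astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        if phi == 0.0:
            out = stats.poisson.logpmf(y, m)
        else:
            rr = 1.0 / phi
            out = stats.nbinom.logpmf(y, rr, rr / (rr + m))
        out = np.where(m == 0.0, np.where(y == 0, 0.0, -np.inf), out)
    return out if out.ndim else float(out)


def _normal_effect_logpdf(values: np.ndarray, sigma: float) -> float:
    """Sum of Normal(0, sigma^2) log-densities; sigma=0 is a point mass at 0."""
    if sigma == 0.0:
        return 0.0 if np.all(values == 0.0) else -np.inf
    return float(np.sum(stats.norm.logpdf(values, scale=sigma)))


def total_loglik(
    dataset: SurveyDataset,
    det_params,
    dens_params: DensityParams,
    variant: str,
) -> float:
    """Joint log-density: banded-count likelihood plus random-effect terms.

    The count term sums over every band of every surveyed (transect, year)
    pair, treating bands without a record as zero counts.  Random-effect
    terms are Normal(0, sigma^2) log-densities for delta, epsilon and (for
    the mainland variant) eta, plus the log-normal terms for the
    per-transect detection decline rates.
    """
    years = dataset.year_list
    ll = 0.0
    pairs = sorted({(o.transect_id, o.year) for o in dataset.observations})
    counts: dict[tuple[str, int, int], int] = {
        (o.transect_id, o.year, o.band_index): o.count for o in dataset.observations
    }
    for tid, year in pairs:
        for b in range(dataset.bands.n_bands):
            y = counts.get((tid, year, b), 0)
            m = expected_count(dataset, b, tid, year, det_params, dens_params, variant)
            ll += count_loglik(y, m, dens_params.phi)

    delta = np.array([dens_params.delta.get(t, 0.0) for t in dataset.transect_ids])
    eps = np.array([dens_params.epsilon.get(y, 0.0) for y in years])
    ll += _normal_effect_logpdf(delta, dens_params.sigma_transect)
    ll += _normal_effect_logpdf(eps, dens_params.sigma_year)
    if variant == "mainland":
        regions = dataset.region_names
        eta = np.array([dens_params.eta.get(r, 0.0) for r in regions])
        ll += _normal_effect_logpdf(eta, dens_params.sigma_region)
        if isinstance(det_params, MainlandDetectionParams) and det_params.sigma_alpha > 0:
            la = np.log(np.asarray(det_params.alpha, dtype=float))
            ll += float(
                np.sum(stats.norm.logpdf(la, loc=det_params.mu_alpha, scale=det_params.sigma_alpha))
            )
    return float(ll)
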