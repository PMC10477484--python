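import numpy as np
import pytest

import banddist as bd


@pytest.fixture(scope="session")
def flinders_sim():
    """A small island-style simulated dataset with its generating truth."""
    design = bd.make_design("flinders", 4, range(2016, 2021), seed=11)
    return bd.simulate(design, bd.default_truth("flinders"), seed=11)


@pytest.fixture(scope="session")
def mainland_sim():
    """A small mainland-style simulated dataset (habitats + regions)."""
    design = bd.make_design(
        "mainland", 6, range(2016, 2021), n_habitats=3, n_regions=2, seed=12
    )
    return bd.simulate(design, bd.default_truth("mainland"), seed=12)


def make_posterior(
    variant="flinders",
    n_chain=2,
    n_draw=50,
    lambda0=None,
    r=None,
    epsilon=None,
    beta=None,
    eta=None,
    years=(2019, 2020),
    habitats=("hab_1", "hab_2", "hab_3"),
    regions=("region_1", "region_2"),
    reference_year=2020,
):
    """Hand-built PosteriorDraws for unit-testing the post-processing ops."""
    shape = (n_chain, n_draw)

    def fill(val, extra=()):
        if val is None:
            val = 0.0
        a = np.asarray(val, dtype=float)
        if a.shape == () or (extra and a.shape == (len(extra),)):
            return np.broadcast_to(a, shape + ((len(extra),) if extra else ())).copy()
        return a

    draws = {
        "lambda0": fill(0.5 if lambda0 is None else lambda0),
        "r": fill(0.0 if r is None else r),
        "phi": fill(0.5),
        "epsilon": fill(epsilon, extra=years),
        "delta": fill(None, extra=("T1",)),
        "sigma_transect": fill(0.3),
        "sigma_year": fill(0.15),
    }
    dims = {
        "lambda0": None,
        "r": None,
        "phi": None,
        "epsilon": "year",
        "delta": "transect",
        "sigma_transect": None,
        "sigma_year": None,
    }
    if variant == "mainland":
        draws["beta"] = fill(beta, extra=habitats)
        draws["eta"] = fill(eta, extra=regions)
        draws["kappa"] = fill(0.05)
        dims.update({"beta": "habitat", "eta": "region", "kappa": None})
    coords = {
        "transect": ["T1"],
        "year": list(years),
        "habitat": list(habitats) if variant == "mainland" else [],
        "region": list(regions) if variant == "mainland" else [],
    }
    return bd.PosteriorDraws(
        draws=draws,
        coords=coords,
        dims=dims,
        variant=variant,
        reference_year=reference_year,
        reference_habitat=habitats[0] if variant == "mainland" else None,
        fingerprint="synthetic",
        config={},
        rhat={},
    )
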