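import numpy as np
import pytest

import edufert as ef


@pytest.fixture(scope="session")
def world():
    """Default desk-scale synthetic world (6 countries, 1,680 cells)."""
    return ef.generate_world(seed=11)


@pytest.fixture(scope="session")
def glm(world):
    return ef.GLMInitializer(world.lattice).fit(world.surveys)


@pytest.fixture(scope="session")
def inputs(world, glm):
    return ef.build_inputs(world, glm)


@pytest.fixture(scope="session")
def fitted(inputs):
    """A short but converged fit of the final model on the default world."""
    return ef.EAFRModel(chains=2, warmup=300, iterations=500, random_state=5).fit(
        inputs
    )


@pytest.fixture(scope="session")
def small_world():
    """A 3-country, 5-period world for the expensive refit loops."""
    regions = {
        "Country A": "sub-Saharan Africa",
        "Country B": "North Africa",
        "Country C": "Latin America",
    }
    cfg = ef.WorldConfig(
        region_assignment=regions,
        periods=tuple(f"{y}-{y+5}" for y in range(1995, 2020, 5)),
        survey_years={c: [2005, 2015] for c in regions},
        seed=7,
    )
    return ef.generate_world(cfg)


@pytest.fixture(scope="session")
def small_inputs(small_world):
    glm = ef.GLMInitializer(small_world.lattice).fit(small_world.surveys)
    return ef.build_inputs(small_world, glm)


def single_cell_inputs(m0=0.2, tau0=400.0, bench=0.25, tau_asfr=400.0):
    """One-cell lattice with degenerate weight 1: the conjugate oracle setup."""
    lat = ef.Lattice(
        countries=("Country A",),
        regions={"Country A": "Europe"},
        periods=("2000-2005",),
        age_groups=("25-29",),
        education_levels=("No Education",),
    )
    stats = ef.PriorStatistics(
        sigma_e=np.array([0.05]),
        mu_e=np.array([0.05]),
        sigma2_e=np.array([0.0025]),
        sigma2_pooled=0.0025,
        sigma_pooled=0.05,
        sigma2_est=0.01,
        sigma_ae=np.array([[0.05]]),
        sigma_etfr_e4=0.5,
        var_mean_ratio=0.05,
    )
    spec = ef.PriorSpec(
        name="final",
        shape=np.array([[1.0 / 0.05]]),
        rate=np.array([[2 * 0.05]]),
        grouping="education",
    )
    return ef.ModelInputs(
        lattice=lat,
        init_mean=np.full((1, 1, 1, 1), m0),
        weights=np.ones((1, 1, 1, 1)),
        benchmark=np.full((1, 1, 1), bench),
        prior_stats=stats,
        prior_spec=spec,
        tau_asfr=tau_asfr,
    ), tau0
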