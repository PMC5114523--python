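import pytest

from ckmrkit import simulate as sim
from ckmrkit.popdyn import Logistic, PowerFecundity


@pytest.fixture(scope="session")
def growth():
    return sim.default_growth()


@pytest.fixture(scope="session")
def pop_params():
    return sim.default_pop_params()


@pytest.fixture(scope="session")
def sim_config():
    return sim.default_config()


@pytest.fixture(scope="session")
def small_population():
    """One desk-scale population plus samples, reused across read-only tests."""
    cfg = sim.default_config()
    pop = sim.simulate_population(cfg, 42)
    samples = sim.simulate_sampling(pop, None, 42)
    return pop, samples


@pytest.fixture(scope="session")
def genotyped_dataset(small_population):
    """Population, samples and one error-free genotype realization."""
    pop, samples = small_population
    panel = sim.simulate_genotypes(pop, samples.fish_id.tolist(), 42,
                                   miscall_rate=0.0)
    return pop, samples, panel


def equal_fecundity_params(n_adults=2000.0, survival=0.77):
    """Flat selectivity and length-independent fecundity: every adult of a
    sex has the same chance of parenting (the simple-estimator limit)."""
    p = sim.default_pop_params(n_adults=n_adults, survival=survival,
                               sigma_r=0.0)
    flat = Logistic(0.0, 0.0)  # constant 0.5 at all lengths
    return type(p)(growth=p.growth, z=p.z,
                   mean_log_recruitment=p.mean_log_recruitment,
                   years=p.years, sigma_r=0.0,
                   selectivity_female=flat, selectivity_male=flat,
                   female_daily_fecundity=PowerFecundity(1.0, 0.0),
                   length_weight=p.length_weight)
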