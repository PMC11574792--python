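import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_population():
    """A 300-subject phantom population on a 16^3 grid with the default truth."""
    from dosemap_ntcp import synthetic_cohort as sc

    config = sc.PhantomConfig(grid_shape=(16, 16, 16), seed=11)
    return sc.generate_population(config, sc.PlantedTruth(), 300)


@pytest.fixture(scope="session")
def strong_population():
    """A 200-subject population with a strong planted dose effect and no
    clinical contribution (near-balanced classes, planted AUROC ~0.98)."""
    from dosemap_ntcp import synthetic_cohort as sc

    config = sc.PhantomConfig(grid_shape=(16, 16, 16), seed=7)
    truth = sc.PlantedTruth(beta0=-18.0, beta_dose=0.45, beta_clinical={})
    return sc.generate_population(config, truth, 200)


@pytest.fixture(scope="session")
def strong_maps(strong_population):
    """Preprocessed, normalised (N,1,12,12,12) dose maps of strong_population."""
    import numpy as np

    from dosemap_ntcp import preprocess as pp

    maps = []
    for s in strong_population.subjects:
        eq = pp.EQD2Params(alpha_beta=3.0, n_fractions=s.record.n_fractions)
        maps.append(
            pp.preprocess_subject(
                s.dose, s.mask, eq, None, (12, 12, 12), margin=1,
                subject_id=s.record.subject_id,
            )
        )
    stats = pp.fit_normalisation([m.values for m in maps])
    x = np.stack([pp.apply_normalisation(m.values, stats) * m.mask for m in maps])
    return x[:, None], strong_population.labels()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
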