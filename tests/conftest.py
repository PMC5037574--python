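import numpy as np
import pytest

from metabodisc.preprocess import BinningConfig
from metabodisc.simulate import CohortScenario, MetaboliteSpec


@pytest.fixture(scope="session")
def tiny_library():
    """Three well-separated singlet metabolites on a short axis."""
    return (
        MetaboliteSpec("A", ((1.0, 1.0, 1.2),), 5.0),
        MetaboliteSpec("B", ((2.0, 1.0, 1.2),), 5.0),
        MetaboliteSpec("C", ((3.0, 1.0, 1.2),), 5.0),
    )


@pytest.fixture
def tiny_scenario(tiny_library):
    """Small, fast cohort: 3 metabolites, 0.5-3.5 ppm, 4096 points."""
    return CohortScenario(
        library=tiny_library,
        n_per_group=5,
        axis_range=(0.5, 3.5),
        n_points=4096,
        fold_changes={"B": 2.0},
        within_group_cv=0.02,
        noise_sd=0.5,
        shift_jitter_sd=0.0002,
        seed=7,
    )


@pytest.fixture
def tiny_binning():
    """Binning config matched to the tiny scenario's 0.5-3.5 ppm axis."""
    return BinningConfig(bin_width=0.002, range=(0.5, 3.5), excluded_regions=())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


def small_cohort_calls(fold, seed, cv=0.05):
    """Run the full pipeline on a 3-metabolite cohort, returning the call table."""
    from metabodisc.pipeline import RunConfig, run_pipeline

    library = (
        MetaboliteSpec("target", ((1.5, 1.0, 1.2),), 8.0),
        MetaboliteSpec("bg1", ((2.2, 1.0, 1.2),), 8.0),
        MetaboliteSpec("bg2", ((2.8, 1.0, 1.2),), 8.0),
    )
    scenario = CohortScenario(
        library=library, n_per_group=5, axis_range=(0.5, 3.5), n_points=3000,
        fold_changes={"target": fold} if fold != 1.0 else {},
        within_group_cv=cv, noise_sd=0.5, shift_jitter_sd=0.0002, seed=seed,
    )
    config = RunConfig(
        scenario=scenario,
        binning=BinningConfig(range=(0.5, 3.5), excluded_regions=()),
        seed=seed,
    )
    return run_pipeline(config).calls
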