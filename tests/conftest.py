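import logging

import numpy as np
import pytest

from cansplice.diff_splicing import screen_events
from cansplice.synthetic_cohort import SyntheticConfig, generate_cohort

logging.getLogger("cansplice").setLevel(logging.ERROR)


def null_config(seed: int, **overrides) -> SyntheticConfig:
    """A cohort with nothing planted (type-I-error calibration conditions)."""
    kwargs = dict(
        seed=seed, n_planted_shared=0, n_planted_specific=0,
        n_planted_regulators=0, survival_coupled_events=0, n_subtype_events=0,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 3 cancers, 40/40, 150 planted shared."""
    return generate_cohort(SyntheticConfig(seed=20240901))


@pytest.fixture(scope="session")
def default_screen(default_bundle):
    b = default_bundle
    return {c: screen_events(b.psi[c], b.meta) for c in sorted(b.psi)}


@pytest.fixture(scope="session")
def small_bundle():
    """A light single-cancer cohort for unit-level checks."""
    cfg = SyntheticConfig(
        seed=7, n_cancers=1, n_tumor=30, n_normal=30,
        n_events_per_mode={"SE": 200, "RI": 40, "A3SS": 30, "A5SS": 30},
        n_planted_shared=30, n_planted_specific=10,
        n_genes=120, n_planted_regulators=2, regulator_subset_size=25,
        survival_coupled_events=1, n_subtype_events=10,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
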