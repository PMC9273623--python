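"""Shared fixtures: small, fast phantom cohorts reused across test modules."""

import numpy as np
import pytest

import ssm_pattern as sp


def small_config(**overrides):
    """A 16x20x16 phantom with two blobs; fast enough for per-test simulation."""
    defaults = dict(
        grid_shape=(16, 20, 16),
        mask_semiaxes=(7.0, 9.0, 7.0),
        blobs=(
            sp.Blob(center=(4.5, 13.0, 9.0), radius=2.0, sign=-1, amplitude=1.0),
            sp.Blob(center=(11.0, 13.0, 9.0), radius=2.0, sign=-1, amplitude=1.0),
            sp.Blob(center=(8.0, 4.5, 5.5), radius=2.2, sign=+1, amplitude=1.0),
        ),
        n_per_group=8,
        seed=7,
    )
    defaults.update(overrides)
    return sp.PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    images, manifest, truth = sp.simulate_cohort(cfg)
    return cfg, images, manifest, truth


@pytest.fixture(scope="session")
def small_derivation(small_cohort):
    _, images, manifest, _ = small_cohort
    return sp.derive_pattern(
        images,
        manifest["group"].tolist(),
        subject_ids=manifest["subject_id"].tolist(),
        patient_label="AD",
        control_label="NC",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
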