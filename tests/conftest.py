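import logging

import numpy as np
import pytest

import fernpipe as fp

logging.getLogger("fernpipe").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def sphere():
    return fp.default_sphere()


@pytest.fixture(scope="session")
def montage(sphere):
    return fp.default_montage(sphere)


@pytest.fixture(scope="session")
def source_space(sphere):
    return fp.build_source_space(sphere)


@pytest.fixture(scope="session")
def leadfield(montage, source_space, sphere):
    return fp.build_spherical_leadfield(montage, source_space, sphere)


@pytest.fixture(scope="session")
def small_igt_config():
    """Scaled-down gambling task used for chain tests (conditions unchanged)."""
    return fp.IGTConfig(
        n_trials_per_version=20, block_len=10, n_versions=2, iti_range=(0.9, 1.2)
    )


@pytest.fixture(scope="session")
def noiseless_control_epochs(small_igt_config, montage, sphere, source_space):
    """One noiseless control subject run through the full preprocessing chain."""
    session = fp.simulate_igt_session(small_igt_config, seed=11)
    raw = fp.synthesize_eeg(
        session,
        fp.ERPTemplate.for_profile("control"),
        montage,
        fp.NoiseParams(rms_uv=0.0, blink_rate_hz=0.0),
        seed=11,
        sphere=sphere,
        source_space=source_space,
    )
    return fp.preprocess(raw)


@pytest.fixture()
def toy_montage():
    """Minimal 3-channel montage: the scoring electrode plus both mastoids."""
    r = 0.092
    pos = np.array([[0.0, 0.05, 0.077], [-0.085, -0.028, -0.017], [0.085, -0.028, -0.017]])
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True) * r
    return fp.Montage(names=("Fz", "M1", "M2"), positions=pos)


def igt_condition_labels(epochs, which="hf"):
    """Loss/win label pools for the disadvantageous or high-loss-frequency decks."""
    decks = {"dd": ("v1-DD", "v2-DD"), "hf": ("v1-DD", "v2-AD")}[which]
    loss = [f"igt/{d}/loss" for d in decks]
    win = [f"igt/{d}/win" for d in decks]
    return loss, win
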