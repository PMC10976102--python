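import numpy as np
import pytest

from fcgru.evaluation import TrainConfig, prepare_features
from fcgru.network import HyperParams
from fcgru.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def separable_spec() -> SyntheticSpec:
    """Strongly separable study conditions: full coupling + 2x beta gain."""
    return SyntheticSpec(
        n_subjects=5,
        n_trials_per_subject=25,
        trial_duration=8.0,
        coupling_strength=1.0,
        band_power_offsets={"beta": 2.0},
        noise_sd=0.1,
        seed=42,
    )


@pytest.fixture(scope="session")
def separable_features(separable_spec):
    """Fused PLV+band tensors for the separable dataset (200 samples/subject)."""
    recs = generate_dataset(separable_spec)
    return prepare_features(recs, "arousal", separable_spec.threshold)


@pytest.fixture(scope="session")
def separable_band_features(separable_spec):
    """Band-only tensors (no connectivity columns) for CNN-only variants."""
    recs = generate_dataset(separable_spec)
    return prepare_features(
        recs, "arousal", separable_spec.threshold, use_plv=False
    )


@pytest.fixture(scope="session")
def small_hyper() -> HyperParams:
    return HyperParams.small()


@pytest.fixture(scope="session")
def fast_train_cfg() -> TrainConfig:
    """Desk-scale optimizer settings: 20 epochs, batch 32."""
    return TrainConfig(epochs=20, batch_size=32, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
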