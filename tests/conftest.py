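import numpy as np
import pytest

from dadpc.synthetic import SyntheticRecipe, generate
from dadpc.trainer import TrainConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_pair():
    """The default two-domain adaptation problem (recipe seed 7)."""
    from dadpc.synthetic import default_domain_pair

    return default_domain_pair(seed=7)


@pytest.fixture(scope="session")
def light_config():
    """Small, fast training configuration for structural tests."""
    return TrainConfig(seed=0, max_epochs=30, warmup_epochs=10, hidden_dims=(16, 8, 16))


@pytest.fixture(scope="session")
def easy_manifest():
    """15-subject, 3-session dataset with perfectly separable classes and
    no domain shift, for protocol-structure tests."""
    return generate(
        SyntheticRecipe(
            n_subjects=15,
            n_sessions=3,
            n_per_class=8,
            d=8,
            class_sep=14.0,
            subject_rotation_deg=0.0,
            subject_translation=0.0,
            session_rotation_deg=0.0,
            session_translation=0.0,
            outlier_fraction=0.0,
            seed=5,
        )
    )
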