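import numpy as np
import pytest

from ecgbmi.nn_models import ModelConfig
from ecgbmi.synthetic_cohort import SubjectPhenotype, synthesize_ecg


def make_phenotype(latent: float = 0.0, bmi: float = 26.0, **kw) -> SubjectPhenotype:
    defaults = dict(
        subject_id="T00000",
        sex="male",
        age=60.0,
        bmi=bmi,
        vat=5.0,
        htn=0,
        chd=0,
        dm=0,
        dyslip=0,
        latent_adiposity=latent,
    )
    defaults.update(kw)
    return SubjectPhenotype(**defaults)


@pytest.fixture
def clean_record():
    """Noise-free 500 Hz record for a z = 0 subject (seed 3: HR near 60)."""
    return synthesize_ecg(make_phenotype(), fs=500.0, duration=10.0, seed=3, noise_sd=0.0)


def tiny_config(task="binary", **kw) -> ModelConfig:
    """A deliberately small network for protocol and contract tests."""
    defaults = dict(
        architecture="model1",
        task=task,
        input_form="averaged_beat",
        batch_size=16,
        n_epochs=1,
        learning_rate=0.01,
        seed=0,
        conv_filters=(4,),
        gru_hidden=8,
        attention_dim=4,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def random_features(n: int, seed: int = 0, input_form: str = "averaged_beat"):
    """Random (ids, x, bp) with no label signal, for plumbing tests."""
    rng = np.random.default_rng(seed)
    nf = 10 if input_form == "averaged_beat" else 50
    x = rng.random((n, 100, nf, 12)).astype(np.float32)
    bp = rng.random((n, 36)).astype(np.float32)
    ids = np.array([f"R{i:04d}" for i in range(n)])
    return ids, x, bp
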