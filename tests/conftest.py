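import numpy as np
import pytest
from hypothesis import settings

from screenprio.corpus import Collection, Reference
from screenprio.synth import SynthConfig, generate_collection

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_collection() -> Collection:
    """Hand-written six-reference corpus with known lemma content."""
    refs = [
        Reference("r1", "Diabetes in pregnancy", "Cohort study of diabetes outcomes"),
        Reference("r2", "Pregnancy outcomes", "Diabetes complicates pregnancy often"),
        Reference("r3", "Blood pressure control", "Systolic blood pressure in trials"),
        Reference("r4", "Hypertension trials", "Blood pressure lowering drugs"),
        Reference("r5", "Walking and cycling", "Physical activity for transport"),
        Reference("r6", "Cycling safety", "Transport policy and physical activity"),
    ]
    return Collection(refs, name="toy")


@pytest.fixture(scope="session")
def small_labelled():
    """A small learnable synthetic collection shared across tests."""
    config = SynthConfig(n_references=200, specificity=0.1, signal_strength=0.9, seed=11)
    return generate_collection(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
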