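import numpy as np
import pytest

from fpcrevise import synthetic
from fpcrevise.fingerprint import FingerprintDataset, ShiftFingerprint


@pytest.fixture(scope="session")
def class_templates():
    return synthetic.default_class_templates()


@pytest.fixture(scope="session")
def fingerprint_dataset(class_templates):
    """6-class synthetic dataset, 30 compounds/class, fixed seed."""
    return synthetic.gen_fingerprint_dataset(class_templates, 30, seed=42)


@pytest.fixture(scope="session")
def dp4_scenario():
    """Default-regime two-candidate scenario (correct vs 6 offset carbons)."""
    return synthetic.gen_dp4_scenario(synthetic.ScenarioConfig(seed=7))


@pytest.fixture()
def toy_fingerprints():
    """Three hand-written fingerprints, one with a missing C9 slot."""
    def fp(cid, cls, c9, h2=10.0):
        vals = [165.0, 104.0, 168.0, 105.0, 166.0, 104.0, 192.0, c9,
                10.1, h2, 12.6, 13.2]
        return ShiftFingerprint(cid, cls, tuple(vals))

    return FingerprintDataset(records=(
        fp("cpd-1", "A", 191.0),
        fp("cpd-2", "A", np.nan),
        fp("cpd-3", "B", 187.0),
    ))
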