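"""Shared fixtures: small synthetic records and reduced model settings."""
from __future__ import annotations

import numpy as np
import pytest

from dse_ecg import EcgRecord, SynthConfig, synth_dataset, synth_record

#: Reduced architecture used by training tests: same wiring as the full
#: network (residual trunk, detached SE, aux inputs) at desk scale.
REDUCED_MODEL = dict(input_len=1024, kernel=16, channels=(4, 8))


@pytest.fixture(scope="session")
def quiet_config() -> SynthConfig:
    """Noise-free short-record generator config for deterministic checks."""
    return SynthConfig(
        n_records=8,
        seed=11,
        duration_range=(8.0, 12.0),
        duration_lognorm=(np.log(10.0), 0.08),
        heart_rate_range=(60.0, 75.0),
    ).noise_free()


@pytest.fixture(scope="session")
def example_record(quiet_config) -> EcgRecord:
    return synth_record(
        "Normal", quiet_config, np.random.default_rng(5), record_id="R0001",
        duration=10.0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 27-record noisy dataset over all 9 classes with its manifest."""
    cfg = SynthConfig(
        n_records=27,
        seed=7,
        class_mix={c: 1 / 9 for c in
                   ("Normal", "AF", "I-AVB", "LBBB", "RBBB",
                    "PAC", "PVC", "STD", "STE")},
        duration_range=(6.0, 30.0),
        duration_lognorm=(np.log(12.0), 0.4),
    )
    return synth_dataset(cfg)
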