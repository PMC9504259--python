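import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from emgfusion.data_model import DatasetManifest, ManifestEntry, MultichannelEmgRecord
from emgfusion.synthetic_data import GeneratorConfig, generate_records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


def make_record(signal, subject="s01", motion="m01", trial=1, rate=200.0, side=None):
    return MultichannelEmgRecord(
        subject_id=subject, motion_id=motion, trial=trial,
        sampling_rate=rate, signal=np.asarray(signal, dtype=float), side=side,
    )


def label_manifest(n_subjects, n_motions, n_sides, n_trials):
    """A labels-only manifest (no signal data) for split-arithmetic tests."""
    sides = [None] if n_sides == 1 else ["left", "right"][:n_sides]
    entries = [
        ManifestEntry(
            subject_id=f"s{s:03d}", motion_id=f"m{m:02d}", trial=t,
            sampling_rate=200.0, side=side,
        )
        for s in range(n_subjects)
        for m in range(n_motions)
        for side in sides
        for t in range(1, n_trials + 1)
    ]
    return DatasetManifest(entries)


@pytest.fixture(scope="session")
def small_dataset():
    """In-memory synthetic dataset: 6 subjects x 2 motions x 4 trials, 2 channels."""
    cfg = GeneratorConfig(
        n_subjects=6, n_motions=2, n_trials=4, n_channels=2,
        n_samples=640, sampling_rate=200.0, seed=7,
    )
    return cfg, generate_records(cfg)
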