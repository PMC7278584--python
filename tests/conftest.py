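"""Shared fixtures: simulated cohorts are expensive, so they are built once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from oliveqc import simulate as sim
from oliveqc.heatmap import build_feature_matrix
from oliveqc.library import default_compound_library


@pytest.fixture(scope="session")
def library():
    return default_compound_library()


def _features_and_labels(design, library, grid):
    labels = []

    def stream():
        for hmap, label in sim.iter_dataset(design, library=library, grid=grid):
            labels.append(label)
            yield hmap

    features = build_feature_matrix(stream(), library)
    return features, labels


@pytest.fixture(scope="session")
def study(library):
    """Default full-grid study: 198 samples, strong class separation."""
    design = sim.StudyDesign(seed=1)
    return _features_and_labels(design, library, sim.GridSpec())


@pytest.fixture(scope="session")
def null_cohorts(library):
    """Two independent null-effect cohorts (train/evaluate), coarse grid."""
    out = []
    for seed in (701, 702):
        design = sim.StudyDesign(n_evoo=210, n_voo=175, n_loo=115,
                                 effect_scale=0.0, seed=seed)
        out.append(_features_and_labels(design, library, sim.COARSE_GRID))
    return out


@pytest.fixture(scope="session")
def sma_series(library):
    """SMA dilution series at 1% multiplicative noise."""
    return sim.generate_calibration_series(library, "SMA", noise_cv=0.01,
                                           seed=42)


@pytest.fixture(scope="session")
def smb_series(library):
    return sim.generate_calibration_series(library, "SMB", noise_cv=0.01,
                                           seed=43)


@pytest.fixture(scope="session")
def noiseless_sma(library):
    return sim.generate_calibration_series(library, "SMA", noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_smb(library):
    return sim.generate_calibration_series(library, "SMB", noise_cv=0.0)
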