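import numpy as np
import pytest

from thighacc.io_cli import PipelineConfig, build_window_table
from thighacc.synthetic_data import simulate_dataset

# Published cross-validation confusion matrices of the four algorithms
# (rows = predicted, columns = reference; class order Sedentary, Standing,
# LIPA, MVPA) together with the printed per-class sensitivity, specificity
# and balanced accuracy percentages.
PUBLISHED_MATRICES = {
    "svm": [
        [1463, 0, 12, 0],
        [0, 588, 48, 0],
        [1, 48, 448, 61],
        [0, 0, 272, 2951],
    ],
    "ima": [
        [1463, 0, 12, 0],
        [0, 588, 48, 0],
        [1, 48, 469, 66],
        [0, 0, 251, 2946],
    ],
    "tm": [
        [1454, 0, 12, 0],
        [0, 588, 48, 0],
        [10, 47, 398, 67],
        [0, 1, 322, 2945],
    ],
    "random_forest": [
        [1463, 0, 34, 0],
        [0, 585, 48, 0],
        [1, 47, 497, 82],
        [0, 4, 201, 2930],
    ],
}

# (sensitivity, specificity, balanced accuracy) as printed, per class
PUBLISHED_PERFORMANCE = {
    "svm": {
        "Sedentary": (99.9, 99.7, 99.8),
        "Standing": (92.5, 99.1, 95.8),
        "LIPA": (57.4, 97.8, 77.6),
        "MVPA": (98.0, 90.6, 94.3),
    },
    "ima": {
        "Sedentary": (99.9, 99.7, 99.8),
        "Standing": (92.5, 99.1, 95.8),
        "LIPA": (60.1, 97.8, 78.9),
        "MVPA": (97.8, 91.3, 94.5),
    },
    "tm": {
        "Sedentary": (99.3, 99.7, 99.5),
        "Standing": (92.5, 99.1, 95.8),
        "LIPA": (51.0, 97.6, 74.3),
        "MVPA": (97.8, 88.8, 93.3),
    },
    "random_forest": {
        "Sedentary": (99.9, 99.2, 99.6),
        "Standing": (92.0, 99.1, 95.5),
        "LIPA": (63.7, 97.5, 80.6),
        "MVPA": (97.3, 92.9, 95.1),
    },
}

REFERENCE_COLUMN_TOTALS = (1464, 636, 780, 3012)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-participant synthetic protocol dataset (reused across tests)."""
    return simulate_dataset(6, seed=42)


@pytest.fixture(scope="session")
def window_table(small_dataset):
    """Full per-window feature/metric/label table for the small dataset."""
    return build_window_table(small_dataset, PipelineConfig(seed=42))
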