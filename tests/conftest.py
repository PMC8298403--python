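"""Shared fixtures: small synthetic sessions and a cached cohort pipeline.

The full-cohort pipeline (12 participants, one session kind) is expensive,
so runs are cached per (seed, n_participants, noise_factor) for the whole
test session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from emgesture import (
    FeatureMatrix,
    SimConfig,
    TaskSegment,
    build_feature_matrix,
    dissimilarity,
    extract_task_segments,
    intra_subject_similarity,
    preprocess_signals,
    rms_patterns,
    simulate_session,
)
from emgesture.classify import run_classification
from emgesture.simulate import iter_cohort, low_noise_config

FS = 2000.0


@pytest.fixture(scope="session")
def small_session():
    """One participant's flexion session at default protocol settings."""
    cfg = SimConfig(n_participants=1, seed=7)
    return simulate_session(1, "flexion", cfg, seed=7)


@pytest.fixture(scope="session")
def small_session_filtered(small_session):
    return preprocess_signals(small_session.signals, small_session.sampling_rate_hz)


@pytest.fixture
def random_segment():
    """A 3 s, 8-channel segment of EMG-band-ish noise (no simulation)."""
    rng = np.random.default_rng(3)
    return TaskSegment(1, "F1", 1, FS, rng.standard_normal((8, 6000)))


def synthetic_feature_frame(
    n_participants: int = 12, rng_seed: int = 5, informative: bool = False
) -> FeatureMatrix:
    """A structurally complete feature matrix with random values.

    ``informative=True`` adds a class-dependent mean shift so classifiers
    can separate the movements.
    """
    import pandas as pd

    from emgesture.io import FEATURE_COLUMNS, LABEL_COLUMNS

    rng = np.random.default_rng(rng_seed)
    rows = []
    for pid in range(1, n_participants + 1):
        for code_num in range(1, 7):
            for rep in range(1, 6):
                for win in (1, 2, 3):
                    rows.append((pid, f"F{code_num}", rep, win))
    labels = pd.DataFrame(rows, columns=list(LABEL_COLUMNS))
    values = rng.standard_normal((len(labels), len(FEATURE_COLUMNS)))
    if informative:
        class_idx = labels["movement_code"].str[1:].astype(int).to_numpy()
        centers = rng.normal(0.0, 4.0, size=(7, len(FEATURE_COLUMNS)))
        values = values + centers[class_idx]
    df = pd.concat(
        [labels, pd.DataFrame(values, columns=list(FEATURE_COLUMNS))], axis=1
    )
    return FeatureMatrix(df)


_PIPELINE_CACHE: dict = {}


def flexion_pipeline(seed: int, n_participants: int = 12, noise_factor: float = 1.0):
    """Simulate -> preprocess -> features -> similarity -> DA classification."""
    key = (seed, n_participants, noise_factor)
    if key in _PIPELINE_CACHE:
        return _PIPELINE_CACHE[key]
    cfg = SimConfig(n_participants=n_participants, seed=seed)
    if noise_factor != 1.0:
        cfg = low_noise_config(cfg, factor=noise_factor)
    segments = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # stream sessions so only one raw recording is in memory at a time
        for s in iter_cohort(cfg, session_kinds=("flexion",)):
            filt = preprocess_signals(s.signals, s.sampling_rate_hz)
            segments.extend(extract_task_segments(s, filt))
        fm = build_feature_matrix(segments)
        patterns = rms_patterns(fm)
        reports = intra_subject_similarity(patterns)
        dms = dissimilarity(patterns)
        da = run_classification(fm, kinds=("DA",), tuning_seed=seed)["DA"]
    result = {
        "config": cfg,
        "fm": fm,
        "patterns": patterns,
        "similarity_reports": reports,
        "dissimilarities": dms,
        "da_report": da,
    }
    _PIPELINE_CACHE[key] = result
    return result


@pytest.fixture(scope="session")
def cohort_pipeline():
    """The default 12-participant flexion pipeline (seed 1)."""
    return flexion_pipeline(1)
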