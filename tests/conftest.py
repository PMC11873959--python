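"""Shared fixtures: small synthetic cohorts and session-scoped trained models.

Training the comparison network is the expensive step, so each task variant
is trained once per session at desk scale and shared by every test that
needs a fitted model.
"""

from __future__ import annotations

import numpy as np
import pytest

import longchange as lc


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 8 frames, 64x64, default nuisance levels."""
    cfg = lc.SyntheticConfig(n_subjects=10, n_timepoints=8, seed=3)
    records, truths = lc.generate_cohort_records(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def ordering_fit():
    """Ordering model trained on a 100-subject cohort (60/20/20 subjects)."""
    cfg = lc.SyntheticConfig(n_subjects=100, n_timepoints=12, seed=7)
    records, truths = lc.generate_cohort_records(cfg)
    model = lc.PairwiseChangeModel(records, task="ordering", seed=0,
                                   max_pairs_per_subject=16)
    results = model.fit(max_epochs=10, patience=3, batch_size=32)
    return model, results, truths


@pytest.fixture(scope="session")
def interval_fit():
    """Interval-regression model on a 60-subject, 10-frame cohort."""
    cfg = lc.SyntheticConfig(n_subjects=60, n_timepoints=10, seed=11)
    records, truths = lc.generate_cohort_records(cfg)
    model = lc.PairwiseChangeModel(records, task="interval", seed=2,
                                   max_pairs_per_subject=12)
    results = model.fit(max_epochs=12, patience=4, batch_size=32)
    return model, results, truths


@pytest.fixture(scope="session")
def score_fit():
    """Score model with metadata (t, sex*t) on a confounded cohort.

    The target-linked process grows the central disk at subject-specific
    rates while a disjoint corner square shrinks as a pure function of time;
    metadata hands the model the time interval, so only the disk region adds
    predictive signal beyond it.
    """
    cfg = lc.SyntheticConfig(n_subjects=40, n_timepoints=8, seed=19,
                             change_rate_mean=0.8, change_rate_sd=0.25,
                             confound_rate=0.5, emit_metadata=True)
    records, truths = lc.generate_cohort_records(cfg)
    model = lc.PairwiseChangeModel(records, task="score", seed=4,
                                   max_pairs_per_subject=12)
    results = model.fit(max_epochs=12, patience=4, batch_size=32)
    return model, results, truths


def occlusion_peak(score_fn, image, patch: int):
    """Independent localization oracle: occlusion sensitivity.

    Slides a mean-filled patch over ``image`` on a grid, measures |score
    change| for each occlusion, and returns the grid cell with the largest
    effect.  Brute force, model-agnostic.  Mean filling (rather than zeros)
    keeps the per-image intensity range intact so the occlusion perturbs the
    patch, not the global normalization.
    """
    base = score_fn(image)
    fill = float(image.mean())
    shape = image.shape
    best, best_cell = -1.0, None
    for i in range(0, shape[0], patch):
        for j in range(0, shape[1], patch):
            occ = image.copy()
            occ[i:i + patch, j:j + patch] = fill
            delta = abs(score_fn(occ) - base)
            if delta > best:
                best, best_cell = delta, (i // patch, j // patch)
    return best_cell


@pytest.fixture
def rng():
    return np.random.default_rng(0)
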