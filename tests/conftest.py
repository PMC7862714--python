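"""Shared fixtures.

The expensive end-to-end recovery experiment (10 synthetic animals,
full preprocess + fit pipeline) runs once per session; several tests
assert different properties of its output.
"""

from __future__ import annotations

import numpy as np
import pytest

import wormdyn as w
from wormdyn.fitting import FitConfig, fit_model
from wormdyn.preprocessing import LatentExtractor

N_RECOVERY_SEEDS = 10


@pytest.fixture(scope="session")
def worm5() -> w.ModelParams:
    """The reference animal-5 parameter set used throughout."""
    return w.REFERENCE_FITS[5]


@pytest.fixture(scope="session")
def small_dataset() -> w.SynthDataset:
    """A short synthetic dataset for cheap structural tests."""
    return w.make_dataset(w.SynthConfig(n_frames=800, seed=7))


@pytest.fixture(scope="session")
def default_dataset() -> w.SynthDataset:
    """One full-size dataset at default (study) conditions."""
    return w.make_dataset(w.SynthConfig(seed=11))


def run_full_pipeline(dataset: w.SynthDataset, fit_seed: int):
    """preprocess -> fit, exactly as a user would run it."""
    extractor = LatentExtractor(frame_interval=dataset.recording.frame_interval)
    extractor.fit(dataset.recording.traces.T, dataset.labels)
    series = extractor.latent_series_
    labels = dataset.labels[1:]
    result = fit_model(series, labels, FitConfig(seed=fit_seed))
    return series, labels, result


@pytest.fixture(scope="session")
def recovery_experiment():
    """Fitted vs true parameters over 10 independent synthetic animals."""
    rows = []
    for i in range(N_RECOVERY_SEEDS):
        ds = w.make_dataset(w.SynthConfig(seed=1000 + i))
        series, labels, result = run_full_pipeline(ds, fit_seed=500 + i)
        rows.append({
            "true": ds.true_params,
            "fitted": result.params,
            "objective": result.objective,
            "series": series,
            "labels": labels,
        })
    return rows


def median_abs_error(rows, name: str) -> float:
    errs = [abs(getattr(r["fitted"], name) - getattr(r["true"], name)) for r in rows]
    return float(np.median(errs))
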