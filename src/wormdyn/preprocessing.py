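"""From raw calcium traces to the oriented two-mode latent trajectory.

The pipeline mirrors the standard whole-brain-imaging reduction: take time
derivatives of the normalized dF/F traces, mean-center each neuron's
derivative series, run PCA, subtract a long-timescale moving average from
each principal-component score (slow photobleaching drift), then orient
and rescale the dominant mode so that the forward-state cluster sits at
+1 and the sustained-reversal cluster at -1 -- the fixed points of the
bistable model the latents are fit to.

The sklearn-style :class:`LatentExtractor` wraps the whole chain; the
module functions expose the individual stages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .control import STABLE_FORWARD, STABLE_REVERSAL, validate_labels

__all__ = [
    "DegeneratePCAError",
    "CannotOrientError",
    "InvalidWindowError",
    "NeuralRecording",
    "LatentSeries",
    "differentiate_and_pca",
    "drift_correct",
    "orient_and_scale",
    "LatentExtractor",
]


class DegeneratePCAError(ValueError):
    """Recording carries no variance to decompose."""


class CannotOrientError(ValueError):
    """Labels lack a forward ({1,2}) or reversal ({7}) frame."""


class InvalidWindowError(ValueError):
    """Moving-average window outside [1, len(series))."""


@dataclass
class NeuralRecording:
    """neurons x time matrix of dF/F traces with a uniform frame interval."""

    traces: np.ndarray
    frame_interval: float
    neuron_ids: list[str] | None = None

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (neurons x time)")
        if not np.isfinite(self.traces).all():
            raise ValueError("traces contain missing or non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.neuron_ids is None:
            self.neuron_ids = [f"n{i:03d}" for i in range(self.traces.shape[0])]
        elif len(self.neuron_ids) != self.traces.shape[0]:
            raise ValueError("neuron_ids length must match the neuron axis")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class LatentSeries:
    """Scores of the first two PCA modes, v1(t) and v2(t).

    variance_fractions are the per-mode explained-variance ratios (sorted
    descending).  scale_factor, orientation_sign and center_offset record
    the affine map applied by :func:`orient_and_scale` (identity until it
    runs).  frame_interval is the recording's frame spacing in seconds and
    is the integration weight of the fitting error functional.
    """

    v1: np.ndarray
    v2: np.ndarray
    variance_fractions: np.ndarray
    frame_interval: float = 1.0
    scale_factor: float = 1.0
    orientation_sign: int = 1
    center_offset: float = 0.0

    def __post_init__(self):
        self.v1 = np.asarray(self.v1, dtype=float)
        self.v2 = np.asarray(self.v2, dtype=float)
        if len(self.v1) != len(self.v2):
            raise ValueError("v1 and v2 must share one length")
        vf = np.asarray(self.variance_fractions, dtype=float)
        if vf.size and (np.any(vf < -1e-12) or vf.sum() > 1 + 1e-9 or np.any(np.diff(vf) > 1e-12)):
            raise ValueError("variance_fractions must be in [0,1], descending, summing to <= 1")
        self.variance_fractions = vf

    def __len__(self) -> int:
        return len(self.v1)


def differentiate_and_pca(recording: NeuralRecording, n_modes: int = 2) -> LatentSeries:
    """First-difference each trace, mean-center, and run PCA over time.

    The derivative loses one frame, so the scores have n_frames - 1
    samples; align labels by dropping their first frame.
    """
    if recording.n_frames < 2:
        raise ValueError("need at least 2 timepoints")
    if n_modes < 2:
        raise ValueError("n_modes must be >= 2")
    deriv = np.diff(recording.traces, axis=1) / recording.frame_interval
    deriv = deriv - deriv.mean(axis=1, keepdims=True)
    if not np.any(np.abs(deriv) > 1e-14):
        raise DegeneratePCAError("recording is constant; derivative carries no variance")
    n_modes = min(n_modes, recording.n_neurons, deriv.shape[1])
    pca = PCA(n_components=n_modes)
    scores = pca.fit_transform(deriv.T)
    return LatentSeries(
        v1=scores[:, 0],
        v2=scores[:, 1],
        variance_fractions=pca.explained_variance_ratio_,
        frame_interval=recording.frame_interval,
    )


def drift_correct(series, window: int):
    """Subtract a centered moving average of width ``window``.

    Edges use shrunken (partial) windows.  A window spanning most of the
    recording removes slow monotone drift such as photobleaching while
    minimally distorting behavior-timescale structure.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if not 1 <= window < n:
        raise InvalidWindowError(f"window must be in [1, {n}), got {window}")
    ma = (
        pd.DataFrame(series)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    out = series - ma.reshape(series.shape)
    return out


def orient_and_scale(series: LatentSeries, labels) -> LatentSeries:
    """Pin the stable behavioral clusters of v1 to the model's wells +/-1.

    Flips v1 so the forward-state mean is the larger, removes the midpoint
    of the forward/reversal cluster means (PCA scores are mean-centered,
    so the clusters are generically offset from +/-1), and rescales both
    modes so the cluster means land at exactly +1 (forward) and -1
    (reversal).  v2's sign is chosen so that corr(diff(v1), v2) >= 0,
    matching the model's x' = y.  Idempotent.
    """
    labels = validate_labels(labels)
    if len(labels) != len(series):
        raise ValueError("labels must align with the latent series")
    fwd = np.isin(labels, STABLE_FORWARD)
    rev = np.isin(labels, STABLE_REVERSAL)
    if not (fwd.any() and rev.any()):
        raise CannotOrientError("need at least one forward (1/2) and one reversal (7) frame")

    v1 = series.v1.copy()
    v2 = series.v2.copy()
    mf = v1[fwd].mean()
    mr = v1[rev].mean()
    sign = 1 if mf >= mr else -1
    v1 *= sign
    mf, mr = sign * mf, sign * mr
    offset = (mf + mr) / 2.0
    half_gap = (mf - mr) / 2.0
    if half_gap <= 0:
        raise CannotOrientError("forward and reversal clusters are not separated in v1")
    scale = 1.0 / half_gap
    v1 = (v1 - offset) * scale
    v2 = v2 * scale
    if len(v1) > 1:
        dv1 = np.diff(v1)
        if dv1.std() > 0 and v2[:-1].std() > 0 and np.corrcoef(dv1, v2[:-1])[0, 1] < 0:
            v2 = -v2
    return replace(
        series,
        v1=v1,
        v2=v2,
        scale_factor=series.scale_factor * scale,
        orientation_sign=series.orientation_sign * sign,
        center_offset=series.center_offset + offset,
    )


class LatentExtractor(BaseEstimator, TransformerMixin):
    """Transformer: frames x neurons traces -> frames-1 x 2 latent scores.

    Parameters
    ----------
    n_modes : int
        PCA modes to keep (>= 2; modes beyond the first two only feed the
        variance report).
    drift_window : int or None
        Moving-average window (frames) for drift correction.  None uses
        the full recording (n-1), which removes slow monotone drift with
        the least distortion of state structure; 0 disables correction.
    frame_interval : float
        Seconds per frame.
    orient : bool
        Whether to orient/rescale with the behavioral labels passed as
        ``y`` to :meth:`fit`.

    Attributes (after fit)
    ----------------------
    pca_ : fitted sklearn PCA over the mean-centered derivative matrix
    derivative_matrix_ : neurons x (frames-1) mean-centered derivatives
    latent_series_ : the resulting LatentSeries
    variance_fractions_, scale_factor_, orientation_sign_ : convenience
    """

    def __init__(self, n_modes: int = 2, drift_window: int | None = None,
                 frame_interval: float = 1.0, orient: bool = True):
        self.n_modes = n_modes
        self.drift_window = drift_window
        self.frame_interval = frame_interval
        self.orient = orient

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (frames x neurons)")
        self.n_features_in_ = X.shape[1]
        rec = NeuralRecording(traces=X.T, frame_interval=self.frame_interval)
        deriv = np.diff(rec.traces, axis=1) / rec.frame_interval
        deriv = deriv - deriv.mean(axis=1, keepdims=True)
        if not np.any(np.abs(deriv) > 1e-14):
            raise DegeneratePCAError("recording is constant; derivative carries no variance")
        n_modes = min(self.n_modes, rec.n_neurons, deriv.shape[1])
        self.pca_ = PCA(n_components=n_modes).fit(deriv.T)
        self.derivative_matrix_ = deriv
        series = self._scores_to_series(self.pca_.transform(deriv.T))
        if self.orient:
            if y is None:
                raise CannotOrientError("orient=True requires behavioral labels as y")
            labels = validate_labels(y)
            if len(labels) == len(X):
                labels = labels[1:]  # derivative drops the first frame
            series = orient_and_scale(series, labels)
        self.latent_series_ = series
        self.variance_fractions_ = series.variance_fractions
        self.scale_factor_ = series.scale_factor
        self.orientation_sign_ = series.orientation_sign
        return self

    def _scores_to_series(self, scores: np.ndarray) -> LatentSeries:
        if self.drift_window != 0:
            w = self.drift_window if self.drift_window else scores.shape[0] - 1
            w = min(w, scores.shape[0] - 1)
            scores = drift_correct(scores, w)
        return LatentSeries(
            v1=scores[:, 0],
            v2=scores[:, 1],
            variance_fractions=self.pca_.explained_variance_ratio_,
            frame_interval=self.frame_interval,
        )

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "pca_")
        X = np.asarray(X, dtype=float)
        deriv = np.diff(X.T, axis=1) / self.frame_interval
        deriv = deriv - deriv.mean(axis=1, keepdims=True)
        series = self._scores_to_series(self.pca_.transform(deriv.T))
        v1 = (series.v1 * self.orientation_sign_ - self.latent_series_.center_offset) \
            * self.scale_factor_
        v2 = series.v2 * self.scale_factor_
        return np.column_stack([v1, v2])

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y)
        s = self.latent_series_
        return np.column_stack([s.v1, s.v2])
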