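"""Synthetic whole-brain-recording generator with known ground truth.

The generator runs the data-generating story backwards through the
preprocessing pipeline: a behavioral-state script drives the controlled
bistable SDE to produce latents (x, y); random per-neuron loadings embed
the latents as *derivative* signals plus observation noise; cumulative
integration produces dF/F-like traces; a multiplicative exponential
envelope emulates photobleaching.  By construction, differentiation +
PCA + drift correction recovers the latents up to sign and scale, so
preprocessing, fitting and analysis are testable end to end with no
downloads.

The default configuration emulates the reference recordings: 120 neurons
(the real datasets span 107-131), 3000 frames at ~0.35 s, Table-2-
magnitude parameters (animal 5), mean stable dwell of 150 frames, and
transition windows long enough for the fitted control strengths to
actually complete the basin crossing (~33 frames of sustained u34 are
needed deterministically; 80-frame turn windows cover the noisy tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .control import control_from_labels, validate_labels
from .dynamics import ModelParams, SimTrajectory, simulate
from .preprocessing import NeuralRecording

__all__ = [
    "REFERENCE_FITS",
    "SynthConfig",
    "SynthDataset",
    "generate_labels",
    "generate_latents_and_labels",
    "embed_recording",
    "make_dataset",
]

#: published fitted parameter sets for the five reference animals
REFERENCE_FITS = {
    1: ModelParams(beta=0.1108, gamma=-1.5027, sigma=0.0574, u34=0.4969, u56=-0.7531, dt=0.2902),
    2: ModelParams(beta=0.1124, gamma=-1.5281, sigma=0.0584, u34=0.5059, u56=-0.7159, dt=0.2953),
    3: ModelParams(beta=0.1107, gamma=-1.5321, sigma=0.0584, u34=0.5262, u56=-0.7549, dt=0.2951),
    4: ModelParams(beta=0.1135, gamma=-1.4830, sigma=0.0591, u34=0.5076, u56=-0.7292, dt=0.3008),
    5: ModelParams(beta=0.1087, gamma=-1.5115, sigma=0.0598, u34=0.5350, u56=-0.7731, dt=0.2929),
}


def _default_params() -> ModelParams:
    return REFERENCE_FITS[5]


@dataclass
class SynthConfig:
    """Ground-truth generator settings.

    bleach_timescale is the e-folding time (frames) of the multiplicative
    fluorescence decay; obs_noise_sd is per-neuron white noise on the
    derivative signal; loading_scale multiplies the unit-norm neuron
    loadings.  turn_window / reversal_window are the lengths (frames) of
    the 3/4 and 5/6 transition-label windows; mean_dwell and min_dwell
    shape the geometric stable-state dwell distribution.
    """

    n_neurons: int = 120
    n_frames: int = 3000
    frame_interval: float = 0.35
    true_params: ModelParams = dc_field(default_factory=_default_params)
    loading_scale: float = 1.0
    bleach_timescale: float = 12000.0
    obs_noise_sd: float = 0.05
    mean_dwell: float = 150.0
    min_dwell: int = 30
    turn_window: int = 80
    reversal_window: int = 16
    label_script: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 3:
            raise ValueError("n_neurons must be >= 3")
        if self.n_frames < 100:
            raise ValueError("n_frames must be >= 100")
        for name in ("frame_interval", "loading_scale", "bleach_timescale", "mean_dwell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be >= 0")
        if self.label_script is not None:
            self.label_script = validate_labels(self.label_script)
            if len(self.label_script) != self.n_frames:
                raise ValueError(
                    f"label_script length {len(self.label_script)} != n_frames {self.n_frames}"
                )


@dataclass
class SynthDataset:
    recording: NeuralRecording
    labels: np.ndarray
    true_latents: SimTrajectory
    true_params: ModelParams
    loadings: np.ndarray

    def __post_init__(self):
        if not (self.recording.n_frames == len(self.labels) == len(self.true_latents)):
            raise ValueError("recording, labels and latents must share the frame axis")


def generate_labels(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Two-state renewal script with transition windows.

    Stable dwells are min_dwell plus a geometric draw (mean mean_dwell);
    each reversal->forward switch carries a turn window labeled 3 or 4,
    each forward->reversal switch a window labeled 5 or 6.  The script
    starts in sustained reversal (state 7).
    """
    n = config.n_frames
    lab = np.empty(n, dtype=int)
    geo_mean = max(config.mean_dwell - config.min_dwell, 1.0)
    state = 7
    t = 0
    while t < n:
        dwell = config.min_dwell + int(rng.geometric(1.0 / geo_mean))
        end = min(t + dwell, n)
        lab[t:end] = 1 if state == 1 else 7
        t = end
        if t >= n:
            break
        window = config.turn_window if state == 7 else config.reversal_window
        end = min(t + window, n)
        lab[t:end] = rng.choice((3, 4)) if state == 7 else rng.choice((5, 6))
        t = end
        state = 1 if state == 7 else 7
    return lab


def generate_latents_and_labels(config: SynthConfig) -> tuple[SimTrajectory, np.ndarray]:
    """Label script (given or generated) -> control -> simulated latents."""
    ss = np.random.SeedSequence(config.seed)
    label_ss, noise_ss, _ = ss.spawn(3)
    if config.label_script is not None:
        labels = config.label_script
    else:
        labels = generate_labels(config, np.random.default_rng(label_ss))
    p = config.true_params
    u = control_from_labels(labels, p.u34, p.u56)
    x0 = -1.0 if labels[0] in (5, 6, 7) else 1.0
    sim_seed = int(noise_ss.generate_state(1)[0] % (2**31))
    traj = simulate(p, u, x0, 0.0, config.n_frames, seed=sim_seed)
    return traj, labels


def embed_recording(latents: SimTrajectory, config: SynthConfig) -> NeuralRecording:
    """Latents -> derivative signals -> integrated, bleached dF/F traces.

    Each neuron's derivative is loadings @ [x, y] plus white noise;
    cumulative integration (times the frame interval) gives the trace,
    and a multiplicative exp(-t / bleach_timescale) envelope emulates
    photobleaching.
    """
    if not (np.isfinite(latents.x).all() and np.isfinite(latents.y).all()):
        raise ValueError("latents must be finite")
    ss = np.random.SeedSequence(config.seed)
    _, _, embed_ss = ss.spawn(3)
    rng = np.random.default_rng(embed_ss)
    n = len(latents)
    loadings = rng.standard_normal((config.n_neurons, 2))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    loadings *= config.loading_scale
    deriv = loadings @ np.vstack([latents.x, latents.y])
    deriv += config.obs_noise_sd * rng.standard_normal((config.n_neurons, n))
    traces = np.cumsum(deriv, axis=1) * config.frame_interval
    traces *= np.exp(-np.arange(n) / config.bleach_timescale)
    return NeuralRecording(traces=traces, frame_interval=config.frame_interval)


def _loadings_of(config: SynthConfig) -> np.ndarray:
    ss = np.random.SeedSequence(config.seed)
    _, _, embed_ss = ss.spawn(3)
    rng = np.random.default_rng(embed_ss)
    loadings = rng.standard_normal((config.n_neurons, 2))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    return loadings * config.loading_scale


def make_dataset(config: SynthConfig | None = None) -> SynthDataset:
    """Full synthetic dataset with ground truth packaged alongside."""
    config = config or SynthConfig()
    latents, labels = generate_latents_and_labels(config)
    recording = embed_recording(latents, config)
    return SynthDataset(
        recording=recording,
        labels=labels,
        true_latents=latents,
        true_params=config.true_params,
        loadings=_loadings_of(config),
    )
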