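"""Feed-forward control signals u(t).

Two constructions are supported:

* label-derived signals for model fitting: u(t) = u34 during the turn
  states 3 and 4 (reverse-to-forward transitions), u(t) = u56 during the
  rev1/rev2 states 5 and 6 (forward-to-reverse transitions), and u(t) = 0
  during the stable states 1, 2 and 7;
* random pulse trains for the occupancy/sweep experiments: pulse onsets
  with exponential inter-arrival times (dead time equal to the pulse
  duration), each pulse a constant level for a fixed number of frames.

Control always enters the dynamics through the y-equation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "InvalidLabelError",
    "PulseConfig",
    "control_from_labels",
    "pulse_onsets",
    "random_pulse_control",
]

VALID_STATES = frozenset(range(1, 8))
TURN_STATES = (3, 4)       # dorsal / ventral turn: reversal -> forward
REVERSAL_STATES = (5, 6)   # rev1 / rev2: forward -> reversal
STABLE_FORWARD = (1, 2)    # forward, forward-slow
STABLE_REVERSAL = (7,)     # sustained reversal


class InvalidLabelError(ValueError):
    """A behavioral label outside {1..7}."""


def validate_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, list(VALID_STATES)).all():
        bad = np.unique(labels[~np.isin(labels, list(VALID_STATES))])
        raise InvalidLabelError(f"labels must be integers in 1..7; found {bad.tolist()}")
    return labels.astype(int)


def control_from_labels(labels, u34: float, u56: float) -> np.ndarray:
    """Piecewise-constant u(t) from a behavioral-state track.

    u = u34 on states 3/4, u56 on states 5/6, zero on the uncontrolled
    stable states 1, 2 and 7.
    """
    labels = validate_labels(labels)
    u = np.zeros(len(labels))
    u[np.isin(labels, TURN_STATES)] = u34
    u[np.isin(labels, REVERSAL_STATES)] = u56
    return u


@dataclass(frozen=True)
class PulseConfig:
    """Random pulse-train parameters.

    rate         : expected pulse onsets per frame (exponential gaps)
    duration     : frames per pulse (>= 1)
    amp_forward  : pulse level pushing toward the forward well x = +1
    amp_reverse  : pulse level pushing toward the reversal well x = -1

    Defaults give sparse pulses (about one per 100 frames, occupying
    ~13% of frames) with amplitude on the order of the fitted |u56| and
    enough impulse (amp * duration * dt ~ 3) to complete most basin
    switches.
    """

    rate: float = 0.01
    duration: int = 15
    amp_forward: float = 0.7
    amp_reverse: float = -0.7

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.rate * self.duration >= 1:
            raise ValueError("rate * duration must be < 1 (pulses must be a minority of frames)")


def pulse_onsets(config: PulseConfig, n_steps: int, rng: np.random.Generator) -> list[int]:
    """Onset frames: exponential inter-arrival (mean 1/rate) plus dead time.

    Each pulse occupies ``duration`` frames after its onset; the next gap
    is drawn after the pulse ends, so pulses never overlap.
    """
    onsets: list[int] = []
    t = 0
    while True:
        t += int(np.ceil(rng.exponential(1.0 / config.rate)))
        if t >= n_steps:
            return onsets
        onsets.append(t)
        t += config.duration


def random_pulse_control(
    config: PulseConfig,
    n_steps: int,
    current_state_fn: Callable[[int], str] | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Random pulse train of length n_steps, reproducible under a seed.

    If ``current_state_fn(frame) -> "forward" | "reversal"`` is given, each
    pulse pushes away from the basin occupied at its onset (basin-aware).
    Otherwise pulse directions simply alternate, starting with a push
    toward the reversal well.  For basin-aware control inside a running
    simulation use :func:`wormdyn.analysis.simulate_with_pulses`, which
    resolves the occupied basin on the fly.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be > 0")
    rng = np.random.default_rng(seed)
    u = np.zeros(n_steps)
    toward_reverse = True
    for onset in pulse_onsets(config, n_steps, rng):
        if current_state_fn is not None:
            state = current_state_fn(onset)
            level = config.amp_reverse if state == "forward" else config.amp_forward
        else:
            level = config.amp_reverse if toward_reverse else config.amp_forward
            toward_reverse = not toward_reverse
        u[onset : onset + config.duration] = level
    return u
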