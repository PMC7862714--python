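"""Polynomial vector fields, fixed-point analysis, and the controlled SDE simulator.

The model is a planar second-order system

    x' = y
    y' = f(x) + gamma * y + u(t)

with ``f`` a real polynomial whose roots are the fixed points of the
uncontrolled dynamics (all fixed points lie on the x-axis at ``(r, 0)``).
The working instance is the bistable cubic

    f(x, beta) = -(x + 1)(x - beta)(x - 1)

with stable wells at x = +1 (forward crawling) and x = -1 (sustained
reversal) and a saddle at x = beta whose location sets the relative
stability of the two behaviors.  Stochasticity enters both state equations
as independent Brownian increments of amplitude ``sigma``; trajectories are
integrated with an explicit Euler-Maruyama step, one step per recorded
frame, of size ``dt``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "InvalidFieldError",
    "DivergenceError",
    "PolynomialField",
    "ModelParams",
    "FixedPoint",
    "SimTrajectory",
    "cubic_field",
    "eval_field",
    "find_fixed_points",
    "lyapunov_energy",
    "simulate",
]

#: roots closer than this to the real axis are treated as real; repeated
#: roots closer than this collapse to one "degenerate" fixed point
REAL_TOL = 1e-9

#: state magnitude beyond which an Euler trajectory is declared divergent
#: (legitimate trajectories live in |x|, |y| of order 1)
DIVERGENCE_BOUND = 1e4


class InvalidFieldError(ValueError):
    """Root multiset is not closed under complex conjugation."""


class DivergenceError(RuntimeError):
    """Simulated state left the admissible region; carries the step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"trajectory diverged at step {step}")


def _conjugate_closed(roots: Sequence[complex], tol: float = REAL_TOL) -> bool:
    pending = [complex(r) for r in roots if abs(complex(r).imag) > tol]
    while pending:
        r = pending.pop()
        for i, s in enumerate(pending):
            if abs(s - r.conjugate()) <= tol * max(1.0, abs(r)):
                pending.pop(i)
                break
        else:
            return False
    return True


@dataclass(frozen=True)
class PolynomialField:
    """Real polynomial a * prod(x - r_i) given by leading coefficient and roots.

    Roots must be closed under complex conjugation so the field is real on
    the real line.
    """

    leading_coefficient: float
    roots: tuple

    def __post_init__(self):
        object.__setattr__(self, "roots", tuple(complex(r) for r in self.roots))
        if len(self.roots) < 1:
            raise InvalidFieldError("field needs at least one root")
        if not _conjugate_closed(self.roots):
            raise InvalidFieldError(
                "roots are not closed under complex conjugation; "
                "the field would not be real-valued on the real line"
            )

    @property
    def coefficients(self) -> np.ndarray:
        """Ascending real coefficients of the polynomial."""
        c = self.leading_coefficient * npoly.polyfromroots(self.roots)
        return np.real_if_close(c, tol=1e6).real

    def __call__(self, x):
        return eval_field(self, x)

    def derivative(self, x):
        """f'(x) from the exact polynomial derivative."""
        return npoly.polyval(x, npoly.polyder(self.coefficients))

    def real_roots(self, tol: float = REAL_TOL) -> np.ndarray:
        rr = [r.real for r in self.roots if abs(r.imag) <= tol]
        return np.sort(np.asarray(rr))


def cubic_field(beta: float) -> PolynomialField:
    """The bistable cubic -(x+1)(x-beta)(x-1) with saddle location beta."""
    return PolynomialField(-1.0, (-1.0, float(beta), 1.0))


def eval_field(field: PolynomialField, x):
    """Evaluate a * prod(x - r_i) at real x; tiny imaginary residue is discarded."""
    x = np.asarray(x, dtype=float)
    val = np.full(x.shape, field.leading_coefficient, dtype=complex)
    for r in field.roots:
        val = val * (x - r)
    out = val.real
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FixedPoint:
    """A fixed point (x*, 0) with the linearization's eigenvalues.

    The Jacobian of (x' = y, y' = f(x) + gamma*y) at (x*, 0) is
    [[0, 1], [f'(x*), gamma]], so the eigenvalues solve
    lambda^2 - gamma*lambda - f'(x*) = 0.
    """

    location: float
    eigenvalues: tuple
    classification: str


def _classify(eigs: np.ndarray, tol: float = 1e-12) -> str:
    re = eigs.real
    im = eigs.imag
    if np.any(np.abs(eigs) <= tol):
        return "degenerate"
    if np.all(np.abs(re) <= tol) and np.all(np.abs(im) > tol):
        return "center"
    if re[0] * re[1] < 0:
        return "saddle"
    spiral = np.any(np.abs(im) > tol)
    if np.all(re < 0):
        return "stable-spiral" if spiral else "stable-node"
    return "unstable-spiral" if spiral else "unstable-node"


def find_fixed_points(field: PolynomialField, gamma: float) -> list[FixedPoint]:
    """One FixedPoint per distinct real root of the field.

    For the cubic with beta in (-1, 1) and gamma < 0 this returns the two
    sinks at x = +/-1 and the saddle at x = beta.  Repeated real roots are
    reported once with classification "degenerate".  Fields with no real
    roots return an empty list.
    """
    out: list[FixedPoint] = []
    reported: list[float] = []
    for r in field.real_roots():
        if any(abs(r - p) <= REAL_TOL for p in reported):
            # repeated root: keep a single entry, flag it degenerate
            out[-1] = replace(out[-1], classification="degenerate")
            continue
        reported.append(r)
        fp = float(field.derivative(r))
        eigs = np.roots([1.0, -gamma, -fp])
        multiple = sum(abs(r - q.real) <= REAL_TOL and abs(q.imag) <= REAL_TOL for q in field.roots) > 1
        cls = "degenerate" if multiple else _classify(eigs)
        out.append(FixedPoint(location=float(r), eigenvalues=tuple(eigs), classification=cls))
    return out


@dataclass(frozen=True)
class ModelParams:
    """The six fitted parameters P = [beta, gamma, sigma, u34, u56, dt].

    beta  : saddle location, in (-1, 1); sets relative well stability
    gamma : damping (stable wells require gamma < 0)
    sigma : Brownian noise amplitude (>= 0), applied to both equations
    u34   : control level during dorsal/ventral-turn states 3 and 4
    u56   : control level during rev1/rev2 states 5 and 6
    dt    : model time per recorded frame (> 0)
    """

    beta: float
    gamma: float
    sigma: float
    u34: float
    u56: float
    dt: float

    _ORDER = ("beta", "gamma", "sigma", "u34", "u56", "dt")

    def __post_init__(self):
        if not -1.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (-1, 1), got {self.beta}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    @property
    def field(self) -> PolynomialField:
        return cubic_field(self.beta)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER], dtype=float)

    @classmethod
    def from_array(cls, vec) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        return cls(**dict(zip(cls._ORDER, vec)))

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in self._ORDER}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        d = json.loads(text)
        return cls(**{k: float(d[k]) for k in cls._ORDER})


@dataclass
class SimTrajectory:
    """A simulated (x, y) path with the control that produced it.

    times are frame indices scaled by dt; all vectors share one length.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        n = len(self.x)
        if not (len(self.times) == len(self.y) == len(self.u) == n):
            raise ValueError("times, x, y, u must share one length")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "x": self.x, "y": self.y, "u": self.u})


def lyapunov_energy(field: PolynomialField, x, y):
    """V(x, y) = y^2/2 - integral_0^x f(s) ds.

    With u = 0 and gamma < 0 this is non-increasing along the continuous
    flow (dV/dt = gamma * y^2); the discrete Euler map respects it up to
    O(dt^2) per step.
    """
    F = npoly.polyint(field.coefficients)
    return np.asarray(y) ** 2 / 2.0 - npoly.polyval(np.asarray(x, dtype=float), F)


def simulate(
    params: ModelParams,
    control: np.ndarray | None,
    x0: float,
    y0: float,
    n_steps: int,
    seed: int | None = 0,
    field: PolynomialField | None = None,
) -> SimTrajectory:
    """Euler-Maruyama integration, one step per frame of size params.dt.

        x_{k+1} = x_k + y_k*dt + sigma*sqrt(dt)*xi1
        y_{k+1} = y_k + [f(x_k) + gamma*y_k + u_k]*dt + sigma*sqrt(dt)*xi2

    with xi1, xi2 independent standard normals.  Identical seed gives an
    identical trajectory.  ``control=None`` means u = 0; otherwise the
    control must cover at least n_steps frames.  A custom ``field``
    replaces the cubic induced by params.beta (used for the complex-root
    regime where the forward well is lost).

    Raises DivergenceError (with the step index) if the state leaves
    |x|,|y| < 1e4 or becomes non-finite.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if control is None:
        u = np.zeros(n_steps)
    else:
        u = np.asarray(control, dtype=float)
        if len(u) < n_steps:
            raise ValueError(f"control length {len(u)} < n_steps {n_steps}")
        u = u[:n_steps]

    dt = params.dt
    amp = params.sigma * np.sqrt(dt)
    xi = np.random.default_rng(seed).standard_normal((n_steps, 2)) * amp

    if field is None:
        beta = params.beta
        f_at = lambda v: -(v + 1.0) * (v - beta) * (v - 1.0)  # noqa: E731
    else:
        coeffs = field.coefficients
        f_at = lambda v: float(npoly.polyval(v, coeffs))  # noqa: E731

    x = np.empty(n_steps)
    y = np.empty(n_steps)
    x[0], y[0] = float(x0), float(y0)
    gamma = params.gamma
    for k in range(n_steps - 1):
        fx = f_at(x[k])
        x[k + 1] = x[k] + y[k] * dt + xi[k, 0]
        y[k + 1] = y[k] + (fx + gamma * y[k] + u[k]) * dt + xi[k, 1]
        if (
            not (np.isfinite(x[k + 1]) and np.isfinite(y[k + 1]))
            or abs(x[k + 1]) > DIVERGENCE_BOUND
            or abs(y[k + 1]) > DIVERGENCE_BOUND
        ):
            raise DivergenceError(k + 1)
    times = np.arange(n_steps) * dt
    return SimTrajectory(times=times, x=x, y=y, u=u, seed=seed)
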