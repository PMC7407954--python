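"""Phase-encoded qubit-neuron arithmetic.

A qubit neuron holds its state as a phase angle ``y``.  The unit's readout is
the probability of collapsing into the excited basis state, ``sin^2(y)``; the
complementary ground-state probability is ``cos^2(y)``, so the two always sum
to one.  A layer of such units computes, for unit ``j`` fed phase-encoded
inputs ``p~``:

    v_j = sum_i W_ij * e^{i p~_i} - e^{i theta_j}
    y_j = (pi/2) * S(eps_j) - Arg(v_j)
    a_j = sin^2(y_j)

where ``S`` is the logistic sigmoid, ``eps_j`` a reversal parameter that sets
the rotation offset and ``theta_j`` a phase threshold.  Real amplitudes in
[0, 1] are mapped onto quantum phases in [0, pi/2] before entering a layer.

Parameters ``eps`` and ``theta`` are stored as full per-connection matrices
(the learning rules update them connection-wise) and collapsed to the per-unit
scalars used above by a column statistic, the mean by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "DegeneratePreactivationError",
    "QuantumLayerParams",
    "LayerActivation",
    "phasor",
    "logsigmoid",
    "encode_input",
    "complex_phase",
    "layer_forward",
    "prob_readout",
]

#: below this modulus the argument of a pre-activation is numerically undefined
DEGENERATE_TOL = 1e-12

# y = (pi/2)*S(eps) - Arg(v) with S in (0,1) and Arg in (-pi, pi]
Y_LO = -np.pi
Y_HI = 1.5 * np.pi


class DegeneratePreactivationError(ValueError):
    """A pre-activation collapsed to (numerically) zero, so its phase is undefined.

    Signals a pathological parameter state; callers that own an RNG may
    re-randomize the offending unit's parameters and retry.
    """

    def __init__(self, units):
        self.units = tuple(int(u) for u in np.atleast_1d(units))
        super().__init__(
            f"pre-activation modulus below {DEGENERATE_TOL} for unit(s) {self.units}"
        )


def _require_finite(name: str, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return x


def phasor(theta):
    """Unit complex number ``e^{i theta} = cos(theta) + i sin(theta)``."""
    theta = _require_finite("theta", theta)
    return np.exp(1j * theta)


def logsigmoid(x):
    """Logistic sigmoid ``1 / (1 + e^{-x})``, strictly increasing, S(0) = 1/2."""
    x = _require_finite("x", x)
    return expit(x)


def encode_input(p) -> np.ndarray:
    """Map real amplitudes ``p`` in [0, 1] onto quantum phases ``(pi/2) * p``.

    The scaling plays the role of the Hadamard preparation step: an amplitude
    of 1 lands on the quarter turn pi/2 (certain excitation), 0 stays at phase
    0, and intermediate amplitudes interpolate linearly, so the encoded range
    [0, pi/2] is exactly the arc between the two basis states.
    """
    p = np.asarray(p, dtype=float)
    bad = np.flatnonzero(~((p >= 0.0) & (p <= 1.0)))
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"input amplitude out of [0, 1] at index {i}: {p.flat[i]!r}")
    return (np.pi / 2.0) * p


def complex_phase(v):
    """Principal argument of a complex pre-activation, in (-pi, pi].

    Raises :class:`DegeneratePreactivationError` when ``|v|`` is numerically
    zero, where the phase is undefined.
    """
    v = np.asarray(v, dtype=complex)
    small = np.abs(v) < DEGENERATE_TOL
    if np.any(small):
        raise DegeneratePreactivationError(np.flatnonzero(np.atleast_1d(small)))
    return np.angle(v)


@dataclass
class QuantumLayerParams:
    """Weights and quantum circuit parameters for one layer.

    ``W``, ``eps`` and ``theta`` all have shape ``(n_in, n_units)``.  The
    forward pass uses per-unit scalars obtained by collapsing each column
    (``collapse``: "mean" or "median"); the learning rules update the full
    matrices entry-wise.
    """

    W: np.ndarray
    eps: np.ndarray
    theta: np.ndarray
    collapse: str = "mean"

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.eps = np.atleast_2d(np.asarray(self.eps, dtype=float))
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if not (self.W.shape == self.eps.shape == self.theta.shape):
            raise ValueError(
                f"shape mismatch: W {self.W.shape}, eps {self.eps.shape}, "
                f"theta {self.theta.shape}"
            )
        for name in ("W", "eps", "theta"):
            _require_finite(name, getattr(self, name))
        if self.collapse not in ("mean", "median"):
            raise ValueError(f"unknown collapse rule {self.collapse!r}")

    @property
    def n_in(self) -> int:
        return self.W.shape[0]

    @property
    def n_units(self) -> int:
        return self.W.shape[1]

    def _collapse(self, m: np.ndarray) -> np.ndarray:
        if self.collapse == "median":
            return np.median(m, axis=0)
        return m.mean(axis=0)

    @property
    def unit_eps(self) -> np.ndarray:
        """Per-unit reversal parameter eps_j (column collapse of ``eps``)."""
        return self._collapse(self.eps)

    @property
    def unit_theta(self) -> np.ndarray:
        """Per-unit phase threshold theta_j (column collapse of ``theta``)."""
        return self._collapse(self.theta)

    def copy(self) -> "QuantumLayerParams":
        return QuantumLayerParams(
            self.W.copy(), self.eps.copy(), self.theta.copy(), self.collapse
        )

    @classmethod
    def random(cls, n_in: int, n_units: int, rng: np.random.Generator,
               collapse: str = "mean") -> "QuantumLayerParams":
        """Uniform(0, 1) initialization of all three parameter matrices."""
        return cls(
            rng.uniform(0.0, 1.0, (n_in, n_units)),
            rng.uniform(0.0, 1.0, (n_in, n_units)),
            rng.uniform(0.0, 1.0, (n_in, n_units)),
            collapse,
        )

    def rerandomize_units(self, units, rng: np.random.Generator) -> None:
        """Redraw the parameter columns of ``units`` from the init distribution."""
        for j in units:
            self.W[:, j] = rng.uniform(0.0, 1.0, self.n_in)
            self.eps[:, j] = rng.uniform(0.0, 1.0, self.n_in)
            self.theta[:, j] = rng.uniform(0.0, 1.0, self.n_in)


@dataclass
class LayerActivation:
    """Forward-pass record: complex pre-activations, phases, real readouts."""

    v: np.ndarray   # complex, (n_units,)
    y: np.ndarray   # phase angles, (n_units,)
    a: np.ndarray   # sin^2(y) readouts in [0, 1], (n_units,)


def layer_forward(params: QuantumLayerParams, input_angles,
                  eps_clamp: bool = False) -> LayerActivation:
    """One layer of qubit neurons applied to phase-encoded inputs.

    ``eps_clamp`` restricts the per-unit reversal parameter to [0, 1] before
    the sigmoid (off by default; the sigmoid bounds its effect either way).
    """
    input_angles = _require_finite("input_angles", input_angles).ravel()
    if input_angles.shape[0] != params.n_in:
        raise ValueError(
            f"expected {params.n_in} input angles, got {input_angles.shape[0]}"
        )
    eps_j = params.unit_eps
    if eps_clamp:
        eps_j = np.clip(eps_j, 0.0, 1.0)
    v = phasor(input_angles) @ params.W - phasor(params.unit_theta)
    y = (np.pi / 2.0) * logsigmoid(eps_j) - complex_phase(v)
    if np.any(y < Y_LO - 1e-9) or np.any(y > Y_HI + 1e-9):
        raise AssertionError(f"phase out of admissible range: {y}")
    return LayerActivation(v=v, y=y, a=prob_readout(y))


def prob_readout(y):
    """Excited-state probability ``sin^2(y)`` of a unit with phase ``y``."""
    y = _require_finite("y", y)
    return np.sin(y) ** 2
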