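"""Cortical module: adaptive single-layer feedforward qubit network.

Maps a cue to a scalar conditioned response (CR) in [0, 1] through Q hidden
qubits and one output qubit.  The hidden layer learns by the instar rule
(incoming parameters drift toward the cue, gated by activation, at a slow
relative rate); the output layer learns by the Widrow-Hoff (LMS/delta) rule
against the reinforcement target d (1 when the US is present, 0 when absent).

Two forms of the output-layer step are provided.  The default ``"gradient"``
form is the delta rule taken through the output qubit's actual readout: the
squared error (d - CR)^2 is differentiated through CR = sin^2(y) and
y = (pi/2) S(eps) - Arg(v), so weight changes rotate the pre-activation
phasor toward the phase that realizes the target, with the rotation step
normalized by |v| (scale-free) and floored to stay finite near cancellation.
The ``"printed"`` form is the plain scalar rule Delta = mu * a_i * e applied
uniformly to W, eps and theta; it moves every parameter in the same
direction and cannot hold the two opposite steady states a discrimination
requires, so it is kept only for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import InitConfig, LearningConfig
from .core import QuantumLayerParams, encode_input
from .hippocampus import _forward_with_recovery, _instar

__all__ = ["CorticalState", "PredictionRecord", "init_cortical", "cor_forward",
           "cor_instar_update", "widrow_hoff_update",
           "widrow_hoff_gradient_update", "error_statistic", "cor_train_trial"]

#: |v| floor in the gradient step: below this the phase rotation is capped
V_FLOOR = 0.05


@dataclass
class CorticalState:
    """Hidden layer (R x Q), single-output layer (Q x 1), last activations."""

    layer1: QuantumLayerParams
    layer2: QuantumLayerParams
    last_hidden: np.ndarray = field(default=None)        # a_c1 in [0,1]^Q
    last_cr: float = field(default=None)
    # cached output-unit geometry from the last forward pass (needed by the
    # gradient form of the Widrow-Hoff step)
    last_hidden_phase: np.ndarray = field(default=None)  # y_c1, radians
    last_v_out: complex = field(default=None)            # output pre-activation
    last_y_out: float = field(default=None)              # output phase

    def __post_init__(self):
        if self.layer1.n_units != self.layer2.n_in:
            raise ValueError(
                f"hidden-size mismatch: layer1 has {self.layer1.n_units} units, "
                f"layer2 expects {self.layer2.n_in}"
            )
        if self.layer2.n_units != 1:
            raise ValueError(
                f"cortical output layer must have exactly one unit, "
                f"got {self.layer2.n_units}"
            )

    @property
    def r(self) -> int:
        return self.layer1.n_in

    @property
    def q(self) -> int:
        return self.layer1.n_units

    def copy(self) -> "CorticalState":
        st = CorticalState(self.layer1.copy(), self.layer2.copy())
        st.last_hidden = None if self.last_hidden is None else self.last_hidden.copy()
        st.last_cr = self.last_cr
        st.last_hidden_phase = (None if self.last_hidden_phase is None
                                else self.last_hidden_phase.copy())
        st.last_v_out = self.last_v_out
        st.last_y_out = self.last_y_out
        return st


@dataclass
class PredictionRecord:
    """One supervised trial: CR, target d, error e and the running signed
    half-sum error statistic."""

    cr: float
    target: float
    error: float
    cumulative_error: float


def init_cortical(r: int, q: int, rng: np.random.Generator,
                  init: InitConfig | None = None,
                  collapse: str = "mean") -> CorticalState:
    """Random initialization for R inputs, Q hidden qubits, 1 output.

    The hidden layer draws U(0, 1); the output layer draws per
    :class:`InitConfig` so that the initial conditioned response starts near
    its naive (unreinforced) baseline.
    """
    if r < 1 or q < 1:
        raise ValueError(f"need r, q >= 1, got r={r}, q={q}")
    init = init or InitConfig()
    layer1 = QuantumLayerParams.random(r, q, rng, collapse)
    layer2 = QuantumLayerParams(
        rng.uniform(0.0, init.out_w_scale, (q, 1)),
        rng.uniform(init.out_eps_low, init.out_eps_high, (q, 1)),
        rng.uniform(0.0, 1.0, (q, 1)),
        collapse,
    )
    return CorticalState(layer1, layer2)


def cor_forward(state: CorticalState, p,
                learning: LearningConfig | None = None,
                rng: np.random.Generator | None = None) -> float:
    """Cue -> hidden representation -> scalar CR; activations cached on state."""
    learning = learning or LearningConfig()
    p = np.asarray(p, dtype=float).ravel()
    if p.shape[0] != state.r:
        raise ValueError(f"cue length {p.shape[0]} != R={state.r}")
    h = _forward_with_recovery(state.layer1, encode_input(p),
                               learning.eps_clamp, rng, "cortical layer1")
    o = _forward_with_recovery(state.layer2, h.y,
                               learning.eps_clamp, rng, "cortical layer2")
    state.last_hidden = h.a
    state.last_hidden_phase = h.y
    state.last_v_out = complex(o.v[0])
    state.last_y_out = float(o.y[0])
    state.last_cr = float(o.a[0])
    return state.last_cr


def cor_instar_update(state: CorticalState, p, a_c1,
                      cfg: LearningConfig) -> CorticalState:
    """Instar step on the cortical hidden layer (same rule as the
    hippocampal one, at the slow cortical rate ``mu * instar_scale``)."""
    p = np.asarray(p, dtype=float).ravel()
    a_c1 = np.asarray(a_c1, dtype=float).ravel()
    _instar(state.layer1, p, a_c1, cfg.mu * cfg.instar_scale)
    return state


def widrow_hoff_update(state: CorticalState, a_c1, error: float,
                       cfg: LearningConfig) -> CorticalState:
    """LMS step on the output layer: ``P_i <- P_i + mu * a_i^c1 * e`` for each
    of W, eps, theta (single output column)."""
    a_c1 = np.asarray(a_c1, dtype=float).ravel()
    delta = (cfg.mu * float(error)) * a_c1[:, np.newaxis]
    for m in (state.layer2.W, state.layer2.eps, state.layer2.theta):
        m += delta
    return state


def widrow_hoff_gradient_update(state: CorticalState, error: float,
                                cfg: LearningConfig,
                                rate_gate: float = 1.0) -> CorticalState:
    """Delta-rule step through the output qubit's readout geometry.

    Ascends CR toward the target by the chain rule through
    ``CR = sin^2(y)`` and ``y = (pi/2) S(eps_bar) - Arg(v)``:

    * eps:   dy/deps_i   = (pi/2) S'(eps_bar) / Q   (column-mean collapse)
    * theta: dy/dtheta_i = Re(e^{i theta_bar} conj(v)) / max(|v|, floor) / Q
    * W_j:   dy/dW_j     = -Im(conj(v) h_j) / max(|v|, floor)

    where ``h_j = e^{i y_j}`` are the hidden phasors.  The phase-rotation
    terms are normalized by |v| rather than |v|^2, making the angular step
    scale-free — without this, learned states with a large pre-activation
    modulus become nearly frozen and reversals stall.

    ``rate_gate`` scales the step (the hippocampal novelty gate in intact
    systems).  Requires a forward pass on the same trial.
    """
    if state.last_v_out is None:
        raise RuntimeError("gradient update requires a forward pass first")
    q = state.q
    v = state.last_v_out
    y = state.last_y_out
    h = np.exp(1j * state.last_hidden_phase)
    vmod = max(abs(v), V_FLOOR)
    g = np.sin(2.0 * y) * float(error)        # d(CR)/dy * error
    eps_bar = state.layer2.unit_eps[0]
    s = expit(eps_bar)
    d_eps = (np.pi / 2.0) * s * (1.0 - s) / q
    theta_bar = state.layer2.unit_theta[0]
    d_theta = np.real(np.exp(1j * theta_bar) * np.conj(v)) / vmod / q
    d_w = -np.imag(np.conj(v) * h) / vmod     # per hidden unit
    step = cfg.mu * rate_gate * g
    state.layer2.W += step * d_w[:, np.newaxis]
    state.layer2.eps += step * d_eps
    state.layer2.theta += step * d_theta
    return state


def error_statistic(errors) -> tuple[float, float]:
    """Return ``(literal, mean_abs)`` for a sequence of trial errors.

    ``literal`` is the signed half-sum ``0.5 * sum(e_j)`` — the statistic as
    conventionally printed, despite being signed; ``mean_abs`` is the mean
    absolute error, a better-behaved diagnostic (opposite-signed errors cancel
    in the half-sum but not here).
    """
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("error_statistic requires a nonempty error vector")
    return 0.5 * float(errors.sum()), float(np.mean(np.abs(errors)))


def cor_train_trial(state: CorticalState, p, us_present: bool,
                    cfg: LearningConfig,
                    rng: np.random.Generator | None = None,
                    cumulative_error: float = 0.0,
                    rate_gate: float = 1.0):
    """One supervised trial: forward pass, slow instar on layer 1,
    Widrow-Hoff on layer 2.  Returns ``(state, PredictionRecord)``.

    The error convention is e = d - CR under ``error_sign="descent"`` (the
    update reduces the error) and the raw e = CR - d under ``"literal"``
    (a negative control that ascends it).  No output-layer update happens
    when |e| is inside the deadzone — a CR already at its steady state
    leaves no trace.  ``rate_gate`` scales the output-layer step only.
    """
    p = np.asarray(p, dtype=float).ravel()
    cr = cor_forward(state, p, cfg, rng)
    d = 1.0 if us_present else 0.0
    e = (d - cr) if cfg.error_sign == "descent" else (cr - d)
    cor_instar_update(state, p, state.last_hidden, cfg)
    if abs(e) >= cfg.error_deadzone:
        if cfg.output_rule == "gradient":
            widrow_hoff_gradient_update(state, e, cfg, rate_gate)
        else:
            widrow_hoff_update(state, state.last_hidden, e * rate_gate, cfg)
    rec = PredictionRecord(cr=cr, target=d, error=e,
                           cumulative_error=cumulative_error + 0.5 * e)
    return state, rec
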