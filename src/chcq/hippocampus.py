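"""Hippocampal module: an autoencoder of qubit neurons trained by
quantum instar (input layer) and outstar (output layer) rules.

The autoencoder maps an R-dimensional cue through Q hidden qubits back to an
R-dimensional reconstruction.  Its hidden readout ``a_h1`` is the internal
representation that, in the intact system, is forwarded to the cortical
module.  Learning is unsupervised:

* instar, hidden layer:  ``P_ij <- P_ij + mu * a_j^h1 * (p_i - P_ij)`` for
  each of W, eps, theta — incoming parameters drift toward the cue, gated by
  the receiving unit's activation;
* outstar, output layer: ``P_ij <- P_ij + mu * (t_j - P_ij) * a_i^h1`` —
  outgoing parameters drift toward the drive ``t``, gated by the source
  activation.  The drive is the network's own reconstruction ``a_h2``
  ("literal" mode) or the cue ``p`` ("input_target" mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import LearningConfig
from .core import (DegeneratePreactivationError, QuantumLayerParams,
                   encode_input, layer_forward)

__all__ = ["HippocampalState", "init_hippocampal", "hip_forward",
           "instar_update", "outstar_update", "novelty", "hip_train_trial"]

log = logging.getLogger(__name__)

_MAX_RERANDOMIZE = 8


@dataclass
class HippocampalState:
    """Two-layer autoencoder parameters plus the last forward pass."""

    layer1: QuantumLayerParams   # R x Q
    layer2: QuantumLayerParams   # Q x R
    last_hidden: np.ndarray = field(default=None)   # a_h1, in [0,1]^Q
    last_recon: np.ndarray = field(default=None)    # a_h2, in [0,1]^R

    def __post_init__(self):
        if self.layer1.n_units != self.layer2.n_in:
            raise ValueError(
                f"hidden-size mismatch: layer1 has {self.layer1.n_units} units, "
                f"layer2 expects {self.layer2.n_in} inputs"
            )
        if self.layer1.n_in != self.layer2.n_units:
            raise ValueError(
                f"autoencoder must reconstruct its input: R={self.layer1.n_in} "
                f"but layer2 has {self.layer2.n_units} outputs"
            )

    @property
    def r(self) -> int:
        return self.layer1.n_in

    @property
    def q(self) -> int:
        return self.layer1.n_units

    def copy(self) -> "HippocampalState":
        st = HippocampalState(self.layer1.copy(), self.layer2.copy())
        st.last_hidden = None if self.last_hidden is None else self.last_hidden.copy()
        st.last_recon = None if self.last_recon is None else self.last_recon.copy()
        return st


def init_hippocampal(r: int, q: int, rng: np.random.Generator,
                     collapse: str = "mean") -> HippocampalState:
    """Random U(0,1) initialization of both layers for R inputs, Q hidden qubits."""
    if r < 1 or q < 1:
        raise ValueError(f"need r, q >= 1, got r={r}, q={q}")
    return HippocampalState(
        QuantumLayerParams.random(r, q, rng, collapse),
        QuantumLayerParams.random(q, r, rng, collapse),
    )


def _forward_with_recovery(params: QuantumLayerParams, angles, eps_clamp: bool,
                           rng: np.random.Generator | None, label: str):
    """Run a layer forward pass; on a degenerate (zero) pre-activation,
    re-randomize the offending units from the init distribution and retry."""
    for attempt in range(_MAX_RERANDOMIZE):
        try:
            return layer_forward(params, angles, eps_clamp=eps_clamp)
        except DegeneratePreactivationError as err:
            if rng is None:
                raise
            log.warning("degenerate pre-activation in %s unit(s) %s; "
                        "re-randomizing (attempt %d)", label, err.units, attempt + 1)
            params.rerandomize_units(err.units, rng)
    raise DegeneratePreactivationError(())


def hip_forward(state: HippocampalState, p,
                learning: LearningConfig | None = None,
                rng: np.random.Generator | None = None):
    """Encode the cue, compute hidden representation and reconstruction.

    Returns ``(a_h1, a_h2)``; both are also stored on the state.  The hidden
    qubits pass their phase angles ``y`` on to the output layer (the next
    layer consumes the hidden phasors ``e^{iy}`` directly), while the
    learning rules consume the real readout ``a = sin^2(y)``.
    """
    learning = learning or LearningConfig()
    p = np.asarray(p, dtype=float).ravel()
    if p.shape[0] != state.r:
        raise ValueError(f"cue length {p.shape[0]} != R={state.r}")
    h = _forward_with_recovery(state.layer1, encode_input(p),
                               learning.eps_clamp, rng, "hippocampal layer1")
    o = _forward_with_recovery(state.layer2, h.y,
                               learning.eps_clamp, rng, "hippocampal layer2")
    state.last_hidden = h.a
    state.last_recon = o.a
    return h.a, o.a


def _instar(params: QuantumLayerParams, p: np.ndarray, a: np.ndarray,
            mu: float) -> None:
    # P_ij += mu * a_j * (p_i - P_ij), applied to W, eps, theta alike
    gate = mu * a[np.newaxis, :]
    col = p[:, np.newaxis]
    for m in (params.W, params.eps, params.theta):
        m += gate * (col - m)


def instar_update(state: HippocampalState, p, a_h1,
                  cfg: LearningConfig, rate: float | None = None) -> HippocampalState:
    """Instar step on the hidden layer: pull incoming parameters toward the cue,
    gated by the hidden activation from the same trial's forward pass.

    ``rate`` overrides the plain learning rate ``cfg.mu`` (used by the trial
    loop to apply the hippocampal rate scale)."""
    p = np.asarray(p, dtype=float).ravel()
    a_h1 = np.asarray(a_h1, dtype=float).ravel()
    _instar(state.layer1, p, a_h1, cfg.mu if rate is None else rate)
    return state


def outstar_update(state: HippocampalState, a_h1, a_h2, p,
                   cfg: LearningConfig, rate: float | None = None) -> HippocampalState:
    """Outstar step on the output layer: pull outgoing parameters toward the
    drive, gated by the source (hidden) activation.

    The drive is ``a_h2`` in literal mode and the cue ``p`` in input_target
    mode (the classical outstar target, under which the reconstruction
    contracts toward the cue).
    """
    a_h1 = np.asarray(a_h1, dtype=float).ravel()
    drive = np.asarray(p if cfg.outstar_target_mode == "input_target" else a_h2,
                       dtype=float).ravel()
    gate = (cfg.mu if rate is None else rate) * a_h1[:, np.newaxis]
    row = drive[np.newaxis, :]
    for m in (state.layer2.W, state.layer2.eps, state.layer2.theta):
        m += gate * (row - m)
    return state


def novelty(state: HippocampalState, p) -> float:
    """Cue novelty in [0, ~1]: mean |p_i - W^h1_ij| over all instar weights.

    The instar rule contracts the hidden-layer weights toward cues the
    hippocampus has seen, so this distance measures how completely a cue has
    been encoded: ~0.5 for a never-seen cue against U(0,1) weights, -> 0
    with repeated exposure.  It is the familiarity signal the intact system
    uses to gate cortical plasticity.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.shape[0] != state.r:
        raise ValueError(f"cue length {p.shape[0]} != R={state.r}")
    return float(np.mean(np.abs(p[:, np.newaxis] - state.layer1.W)))


def hip_train_trial(state: HippocampalState, p, cfg: LearningConfig,
                    rng: np.random.Generator | None = None):
    """One unsupervised trial: forward pass, instar on layer 1, outstar on
    layer 2, both at the hippocampal rate ``mu * hippocampal_scale``.
    Returns ``(state, recon_error)`` with the mean absolute reconstruction
    error of the pre-update forward pass."""
    p = np.asarray(p, dtype=float).ravel()
    a_h1, a_h2 = hip_forward(state, p, cfg, rng)
    rate = cfg.mu * cfg.hippocampal_scale
    instar_update(state, p, a_h1, cfg, rate=rate)
    outstar_update(state, a_h1, a_h2, p, cfg, rate=rate)
    return state, float(np.mean(np.abs(a_h2 - p)))
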