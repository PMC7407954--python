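"""The coupled cortico-hippocampal model: intact and lesioned systems.

The intact system couples the two networks through an adaptive signal: after
each hippocampal learning step, the cortical hidden-layer parameters are
blended toward their hippocampal counterparts,

    cortical <- (1 - lambda_trial) * cortical + lambda_trial * hippocampal,

optionally perturbed by zero-mean normal noise (disrupted representations).
At build time the intact cortical hidden layer is likewise blended toward the
hippocampal one with strength ``lambda_init``.  The signal also carries a
familiarity measure: cortical output-layer plasticity is gated by the cue's
hippocampal novelty, so cues the hippocampus has already encoded support
less new cortical learning (the source of latent inhibition in this model).
Lesioning removes the whole link: the hippocampal state is retained but
never read again, so a lesioned run is a pure function of the cortical seed
and the cue sequence.

Per-trial order in the intact system is fixed: hippocampal unsupervised
trial, then the adaptive transfer, then the cortical supervised trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import CouplingConfig, InitConfig, LearningConfig
from .cortex import CorticalState, cor_train_trial, init_cortical
from .hippocampus import (HippocampalState, hip_train_trial, init_hippocampal,
                          novelty)

__all__ = ["CHCQModel", "build_model", "adaptive_transfer", "lesion",
           "model_trial"]

log = logging.getLogger(__name__)


@dataclass
class CHCQModel:
    """Assembled system: hippocampal + cortical networks, coupling, RNGs."""

    hippocampus: HippocampalState
    cortex: CorticalState
    coupling: CouplingConfig
    learning: LearningConfig
    lesioned: bool
    hip_rng: np.random.Generator
    cor_rng: np.random.Generator
    noise_rng: np.random.Generator
    seed: int | None = None
    trial_count: int = 0

    @property
    def r(self) -> int:
        return self.cortex.r

    @property
    def q(self) -> int:
        return self.cortex.q

    def copy(self) -> "CHCQModel":
        import copy as _copy
        return CHCQModel(
            hippocampus=self.hippocampus.copy(),
            cortex=self.cortex.copy(),
            coupling=self.coupling,
            learning=self.learning,
            lesioned=self.lesioned,
            hip_rng=_copy.deepcopy(self.hip_rng),
            cor_rng=_copy.deepcopy(self.cor_rng),
            noise_rng=_copy.deepcopy(self.noise_rng),
            seed=self.seed,
            trial_count=self.trial_count,
        )


def build_model(r: int, q: int, lesioned: bool = False,
                learning: LearningConfig | None = None,
                coupling: CouplingConfig | None = None,
                init: InitConfig | None = None,
                seed: int | None = None,
                hip_seed: int | None = None,
                cor_seed: int | None = None) -> CHCQModel:
    """Build an intact or lesioned system with U(0,1)-initialized networks.

    The hippocampal and cortical networks draw from independent RNG streams
    spawned from ``seed`` (overridable per network), so a lesioned run never
    depends on hippocampal draws.  In the intact system the cortical hidden
    layer is initialized by mapping it toward the hippocampal hidden layer
    with strength ``coupling.lambda_init``; in the lesioned system it stays
    purely random.
    """
    if r < 1 or q < 1:
        raise ValueError(f"need r, q >= 1, got r={r}, q={q}")
    learning = learning or LearningConfig()
    coupling = coupling or CouplingConfig()
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    hip_rng = np.random.default_rng(kids[0] if hip_seed is None else hip_seed)
    cor_rng = np.random.default_rng(kids[1] if cor_seed is None else cor_seed)
    noise_rng = np.random.default_rng(kids[2])
    hip = init_hippocampal(r, q, hip_rng)
    cor = init_cortical(r, q, cor_rng, init)
    model = CHCQModel(hippocampus=hip, cortex=cor, coupling=coupling,
                      learning=learning, lesioned=bool(lesioned),
                      hip_rng=hip_rng, cor_rng=cor_rng, noise_rng=noise_rng,
                      seed=seed)
    if not model.lesioned and coupling.lambda_init > 0.0:
        _blend_layer1(model, coupling.lambda_init, sigma=0.0)
    return model


def _blend_layer1(model: CHCQModel, lam: float, sigma: float) -> None:
    cor1, hip1 = model.cortex.layer1, model.hippocampus.layer1
    for name in ("W", "eps", "theta"):
        c = getattr(cor1, name)
        h = getattr(hip1, name)
        if sigma > 0.0:
            h = h + model.noise_rng.normal(0.0, sigma, h.shape)
        c *= (1.0 - lam)
        c += lam * h


def adaptive_transfer(model: CHCQModel) -> CHCQModel:
    """Carry the hippocampal hidden-layer parameters into the cortical hidden
    layer by per-trial blending (strength ``lambda_trial``), adding
    representation noise when ``noise_sigma`` > 0.  No-op on lesioned models
    (logged)."""
    if model.lesioned:
        log.warning("adaptive_transfer called on a lesioned model; ignored")
        return model
    if model.coupling.lambda_trial > 0.0:
        _blend_layer1(model, model.coupling.lambda_trial,
                      model.coupling.noise_sigma)
    return model


def lesion(model: CHCQModel) -> CHCQModel:
    """Remove the hippocampo-cortical link.  Idempotent; the hippocampal
    state is kept but becomes inert."""
    model.lesioned = True
    return model


def model_trial(model: CHCQModel, p, us_present: bool):
    """Run one full conditioning trial and return ``(cr, model)``.

    Intact: (1) hippocampal unsupervised trial, (2) adaptive transfer of the
    hidden-layer parameters, (3) cortical supervised trial with its
    output-layer plasticity gated by the cue's hippocampal novelty
    (familiar cues support less new learning).  Lesioned: cortical trial
    only, at the full base rate — no hippocampal influence of any kind.
    """
    gate = 1.0
    if not model.lesioned:
        cpl = model.coupling
        nov = novelty(model.hippocampus, p)
        gate = min(1.0, max(cpl.novelty_floor, cpl.novelty_gain * nov))
        hip_train_trial(model.hippocampus, p, model.learning, model.hip_rng)
        adaptive_transfer(model)
    _, rec = cor_train_trial(model.cortex, p, us_present, model.learning,
                             model.cor_rng, rate_gate=gate)
    model.trial_count += 1
    return rec.cr, model
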