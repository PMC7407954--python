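"""Shared configuration dataclasses and YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["LearningConfig", "CouplingConfig", "CriterionConfig", "InitConfig",
           "load_config", "save_config"]


@dataclass
class LearningConfig:
    """Learning-rule configuration shared by both networks.

    mu
        Base learning rate, a small positive number in (0, 1].  The
        supervised (Widrow-Hoff) pathway uses ``mu`` directly; the other
        pathways use scaled rates below.
    instar_scale
        Relative rate of the cortical hidden-layer instar drift
        (``mu * instar_scale``).  Small by default: cortical stimulus
        representations change slowly, which is what lets the supervised
        output layer win the race against representational drift.
    hippocampal_scale
        Relative rate of hippocampal instar/outstar learning.  The
        hippocampus encodes cues faster than the cortex drifts, so the
        familiarity it reports is meaningful on behavioral timescales.
    output_rule
        ``"gradient"`` (default): the Widrow-Hoff step is taken through the
        output qubit's readout geometry (delta rule on (d - CR)^2 with the
        phase-rotation step normalized to be scale-free).  ``"printed"``:
        the plain scalar rule Delta = mu * a_i * e applied uniformly to
        W/eps/theta — retained for fidelity experiments; it cannot solve
        discriminations.
    error_deadzone
        No output-layer update when |d - CR| falls below this value: a
        response already at its steady state leaves no further trace.
    outstar_target_mode
        ``"literal"`` drives the hippocampal output-layer weights toward the
        network's own reconstruction; ``"input_target"`` drives them toward
        the input cue (the classical outstar target, and the mode under which
        reconstruction error provably contracts).
    error_sign
        ``"descent"`` uses the prediction error e = d - CR (standard LMS
        descent); ``"literal"`` uses e = CR - d, which ascends the error and
        is kept only as a negative control.
    eps_clamp
        Clamp the per-unit reversal parameter to [0, 1] in the forward pass.
    """

    mu: float = 0.16
    instar_scale: float = 0.03
    hippocampal_scale: float = 0.3
    output_rule: str = "gradient"
    error_deadzone: float = 0.1
    outstar_target_mode: str = "literal"
    error_sign: str = "descent"
    eps_clamp: bool = False

    def __post_init__(self):
        if not (0.0 < self.mu <= 1.0):
            raise ValueError(f"mu must be in (0, 1], got {self.mu}")
        for name in ("instar_scale", "hippocampal_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.error_deadzone <= 1.0):
            raise ValueError("error_deadzone must be in [0, 1]")
        if self.output_rule not in ("gradient", "printed"):
            raise ValueError(f"unknown output_rule {self.output_rule!r}")
        if self.outstar_target_mode not in ("literal", "input_target"):
            raise ValueError(f"unknown outstar_target_mode {self.outstar_target_mode!r}")
        if self.error_sign not in ("descent", "literal"):
            raise ValueError(f"unknown error_sign {self.error_sign!r}")


@dataclass
class CouplingConfig:
    """Hippocampus-to-cortex adaptive-signal configuration.

    lambda_init
        Blend strength applied once at build time: the intact system's
        cortical hidden-layer parameters start at
        ``(1 - lambda_init) * random + lambda_init * hippocampal``.
    lambda_trial
        Per-trial blend applied after each hippocampal learning step; this is
        the strength of the adaptive signal that carries the hippocampal
        internal-representation parameters into the cortical hidden layer.
    noise_sigma
        Scale of zero-mean normal noise added to the transferred parameters
        (models disrupted/noisy internal representations; 0 disables it).
    novelty_gain, novelty_floor
        The adaptive signal also gates cortical output-layer plasticity by
        cue novelty: the intact learning rate is scaled by
        ``clip(novelty_gain * novelty, novelty_floor, 1)``, where novelty is
        the mean distance between the cue and the hippocampal instar weights
        (1 = fully novel, 0 = fully encoded).  A lesioned system has no such
        signal and always learns at the base rate.
    """

    lambda_init: float = 1.0
    lambda_trial: float = 0.02
    noise_sigma: float = 0.0
    novelty_gain: float = 1.8
    novelty_floor: float = 0.2

    def __post_init__(self):
        for name in ("lambda_init", "lambda_trial"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.novelty_gain < 0:
            raise ValueError("novelty_gain must be >= 0")
        if not (0.0 <= self.novelty_floor <= 1.0):
            raise ValueError("novelty_floor must be in [0, 1]")


@dataclass
class InitConfig:
    """Random-initialization ranges.

    All hippocampal parameters and the cortical hidden layer draw from
    U(0, 1).  The cortical output layer draws its weights from
    U(0, ``out_w_scale``) and its reversal parameters from
    U(``out_eps_low``, ``out_eps_high``); phase thresholds stay U(0, 1).
    A negative reversal range starts the output qubit near its ground state,
    so the conditioned response begins near 0 before any reinforcement —
    the naive-animal baseline the conditioning curves assume.
    """

    out_w_scale: float = 1.0
    out_eps_low: float = -4.0
    out_eps_high: float = -2.0

    def __post_init__(self):
        if self.out_w_scale <= 0:
            raise ValueError("out_w_scale must be positive")
        if self.out_eps_low > self.out_eps_high:
            raise ValueError("out_eps_low must be <= out_eps_high")


@dataclass
class CriterionConfig:
    """Steady-state criterion for the conditioned response.

    A paired item reaches criterion on the first trial opening a run of
    ``consecutive`` trials with CR >= ``hi``; an unpaired item symmetrically
    with CR <= ``lo``.  ``max_trials`` bounds any to-criterion phase.
    """

    hi: float = 0.85
    lo: float = 0.18
    consecutive: int = 3
    max_trials: int = 500

    def __post_init__(self):
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(f"need 0 <= lo < hi <= 1, got lo={self.lo}, hi={self.hi}")
        if self.consecutive < 1:
            raise ValueError("consecutive must be >= 1")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


_SECTIONS = {"learning": LearningConfig, "coupling": CouplingConfig,
             "criterion": CriterionConfig, "init": InitConfig}


def load_config(path) -> dict:
    """Load a YAML config file with ``learning``/``coupling``/``criterion``
    sections (missing sections fall back to defaults); any ``battery``
    section is passed through as a plain dict."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for name, cls in _SECTIONS.items():
        out[name] = cls(**(raw.get(name) or {}))
    if "battery" in raw:
        out["battery"] = raw["battery"]
    return out


def save_config(path, learning: LearningConfig, coupling: CouplingConfig,
                criterion: CriterionConfig, init: InitConfig | None = None,
                battery: dict | None = None) -> None:
    doc = {"learning": asdict(learning), "coupling": asdict(coupling),
           "criterion": asdict(criterion),
           "init": asdict(init or InitConfig())}
    if battery:
        doc["battery"] = dict(battery)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
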