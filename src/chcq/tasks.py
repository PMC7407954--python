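"""Classical-conditioning task battery: cue encoding, paradigm definitions,
steady-state criterion and trials-to-criterion measurement.

Cues are pairs of conditioned stimuli A and B with amplitudes in [0, 1],
presented against one of three contexts (X, Y, Z), paired (+) or unpaired (-)
with the unconditioned stimulus.  A cue is encoded as the length-5 amplitude
vector ``[amp_A, amp_B, 1{ctx=X}, 1{ctx=Y}, 1{ctx=Z}]``.

A "trial" for a multi-item phase is one sweep over all items in listed order,
so discrimination counts are comparable to single-item counts.  A phase runs
either for a fixed number of trials (pre-exposure phases whose length is part
of the protocol) or until every item's CR history satisfies the sustained
steady-state criterion; extended task variants overtrain the relevant phase
by a multiplicative factor after criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import CriterionConfig
from .model import CHCQModel, model_trial

__all__ = ["CueSpec", "Phase", "Paradigm", "TrialLog", "PhaseResult",
           "CONTEXTS", "R_CUE", "encode_cue", "shift_context",
           "make_paradigm", "paradigm_names", "steady_state_index",
           "run_phase", "run_paradigm"]

CONTEXTS = ("X", "Y", "Z")
#: cue vector length: amplitudes of A and B plus three one-hot context slots
R_CUE = 5


@dataclass(frozen=True)
class CueSpec:
    """One conditioning item: stimulus amplitudes, context and US pairing."""

    amp_A: float = 0.0
    amp_B: float = 0.0
    context: str = "X"
    us: bool = False
    label: str | None = None

    def __post_init__(self):
        for name in ("amp_A", "amp_B"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.label is None:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        parts = []
        if self.amp_A > 0:
            parts.append("A" if self.amp_A == 1.0 else f"A{self.amp_A:g}")
        if self.amp_B > 0:
            parts.append("B" if self.amp_B == 1.0 else f"B{self.amp_B:g}")
        return "".join(parts) + self.context + ("+" if self.us else "-")


def encode_cue(spec: CueSpec) -> np.ndarray:
    """Amplitude vector ``[amp_A, amp_B, 1{X}, 1{Y}, 1{Z}]`` (R = 5)."""
    ctx = [1.0 if spec.context == c else 0.0 for c in CONTEXTS]
    return np.array([spec.amp_A, spec.amp_B, *ctx], dtype=float)


def shift_context(spec: CueSpec, new_context: str) -> CueSpec:
    """Same stimuli and pairing in a different context."""
    if new_context == spec.context:
        raise ValueError(f"context shift requires a new context, got {new_context!r}")
    if new_context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {new_context!r}")
    return replace(spec, context=new_context, label=None)


@dataclass(frozen=True)
class Phase:
    """Ordered items plus a stopping mode.

    ``to_criterion`` runs sweeps until every item satisfies the steady-state
    criterion; ``fixed`` runs exactly ``fixed_length`` sweeps; ``overtrain``
    runs to criterion and then continues for ``(overtrain_factor - 1)`` times
    as many extra sweeps (the "extended conditioning" manipulation).
    """

    items: tuple[CueSpec, ...]
    mode: str = "to_criterion"
    fixed_length: Optional[int] = None
    overtrain_factor: int = 3

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise ValueError("a phase needs at least one item")
        if self.mode not in ("to_criterion", "fixed", "overtrain"):
            raise ValueError(f"unknown phase mode {self.mode!r}")
        if (self.mode == "fixed") != (self.fixed_length is not None):
            raise ValueError("fixed_length must be set iff mode='fixed'")
        if self.fixed_length is not None and self.fixed_length < 1:
            raise ValueError("fixed_length must be >= 1")


@dataclass(frozen=True)
class Paradigm:
    """A named ordered list of 1-3 phases, plus optional model overrides
    (e.g. representation noise for the disrupted-system variant)."""

    name: str
    phases: tuple[Phase, ...]
    noise_sigma: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "phases", tuple(self.phases))
        if not (1 <= len(self.phases) <= 3):
            raise ValueError("a paradigm has 1-3 phases")


def _cue(a=0.0, b=0.0, ctx="X", us=False) -> CueSpec:
    return CueSpec(amp_A=a, amp_B=b, context=ctx, us=us)


def _tc(*items) -> Phase:
    return Phase(items, mode="to_criterion")


def _fixed(n, *items) -> Phase:
    return Phase(items, mode="fixed", fixed_length=n)


# Fixed pre-exposure lengths are part of the protocol (their trial counts are
# identical across systems by construction): 50 for unreinforced single- or
# compound-cue pre-exposure and for the final sensory-preconditioning probe,
# 20 for compound reinforced pre-exposure.
PREEXPOSURE_LONG = 50
PREEXPOSURE_SHORT = 20

AX_P = _cue(a=1, us=True)
AX_M = _cue(a=1, us=False)
BX_P = _cue(b=1, us=True)
BX_M = _cue(b=1, us=False)
ABX_P = _cue(a=1, b=1, us=True)
ABX_M = _cue(a=1, b=1, us=False)
AY_P = shift_context(AX_P, "Y")


def _builders():
    return {
        "a_plus": lambda: Paradigm("a_plus", [_tc(AX_P)]),
        "a_minus": lambda: Paradigm("a_minus", [_tc(AX_M)]),
        "stimulus_discrimination": lambda: Paradigm(
            "stimulus_discrimination", [_tc(AX_P, BX_M)]),
        "discrimination_reversal": lambda: Paradigm(
            "discrimination_reversal", [_tc(AX_P, BX_M), _tc(AX_M, BX_P)]),
        "blocking": lambda: Paradigm(
            "blocking", [_tc(AX_P), _tc(ABX_P), _tc(BX_M)]),
        "overshadowing": lambda: Paradigm(
            "overshadowing", [_fixed(PREEXPOSURE_SHORT, ABX_P), _tc(AX_P, BX_P)]),
        "easy_hard_transfer": lambda: Paradigm(
            "easy_hard_transfer",
            [_tc(_cue(a=0.9, us=True), _cue(a=0.1, us=False)),
             _tc(_cue(a=0.6, us=True), _cue(a=0.4, us=False))]),
        "latent_inhibition": lambda: Paradigm(
            "latent_inhibition", [_fixed(PREEXPOSURE_LONG, AX_M), _tc(AX_P)]),
        "sensory_preconditioning": lambda: Paradigm(
            "sensory_preconditioning",
            [_fixed(PREEXPOSURE_LONG, ABX_M), _tc(AX_P),
             _fixed(PREEXPOSURE_LONG, BX_M)]),
        "compound_preconditioning": lambda: Paradigm(
            "compound_preconditioning",
            [_fixed(PREEXPOSURE_SHORT, ABX_M), _tc(AX_P, BX_M)]),
        "context_shift": lambda: Paradigm(
            "context_shift", [_tc(AX_P), _tc(AY_P)]),
        "context_shift_latent_inhibition": lambda: Paradigm(
            "context_shift_latent_inhibition",
            [_fixed(PREEXPOSURE_LONG, AX_M), _tc(AY_P)]),
        "feedforward_comparison": lambda: Paradigm(
            "feedforward_comparison", [_fixed(PREEXPOSURE_LONG, AX_M), _tc(AX_P)]),
        # extended/disrupted variants
        "extended_blocking": lambda: Paradigm(
            "extended_blocking",
            [_tc(AX_P), Phase((ABX_P,), mode="overtrain"), _tc(BX_M)]),
        "extended_overshadowing": lambda: Paradigm(
            "extended_overshadowing",
            [_fixed(3 * PREEXPOSURE_SHORT, ABX_P), _tc(AX_P, BX_P)]),
        "extended_context": lambda: Paradigm(
            "extended_context", [Phase((AX_P,), mode="overtrain"), _tc(AY_P)]),
        "disrupted_discrimination": lambda: Paradigm(
            "disrupted_discrimination", [_tc(AX_P, BX_M)], noise_sigma=0.1),
    }


def paradigm_names() -> list[str]:
    return sorted(_builders())


def make_paradigm(name: str) -> Paradigm:
    """Build a named paradigm (see :func:`paradigm_names` for the catalogue)."""
    try:
        return _builders()[name]()
    except KeyError:
        raise KeyError(
            f"unknown paradigm {name!r}; valid names: {', '.join(paradigm_names())}"
        ) from None


NOT_REACHED = None


def steady_state_index(cr_history, target: int,
                       criterion: CriterionConfig) -> Optional[int]:
    """First 1-based trial opening a sustained criterion run, or None.

    A run is ``criterion.consecutive`` successive trials with CR >= hi
    (target 1) or CR <= lo (target 0).
    """
    cr = np.asarray(list(cr_history), dtype=float)
    if cr.size == 0:
        raise ValueError("empty CR history")
    ok = cr >= criterion.hi if target else cr <= criterion.lo
    need = criterion.consecutive
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= need:
            return i - need + 2   # 1-based index of the run's first trial
    return NOT_REACHED


@dataclass
class TrialLog:
    """Per-presentation CR trace: (phase, trial, item, cr, target) rows."""

    rows: list = field(default_factory=list)

    def add(self, phase: int, trial: int, item: str, cr: float, target: int):
        self.rows.append((phase, trial, item, cr, target))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["phase", "trial", "item", "cr", "target"])

    def extend(self, other: "TrialLog"):
        self.rows.extend(other.rows)


@dataclass
class PhaseResult:
    """Trials-to-criterion for one phase (``trials`` is the fixed length for
    fixed phases, the criterion index otherwise; ``reached`` is False when
    ``max_trials`` sweeps elapsed without criterion)."""

    trials: Optional[int]
    reached: bool
    sweeps_run: int


def _phase_criterion_met(histories, items, criterion) -> Optional[int]:
    idxs = []
    for item, hist in zip(items, histories):
        idx = steady_state_index(hist, 1 if item.us else 0, criterion)
        if idx is NOT_REACHED:
            return NOT_REACHED
        idxs.append(idx)
    return max(idxs)


def run_phase(model: CHCQModel, phase: Phase, criterion: CriterionConfig,
              phase_index: int = 1):
    """Run one phase on a continuously-learning model.

    Returns ``(PhaseResult, TrialLog, model)``.  Each sweep presents every
    item in order; in to-criterion mode sweeps continue until all items
    satisfy the criterion (or ``max_trials`` elapse, reported as not reached
    rather than raised).
    """
    log = TrialLog()
    histories = [[] for _ in phase.items]
    cues = [encode_cue(it) for it in phase.items]

    def sweep(t):
        for it, cue, hist in zip(phase.items, cues, histories):
            cr, _ = model_trial(model, cue, it.us)
            hist.append(cr)
            log.add(phase_index, t, it.label, cr, 1 if it.us else 0)

    if phase.mode == "fixed":
        for t in range(1, phase.fixed_length + 1):
            sweep(t)
        return PhaseResult(phase.fixed_length, True, phase.fixed_length), log, model

    t = 0
    reached_at = NOT_REACHED
    while t < criterion.max_trials:
        t += 1
        sweep(t)
        reached_at = _phase_criterion_met(histories, phase.items, criterion)
        if reached_at is not NOT_REACHED:
            break
    if reached_at is NOT_REACHED:
        return PhaseResult(NOT_REACHED, False, t), log, model

    if phase.mode == "overtrain":
        extra = (phase.overtrain_factor - 1) * t
        for k in range(t + 1, t + extra + 1):
            sweep(k)
        t += extra
    return PhaseResult(reached_at, True, t), log, model


def run_paradigm(model: CHCQModel, paradigm: Paradigm,
                 criterion: CriterionConfig):
    """Run all phases in order on the same model.

    Returns ``(results, log, model)`` where ``results`` is a list of
    :class:`PhaseResult`, one per phase.  A paradigm-level ``noise_sigma``
    override is applied to the model's coupling for the run.
    """
    if paradigm.noise_sigma is not None:
        model.coupling = replace(model.coupling, noise_sigma=paradigm.noise_sigma)
    results, log = [], TrialLog()
    for k, phase in enumerate(paradigm.phases, start=1):
        res, plog, model = run_phase(model, phase, criterion, phase_index=k)
        results.append(res)
        log.extend(plog)
    return results, log, model
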