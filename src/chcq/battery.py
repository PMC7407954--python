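"""Battery runner, calibration and the generic feedforward baseline.

Runs the conditioning-paradigm battery over both systems and many seeds,
aggregates trials-to-criterion into a summary table (one row per task /
system / phase), and exposes the grid-search calibration that produced the
shipped default configuration.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (CouplingConfig, CriterionConfig, InitConfig,
                     LearningConfig, save_config)
from .model import build_model
from .tasks import (CriterionConfig as _Crit, Paradigm, encode_cue,
                    make_paradigm, run_paradigm, steady_state_index)

__all__ = ["BatteryConfig", "BatteryResult", "REFERENCE_COUNTS", "DEFAULT_Q",
           "run_battery", "baseline_feedforward", "calibrate", "seed_list"]

log = logging.getLogger(__name__)

#: number of hidden qubits used throughout the shipped configuration
DEFAULT_Q = 16

#: cue vector length (A, B amplitudes + three context slots)
DEFAULT_R = 5

# Published trials-to-criterion of the quantum cortico-hippocampal model,
# used as the calibration reference: (task, system, 1-based phase) -> trials.
REFERENCE_COUNTS = {
    ("a_plus", "intact", 1): 23, ("a_plus", "lesioned", 1): 18,
    ("a_minus", "intact", 1): 2, ("a_minus", "lesioned", 1): 2,
    ("stimulus_discrimination", "intact", 1): 24,
    ("stimulus_discrimination", "lesioned", 1): 17,
    ("discrimination_reversal", "intact", 2): 22,
    ("discrimination_reversal", "lesioned", 2): 32,
    ("blocking", "intact", 3): 12, ("blocking", "lesioned", 3): 3,
    ("latent_inhibition", "intact", 2): 31,
    ("latent_inhibition", "lesioned", 2): 18,
    ("context_shift", "intact", 2): 1,
}

ALL_TASKS = ("a_plus", "a_minus", "stimulus_discrimination",
             "discrimination_reversal", "blocking", "overshadowing",
             "easy_hard_transfer", "latent_inhibition",
             "sensory_preconditioning", "compound_preconditioning",
             "context_shift")


@dataclass
class BatteryConfig:
    """What to run and how to aggregate."""

    tasks: tuple = ALL_TASKS
    systems: tuple = ("intact", "lesioned")
    n_seeds: int = 25
    base_seed: int = 0
    aggregation: str = "median"
    q: int = DEFAULT_Q
    learning: LearningConfig = field(default_factory=LearningConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    criterion: CriterionConfig = field(default_factory=CriterionConfig)
    init: InitConfig = field(default_factory=InitConfig)
    out_dir: Optional[str] = None
    write_traces: bool = False

    def __post_init__(self):
        if not self.tasks:
            raise ValueError("tasks must be nonempty")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.aggregation not in ("median", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        bad = set(self.systems) - {"intact", "lesioned"}
        if bad:
            raise ValueError(f"unknown systems {sorted(bad)}")


@dataclass
class BatteryResult:
    """Aggregated counts (``summary``) plus the per-run counts (``runs``)."""

    summary: pd.DataFrame
    runs: pd.DataFrame
    config_hash: str
    seeds: list


def seed_list(base_seed: int, n: int) -> list[int]:
    """Deterministic per-run seeds derived from one base seed (all < 2^31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def _config_hash(cfg: BatteryConfig) -> str:
    blob = json.dumps({
        "tasks": list(cfg.tasks), "systems": list(cfg.systems),
        "n_seeds": cfg.n_seeds, "base_seed": cfg.base_seed,
        "aggregation": cfg.aggregation, "q": cfg.q,
        "learning": asdict(cfg.learning), "coupling": asdict(cfg.coupling),
        "criterion": asdict(cfg.criterion), "init": asdict(cfg.init),
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_task(task: str, system: str, seed: int, cfg: BatteryConfig):
    """One fresh model, one paradigm.  Returns (per-phase trials, reached
    flags, TrialLog)."""
    paradigm = make_paradigm(task)
    model = build_model(DEFAULT_R, cfg.q, lesioned=(system == "lesioned"),
                        learning=cfg.learning, coupling=cfg.coupling,
                        init=cfg.init, seed=seed)
    results, tlog, _ = run_paradigm(model, paradigm, cfg.criterion)
    trials = [r.trials if r.reached else cfg.criterion.max_trials
              for r in results]
    reached = [r.reached for r in results]
    return trials, reached, tlog


def run_battery(cfg: BatteryConfig) -> BatteryResult:
    """Run every (task, system, seed) combination and aggregate.

    Not-reached runs are scored as ``max_trials`` and counted, never
    dropped.  With ``out_dir`` set, writes ``summary.csv`` (schema:
    task,system,phase,trials_median,trials_iqr,n_seeds,n_not_reached),
    a ``battery_manifest.json`` audit record, and per-run
    ``trace_<task>_<system>_<seed>.csv`` files when ``write_traces``.
    """
    seeds = seed_list(cfg.base_seed, cfg.n_seeds)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    run_rows, trace_frames = [], []
    for task in cfg.tasks:
        for system in cfg.systems:
            for seed in seeds:
                trials, reached, tlog = run_task(task, system, seed, cfg)
                for ph, (t, ok) in enumerate(zip(trials, reached), start=1):
                    run_rows.append((task, system, seed, ph, t, ok))
                if out and cfg.write_traces:
                    df = tlog.to_frame()
                    df.insert(0, "seed", seed)
                    df.insert(0, "system", system)
                    df.insert(0, "task", task)
                    df = df[["task", "system", "seed", "phase", "trial",
                             "item", "cr", "target"]]
                    df.to_csv(out / f"trace_{task}_{system}_{seed}.csv",
                              index=False)
    runs = pd.DataFrame(run_rows, columns=["task", "system", "seed", "phase",
                                           "trials", "reached"])
    agg = np.median if cfg.aggregation == "median" else np.mean
    rows = []
    for (task, system, ph), grp in runs.groupby(["task", "system", "phase"],
                                                sort=False):
        t = grp["trials"].to_numpy(float)
        iqr = float(np.subtract(*np.percentile(t, [75, 25])))
        rows.append((task, system, ph, float(agg(t)), iqr, len(t),
                     int((~grp["reached"]).sum())))
    summary = pd.DataFrame(rows, columns=[
        "task", "system", "phase", "trials_median", "trials_iqr",
        "n_seeds", "n_not_reached"])
    h = _config_hash(cfg)
    if out:
        summary.to_csv(out / "summary.csv", index=False)
        (out / "battery_manifest.json").write_text(json.dumps({
            "config_hash": h, "seeds": seeds, "learning": asdict(cfg.learning),
            "coupling": asdict(cfg.coupling), "criterion": asdict(cfg.criterion),
            "init": asdict(cfg.init), "q": cfg.q}, indent=2))
    return BatteryResult(summary=summary, runs=runs, config_hash=h, seeds=seeds)


# ---------------------------------------------------------------------------
# generic feedforward baseline

def baseline_feedforward(paradigm: Paradigm, q: int = DEFAULT_Q,
                         mu: float = 0.5, seed: int = 0,
                         criterion: CriterionConfig | None = None):
    """Trials-to-criterion of a standard one-hidden-layer sigmoid network on
    the same cues and criterion (online backprop, squared error).

    This is the conventional supervised network the lesioned system is
    compared against; its response pattern has no hippocampal component by
    construction.  Returns a list of per-phase trial counts (max_trials for
    phases that never reach criterion).
    """
    criterion = criterion or CriterionConfig()
    rng = np.random.default_rng(seed)
    r = DEFAULT_R
    W1 = rng.normal(0.0, 0.5, (r, q)); b1 = np.zeros(q)
    W2 = rng.normal(0.0, 0.5, q); b2 = 0.0

    def trial(p, d):
        nonlocal W1, b1, W2, b2
        h = expit(p @ W1 + b1)
        o = expit(h @ W2 + b2)
        delta_o = (o - d) * o * (1 - o)
        delta_h = delta_o * W2 * h * (1 - h)
        W2 -= mu * delta_o * h; b2 -= mu * delta_o
        W1 -= mu * np.outer(p, delta_h); b1 -= mu * delta_h
        return float(o)

    counts = []
    for phase in paradigm.phases:
        cues = [(encode_cue(it), 1.0 if it.us else 0.0) for it in phase.items]
        if phase.mode == "fixed":
            for _ in range(phase.fixed_length):
                for p, d in cues:
                    trial(p, d)
            counts.append(phase.fixed_length)
            continue
        hists = [[] for _ in cues]
        result = None
        for _ in range(criterion.max_trials):
            for (p, d), hist in zip(cues, hists):
                hist.append(trial(p, d))
            idxs = [steady_state_index(h, int(d), criterion)
                    for h, (_, d) in zip(hists, cues)]
            if all(i is not None for i in idxs):
                result = max(idxs)
                break
        counts.append(result if result is not None else criterion.max_trials)
    return counts


# ---------------------------------------------------------------------------
# calibration

def calibrate(search_space: dict, reference: dict | None = None,
              n_seeds: int = 11, base_seed: int = 0,
              out_path=None):
    """Grid search minimizing the summed relative deviation of aggregated
    trials-to-criterion from the reference counts.

    ``search_space`` maps parameter names (``mu``, ``q``, ``lambda_trial``,
    ``hi``, ``lo``, ``novelty_gain``, ``hippocampal_scale``) to candidate
    lists; unspecified parameters keep their defaults.  Returns
    ``(learning, coupling, criterion, q, objective)`` for the best point and
    optionally writes it as a YAML config.
    """
    reference = reference or REFERENCE_COUNTS
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("search space must be nonempty")
    names = sorted(search_space)
    tasks = tuple(sorted({t for t, _, _ in reference}))
    systems = tuple(sorted({s for _, s, _ in reference}))
    best = None
    for values in itertools.product(*(search_space[n] for n in names)):
        point = dict(zip(names, values))
        learning = LearningConfig(
            mu=point.get("mu", LearningConfig.mu),
            hippocampal_scale=point.get("hippocampal_scale",
                                        LearningConfig.hippocampal_scale))
        coupling = CouplingConfig(
            lambda_trial=point.get("lambda_trial", CouplingConfig.lambda_trial),
            novelty_gain=point.get("novelty_gain", CouplingConfig.novelty_gain))
        criterion = CriterionConfig(hi=point.get("hi", CriterionConfig.hi),
                                    lo=point.get("lo", CriterionConfig.lo))
        q = int(point.get("q", DEFAULT_Q))
        cfg = BatteryConfig(tasks=tasks, systems=systems, n_seeds=n_seeds,
                            base_seed=base_seed, q=q, learning=learning,
                            coupling=coupling, criterion=criterion)
        res = run_battery(cfg)
        obj = 0.0
        med = res.summary.set_index(["task", "system", "phase"])["trials_median"]
        for key, ref in reference.items():
            obj += abs(float(med.loc[key]) - ref) / max(ref, 1)
        log.info("calibrate point %s -> objective %.3f", point, obj)
        if best is None or obj < best[-1]:
            best = (learning, coupling, criterion, q, obj)
    learning, coupling, criterion, q, obj = best
    if out_path is not None:
        save_config(out_path, learning, coupling, criterion,
                    battery={"q": q})
    return best
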