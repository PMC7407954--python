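"""Battery runner, calibration, baseline network, serialization, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from chcq.battery import (BatteryConfig, baseline_feedforward, calibrate,
                          run_battery, seed_list)
from chcq.cli import main as cli_main
from chcq.config import (CouplingConfig, CriterionConfig, InitConfig,
                         LearningConfig, load_config, save_config)
from chcq.io import load_state, save_checkpoint, save_state, state_to_frame
from chcq.model import build_model
from chcq.tasks import make_paradigm

SMALL = dict(tasks=("a_minus",), systems=("lesioned",), n_seeds=2)


def test_seed_list_is_deterministic_and_bounded():
    a = seed_list(0, 10)
    b = seed_list(0, 10)
    assert a == b
    assert all(0 <= s < 2 ** 31 for s in a)
    assert seed_list(1, 10) != a


def test_summary_schema_and_determinism(tmp_path):
    cfg = BatteryConfig(out_dir=str(tmp_path / "one"), **SMALL)
    res1 = run_battery(cfg)
    cfg2 = BatteryConfig(out_dir=str(tmp_path / "two"), **SMALL)
    res2 = run_battery(cfg2)
    assert list(res1.summary.columns) == [
        "task", "system", "phase", "trials_median", "trials_iqr",
        "n_seeds", "n_not_reached"]
    pd.testing.assert_frame_equal(res1.summary, res2.summary)
    c1 = (tmp_path / "one" / "summary.csv").read_text()
    c2 = (tmp_path / "two" / "summary.csv").read_text()
    assert c1 == c2
    manifest = json.loads((tmp_path / "one" / "battery_manifest.json").read_text())
    assert manifest["config_hash"] == res1.config_hash
    assert manifest["seeds"] == res1.seeds


def test_not_reached_runs_counted_not_dropped():
    learning = LearningConfig(mu=0.1, instar_scale=0.0, hippocampal_scale=0.0,
                              error_deadzone=1.0)
    cfg = BatteryConfig(tasks=("a_plus",), systems=("lesioned",), n_seeds=2,
                        learning=learning,
                        criterion=CriterionConfig(max_trials=20))
    res = run_battery(cfg)
    row = res.summary.iloc[0]
    assert row["n_not_reached"] == 2
    assert row["trials_median"] == 20


def test_trace_files_have_documented_schema(tmp_path):
    cfg = BatteryConfig(out_dir=str(tmp_path), write_traces=True, **SMALL)
    res = run_battery(cfg)
    trace = next(tmp_path.glob("trace_a_minus_lesioned_*.csv"))
    df = pd.read_csv(trace)
    assert list(df.columns) == ["task", "system", "seed", "phase", "trial",
                                "item", "cr", "target"]
    assert (df["task"] == "a_minus").all()


def test_battery_config_validation():
    with pytest.raises(ValueError):
        BatteryConfig(tasks=())
    with pytest.raises(ValueError):
        BatteryConfig(systems=("intact", "cortical"))
    with pytest.raises(ValueError):
        BatteryConfig(aggregation="mode")


def test_baseline_feedforward_learns_the_simple_tasks():
    crit = CriterionConfig()
    fast = [baseline_feedforward(make_paradigm("a_minus"), seed=s,
                                 criterion=crit)[0] for s in range(5)]
    assert np.median(fast) < 20
    acq = [baseline_feedforward(make_paradigm("a_plus"), seed=s,
                                criterion=crit)[0] for s in range(5)]
    assert all(t < crit.max_trials for t in acq)


def test_baseline_zero_rate_never_reaches():
    crit = CriterionConfig(max_trials=30)
    counts = baseline_feedforward(make_paradigm("a_plus"), mu=0.0, seed=0,
                                  criterion=crit)
    assert counts[0] == 30


def test_baseline_respects_fixed_phases():
    counts = baseline_feedforward(make_paradigm("latent_inhibition"), seed=1)
    assert counts[0] == 50


def test_calibrate_single_point_returns_it(tmp_path):
    ref = {("a_minus", "lesioned", 1): 2}
    out = tmp_path / "cal.yaml"
    learning, coupling, criterion, q, obj = calibrate(
        {"mu": [0.16], "q": [8]}, reference=ref, n_seeds=2, out_path=out)
    assert learning.mu == 0.16 and q == 8
    assert out.exists()
    sections = load_config(out)
    assert sections["learning"].mu == 0.16


def test_calibrate_objective_zero_iff_exact_match():
    """Using the measured medians themselves as the reference must give a
    zero objective (the objective is a pure deviation measure)."""
    cfg = BatteryConfig(**SMALL)
    res = run_battery(cfg)
    med = res.summary.set_index(["task", "system", "phase"])["trials_median"]
    ref = {k: float(v) for k, v in med.items()}
    *_, obj = calibrate({"mu": [LearningConfig().mu]}, reference=ref,
                        n_seeds=2)
    assert obj == pytest.approx(0.0)
    *_, obj2 = calibrate({"mu": [LearningConfig().mu]},
                         reference={k: v + 5 for k, v in ref.items()},
                         n_seeds=2)
    assert obj2 > 0


def test_calibrate_empty_space_rejected():
    with pytest.raises(ValueError):
        calibrate({})
    with pytest.raises(ValueError):
        calibrate({"mu": []})


def test_state_serialization_round_trip(tmp_path):
    m = build_model(5, 6, seed=3)
    path = tmp_path / "cortex.csv"
    save_state(m.cortex, path)
    loaded = load_state(path, "cortical")
    np.testing.assert_allclose(loaded.layer1.W, m.cortex.layer1.W)
    np.testing.assert_allclose(loaded.layer2.theta, m.cortex.layer2.theta)
    df = state_to_frame(m.cortex)
    assert list(df.columns) == ["layer", "matrix", "row", "col", "value"]


def test_checkpoint_manifest(tmp_path):
    m = build_model(5, 6, lesioned=True, seed=3)
    d = save_checkpoint(m, tmp_path / "ckpt")
    manifest = json.loads((d / "manifest.json").read_text())
    assert manifest["lesioned"] is True
    assert manifest["q"] == 6
    assert (d / "hippocampus.csv").exists() and (d / "cortex.csv").exists()


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "cfg.yaml"
    save_config(path, LearningConfig(mu=0.2), CouplingConfig(lambda_trial=0.1),
                CriterionConfig(hi=0.8), InitConfig(out_w_scale=0.5),
                battery={"q": 4})
    sections = load_config(path)
    assert sections["learning"].mu == 0.2
    assert sections["coupling"].lambda_trial == 0.1
    assert sections["criterion"].hi == 0.8
    assert sections["init"].out_w_scale == 0.5
    assert sections["battery"]["q"] == 4


def test_cli_run_and_battery(tmp_path):
    runner = CliRunner()
    result = runner.invoke(cli_main, ["run", "--task", "a_minus",
                                      "--system", "lesioned", "--seed", "1",
                                      "--out", str(tmp_path)])
    assert result.exit_code == 0, result.output
    assert "phase 1:" in result.output
    assert any(tmp_path.glob("trace_a_minus_lesioned_1.csv"))
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text("battery:\n  tasks: [a_minus, a_plus]\n")
    result = runner.invoke(cli_main, ["battery", "--config", str(cfg_path),
                                      "--out", str(tmp_path / "bat"),
                                      "--n-seeds", "1"])
    assert result.exit_code == 0, result.output
    summary = pd.read_csv(tmp_path / "bat" / "summary.csv")
    assert set(summary["task"]) == {"a_minus", "a_plus"}
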