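"""End-to-end orchestration across the task types."""

import numpy as np
import pytest
import yaml

from simfarm.config import GlobalConfig
from simfarm.backend import BackendConfig
from simfarm.balance import LoadBalanceConfig
from simfarm.fixtures import get_model, make_estimation_dataset
from simfarm.orchestrate import run_task
from simfarm.tasks import TaskSpec


def test_stochastic_repeat_end_to_end(fast_config, birth_death):
    task = TaskSpec(task_type="stochastic_repeat", model=birth_death,
                    name="stoch", repeat_count=12, t_end=3.0, n_points=7,
                    base_seed=1)
    result = run_task(task, fast_config)
    assert result.state == "finished"
    summary_path = result.artifacts["ensemble_summary"]
    header = summary_path.read_text().splitlines()[0]
    assert header == "Time\tA_mean\tA_sd"
    # all 12 repeats accounted for, regardless of how they were chunked
    assert sum(j.assigned_repeats for j in result.bundle.jobs) == 12
    assert result.usage.n_jobs == len(result.bundle.jobs)
    assert result.usage.cpu_hours >= 0.0
    assert (result.task_dir / "task_state.yaml").exists()


def test_scan_end_to_end_matches_direct_evaluation(fast_config):
    task = TaskSpec(task_type="scan", model=get_model("decay"), name="scan",
                    scan_parameters=["k"],
                    scan_grid=[[0.5], [1.0], [1.5], [2.0]],
                    t_end=1.0, n_points=5)
    result = run_task(task, fast_config)
    assert result.state == "finished"
    lines = result.artifacts["scan_results"].read_text().splitlines()
    assert lines[0] == "k\tA"
    ks = [float(l.split("\t")[0]) for l in lines[1:]]
    finals = [float(l.split("\t")[1]) for l in lines[1:]]
    assert ks == [0.5, 1.0, 1.5, 2.0]
    np.testing.assert_allclose(finals, 100.0 * np.exp(-np.array(ks)), rtol=1e-5)


def test_sensitivity_end_to_end(fast_config, birth_death):
    """Steady state of the immigration–death process is k/d: the scaled
    sensitivities are exactly +1 (to k) and −1 (to d) everywhere in the box,
    so each parameter's max = min and importance = 0."""
    task = TaskSpec(task_type="sensitivity", model=birth_death, name="sens",
                    target_spec="A", target_mode="steady_state",
                    sensitivity_parameters=[("k", 8.0, 12.0), ("d", 0.8, 1.2)],
                    algorithm="local_search")
    result = run_task(task, fast_config)
    assert result.state == "finished"
    assert len(result.bundle.jobs) == 4  # 2 parameters -> 4 jobs
    rows = result.artifacts["sensitivity_report"].read_text().splitlines()[1:]
    values = {r.split("\t")[0]: [float(x) for x in r.split("\t")[1:]] for r in rows}
    assert values["k"][0] == pytest.approx(1.0, abs=1e-3)
    assert values["k"][1] == pytest.approx(1.0, abs=1e-3)
    assert values["d"][0] == pytest.approx(-1.0, abs=1e-3)
    assert values["k"][2] == pytest.approx(0.0, abs=2e-3)  # importance


def test_optimization_repeat_end_to_end(fast_config):
    # minimize A(t=1) over k in [0.1, 3]: decay is monotone in k, optimum k=3
    task = TaskSpec(task_type="optimization_repeat", model=get_model("decay"),
                    name="opt", target_spec="A", repeat_count=4,
                    optimization_parameters=[("k", 0.1, 3.0)],
                    algorithm="particle_swarm",
                    algorithm_settings={"swarm_size": 8, "iterations": 20},
                    t_end=1.0, n_points=5, base_seed=2)
    result = run_task(task, fast_config)
    assert result.state == "finished"
    best = yaml.safe_load(result.artifacts["best_result"].read_text())
    assert best["best_parameters"]["k"] == pytest.approx(3.0, abs=1e-2)
    model_doc = result.artifacts["best_model"].read_text()
    assert "k = " in model_doc


def test_parameter_estimation_repeat_end_to_end(fast_config):
    tsv, truth = make_estimation_dataset("decay", noise_sd=0.1, n_points=21, seed=5)
    task = TaskSpec(task_type="parameter_estimation_repeat",
                    model=get_model("decay"), name="fit", repeat_count=3,
                    optimization_parameters=[("k", 0.1, 5.0)],
                    dataset_tsv=tsv, algorithm="particle_swarm",
                    algorithm_settings={"swarm_size": 8, "iterations": 25},
                    base_seed=3)
    result = run_task(task, fast_config)
    assert result.state == "finished"
    best = yaml.safe_load(result.artifacts["best_result"].read_text())
    assert best["best_parameters"]["k"] == pytest.approx(truth["k"], rel=0.05)


def test_algorithm_sweep_end_to_end(fast_config):
    task = TaskSpec(task_type="algorithm_sweep", model=get_model("decay"),
                    name="sweep", target_spec="A",
                    optimization_parameters=[("k", 0.1, 3.0)],
                    algorithms=[("particle_swarm", {"swarm_size": 8, "iterations": 30}),
                                ("local_search", {})],
                    t_end=1.0, n_points=5)
    result = run_task(task, fast_config)
    assert result.state == "finished"
    assert len(result.bundle.jobs) == 2
    best = yaml.safe_load(result.artifacts["best_algorithms"].read_text())
    assert set(best["best_algorithms"]) <= {"particle_swarm", "local_search"}
    assert best["best_algorithms"]


def test_raw_mode_end_to_end(fast_config):
    task = TaskSpec(task_type="raw", name="raw", repeat_count=3,
                    raw_args="--seed {job} -o {out}")
    result = run_task(task, fast_config)
    assert result.state == "finished"
    for i in range(3):
        content = (result.task_dir / f"job_{i}.out").read_text()
        assert content.strip() == f"--seed {i} -o job_{i}.out"


def test_failed_task_produces_report_bundle_and_notification(tmp_path):
    config = GlobalConfig(balance=LoadBalanceConfig(t_target=0.2),
                          backend=BackendConfig(max_parallel=1),
                          work_dir=tmp_path / "w",
                          notification=str(tmp_path / "notes.txt"))
    # negative horizon passes task validation but fails in execution
    task = TaskSpec(task_type="stochastic_repeat", model=get_model("birth_death"),
                    name="bad", repeat_count=2, t_end=3.0, n_points=6)
    from simfarm import orchestrate

    orig = orchestrate.split_task

    def sabotage(t, **kw):
        bundle = orig(t, **kw)
        bundle.jobs[0].document["t_end"] = -1.0
        return bundle

    orchestrate.split_task = sabotage
    try:
        result = run_task(task, config)
    finally:
        orchestrate.split_task = orig
    assert result.state == "error"
    assert result.failure_report.phase == "post_execution"
    assert result.artifacts["failure_bundle"].exists()
    notes = (tmp_path / "notes.txt").read_text()
    assert notes.count("failed") == 1


def test_submit_files_only_backend(tmp_path, birth_death):
    config = GlobalConfig(balance=LoadBalanceConfig(t_target=0.2,
                                                    override_one_per_job=True),
                          backend=BackendConfig(backend="submit_files_only"),
                          work_dir=tmp_path / "w")
    task = TaskSpec(task_type="stochastic_repeat", model=birth_death,
                    name="files", repeat_count=3, t_end=2.0, n_points=6)
    result = run_task(task, config)
    for i in range(3):
        assert (result.task_dir / f"job_{i}.sub").exists()
        assert (result.task_dir / f"job_{i}.yaml").exists()
    text = (result.task_dir / "job_0.sub").read_text()
    assert text.rstrip().endswith("queue")


def test_activity_log_records_every_run(fast_config, birth_death):
    task = TaskSpec(task_type="stochastic_repeat", model=birth_death,
                    name="logged", repeat_count=2, t_end=2.0, n_points=6)
    run_task(task, fast_config)
    log = fast_config.resolved_log_path().read_text()
    assert "task logged" in log and "finished" in log
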