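"""Execution backend: submit files, lifecycle, concurrency, eviction."""

import sys

import pytest

from simfarm.backend import (
    BackendConfig,
    parse_submit_description,
    poll_states,
    run_bundle,
    write_submit_description,
)
from simfarm.fixtures import get_model
from simfarm.tasks import TaskSpec, split_repeats, split_scan


def small_bundle(n_repeats=4, per_job=1, seed=0):
    task = TaskSpec(task_type="stochastic_repeat", model=get_model("birth_death"),
                    name="t", repeat_count=n_repeats, t_end=2.0, n_points=6,
                    base_seed=seed)
    return split_repeats(task, per_job)


def test_submit_description_format(tmp_path):
    bundle = small_bundle(1)
    job = bundle.jobs[0]
    (tmp_path / job.document_filename()).write_text(job.document_yaml())
    extra = [tmp_path / f"data{i}.txt" for i in range(2)]
    for p in extra:
        p.write_text("x")
    sub = write_submit_description(
        job, {"executable": sys.executable, "input_files": extra}, tmp_path)
    lines = sub.read_text().splitlines()
    assert lines[-1] == "queue"
    assert sum(1 for l in lines if l.startswith("queue")) == 1
    transfer = next(l for l in lines if l.startswith("transfer_input_files"))
    assert len(transfer.split("=", 1)[1].split(",")) == 3  # job doc + 2 extras


def test_submit_description_round_trip(tmp_path):
    bundle = small_bundle(1)
    job = bundle.jobs[0]
    (tmp_path / job.document_filename()).write_text(job.document_yaml())
    sub = write_submit_description(job, {"executable": sys.executable,
                                         "requirements": 'OpSys == "LINUX"'}, tmp_path)
    text = sub.read_text()
    assert parse_submit_description(text).to_text() == text


def test_submit_description_missing_input_file(tmp_path):
    bundle = small_bundle(1)
    job = bundle.jobs[0]
    (tmp_path / job.document_filename()).write_text(job.document_yaml())
    with pytest.raises(FileNotFoundError, match="nope.txt"):
        write_submit_description(
            job, {"executable": sys.executable,
                  "input_files": [tmp_path / "nope.txt"]}, tmp_path)


def test_all_jobs_succeed_with_outputs(tmp_path):
    bundle = run_bundle(small_bundle(4), BackendConfig(max_parallel=2), tmp_path)
    for job in bundle.jobs:
        assert job.state == "completed"
        assert job.exit_status == 0
        assert job.attempts == 1
        assert (tmp_path / job.output_filename).exists()
    assert poll_states(bundle).task_state == "finished"


def test_concurrency_never_exceeds_max_parallel(tmp_path):
    bundle = run_bundle(small_bundle(6), BackendConfig(max_parallel=2), tmp_path)
    assert bundle.run_stats["max_concurrent"] <= 2


def test_eviction_requeues_and_completes_on_second_attempt(tmp_path):
    config = BackendConfig(max_parallel=2, eviction_rate=[1.0])  # evict attempt 1 only
    bundle = run_bundle(small_bundle(3), config, tmp_path)
    for job in bundle.jobs:
        assert job.state == "completed"
        assert job.attempts == 2  # attempts = evictions + 1
        assert "evicted" in job.history and "completed" in job.history
        assert job.cpu_time is not None and job.cpu_time >= 0.0


def test_lifecycle_transitions_are_legal(tmp_path):
    legal = {("created", "idle"), ("idle", "running"), ("idle", "held"),
             ("running", "completed"), ("running", "evicted"),
             ("running", "failed"), ("evicted", "idle"), ("completed", "failed")}
    config = BackendConfig(max_parallel=2, eviction_rate=[0.6], seed=5)
    bundle = run_bundle(small_bundle(6), config, tmp_path)
    for job in bundle.jobs:
        states = ["created"] + job.history
        for a, b in zip(states, states[1:]):
            assert (a, b) in legal, f"illegal transition {a} -> {b}"


def test_malformed_document_is_held_and_never_executes(tmp_path):
    bundle = small_bundle(2)
    del bundle.jobs[0].document["model"]  # malformed: no model embedded
    bundle = run_bundle(bundle, BackendConfig(max_parallel=1), tmp_path)
    held, ok = bundle.jobs
    assert held.state == "held"
    assert held.attempts == 0
    assert "executing" not in (tmp_path / "job_0.log").read_text()
    assert ok.state == "completed"
    summary = poll_states(bundle)
    assert summary.task_state == "error"
    assert summary.held_jobs == [0]


def test_failed_job_marks_task_error(tmp_path):
    bundle = small_bundle(2)
    # reference an unknown model parameter so execution (not validation) fails
    bundle.jobs[1].document["t_end"] = -1.0
    bundle = run_bundle(bundle, BackendConfig(max_parallel=1), tmp_path)
    assert bundle.jobs[0].state == "completed"
    assert bundle.jobs[1].state == "failed"
    assert bundle.jobs[1].exit_status == 1
    summary = poll_states(bundle)
    assert summary.task_state == "error"
    assert summary.failed_jobs == [1]


def test_serial_parallel_equivalence(tmp_path):
    """Deterministic jobs produce byte-identical outputs at any parallelism."""
    task = TaskSpec(task_type="scan", model=get_model("decay"), name="s",
                    scan_parameters=["k"],
                    scan_grid=[[0.1 * (i + 1)] for i in range(12)],
                    t_end=1.0, n_points=5)
    outs = {}
    for label, max_parallel in (("serial", 1), ("parallel", 4)):
        d = tmp_path / label
        bundle = run_bundle(split_scan(task, 4), BackendConfig(max_parallel=max_parallel), d)
        outs[label] = [(d / j.output_filename).read_bytes() for j in bundle.jobs]
    assert outs["serial"] == outs["parallel"]
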