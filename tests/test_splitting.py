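"""Task splitting: job-count identities and partition exactness."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simfarm.fixtures import get_model
from simfarm.tasks import (
    TaskSpec,
    TaskValidationError,
    materialize_scan_grid,
    split_algorithm_sweep,
    split_raw,
    split_repeats,
    split_scan,
    split_sensitivity,
)


def sensitivity_task(n_params):
    # a many-parameter variant of the oscillator box: original value ±50%
    model = get_model("oscillator_3var")
    params = {f"p{i}": 1.0 for i in range(n_params)}
    model.parameters.update(params)
    return TaskSpec(
        task_type="sensitivity", model=model, target_spec="X",
        sensitivity_parameters=[(f"p{i}", 0.5, 1.5) for i in range(n_params)],
    )


@pytest.mark.parametrize("n_params,n_jobs", [(30, 60), (10, 20), (27, 54), (1, 2)])
def test_sensitivity_job_count_is_twice_parameters(n_params, n_jobs):
    bundle = split_sensitivity(sensitivity_task(n_params))
    assert len(bundle.jobs) == n_jobs
    # ordering: (param 0 max, param 0 min, param 1 max, ...)
    assert bundle.jobs[0].document["direction"] == "maximize"
    assert bundle.jobs[1].document["direction"] == "minimize"
    assert bundle.jobs[0].document["focus_parameter"] == "p0"
    if n_params > 1:
        assert bundle.jobs[2].document["focus_parameter"] == "p1"


def test_sensitivity_empty_parameter_list_rejected():
    task = sensitivity_task(1)
    task.sensitivity_parameters = []
    with pytest.raises(TaskValidationError, match="non-empty"):
        split_sensitivity(task)


def repeat_task(n):
    return TaskSpec(task_type="stochastic_repeat", model=get_model("birth_death"),
                    repeat_count=n, t_end=5.0, n_points=11)


@pytest.mark.parametrize("repeat_count,per_job,expected", [
    (10, 3, [3, 3, 3, 1]),
    (7, 1, [1] * 7),
    (1500, 3, [3] * 500),
    (4, 10, [4]),
])
def test_repeat_packing(repeat_count, per_job, expected):
    bundle = split_repeats(repeat_task(repeat_count), per_job)
    assert [j.assigned_repeats for j in bundle.jobs] == expected
    assert sum(j.assigned_repeats for j in bundle.jobs) == repeat_count


def test_repeat_offsets_partition_the_ensemble():
    bundle = split_repeats(repeat_task(10), 3)
    covered = []
    for job in bundle.jobs:
        off = job.document["repeat_offset"]
        covered += list(range(off, off + job.document["repeats"]))
    assert covered == list(range(10))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(n=st.integers(1, 500), r=st.integers(1, 50))
def test_repeat_split_identity(n, r):
    bundle = split_repeats(repeat_task(n), r)
    sizes = [j.assigned_repeats for j in bundle.jobs]
    assert len(sizes) == -(-n // r)
    assert sum(sizes) == n
    assert all(s == r for s in sizes[:-1])
    assert [j.job_index for j in bundle.jobs] == list(range(len(sizes)))
    assert [j.seed for j in bundle.jobs] == [i for i in range(len(sizes))]


def scan_task(grid):
    return TaskSpec(task_type="scan", model=get_model("decay"),
                    scan_parameters=["k"], scan_grid=grid, t_end=1.0, n_points=5)


@pytest.mark.parametrize("n_points,chunks,sizes", [
    (100, 4, [25, 25, 25, 25]),
    (10, 3, [4, 3, 3]),
    (5, 5, [1] * 5),
])
def test_scan_chunk_sizes_balanced_larger_first(n_points, chunks, sizes):
    grid = [[0.1 * (i + 1)] for i in range(n_points)]
    bundle = split_scan(scan_task(grid), chunks)
    assert [b - a for a, b in (j.assigned_subrange for j in bundle.jobs)] == sizes


def test_scan_chunks_reconstruct_grid_exactly():
    grid = [[0.01 * (i + 1)] for i in range(37)]
    bundle = split_scan(scan_task(grid), 5)
    concatenated = []
    for job in bundle.jobs:
        concatenated += job.document["points"]
    assert concatenated == [list(map(float, p)) for p in grid]


def test_scan_chunk_count_clamped_to_grid():
    grid = [[0.5], [1.0]]
    bundle = split_scan(scan_task(grid), 10)
    assert len(bundle.jobs) == 2


def test_random_scan_grid_materializes_deterministically():
    task = scan_task({"type": "random", "bounds": [[0.1, 1.0]], "n": 8})
    task.base_seed = 7
    a = materialize_scan_grid(task)
    b = materialize_scan_grid(task)
    assert a == b
    assert len(a) == 8
    assert all(0.1 <= p[0] <= 1.0 for p in a)


def sweep_task(algorithms):
    return TaskSpec(task_type="algorithm_sweep", model=get_model("decay"),
                    target_spec="A", algorithms=algorithms,
                    optimization_parameters=[("k", 0.1, 2.0)])


def test_algorithm_sweep_one_job_per_entry():
    algos = [("particle_swarm", {"swarm_size": 5}), ("local_search", {}),
             ("particle_swarm", {"swarm_size": 9})]
    bundle = split_algorithm_sweep(sweep_task(algos))
    assert len(bundle.jobs) == 3
    for i, (name, settings_) in enumerate(algos):
        assert bundle.jobs[i].document["algorithm"] == name
        assert bundle.jobs[i].document["settings"] == settings_


def test_algorithm_sweep_rejects_duplicates_and_empty():
    with pytest.raises(TaskValidationError, match="duplicate"):
        split_algorithm_sweep(sweep_task([("local_search", {}), ("local_search", {})]))
    with pytest.raises(TaskValidationError, match="non-empty"):
        split_algorithm_sweep(sweep_task([]))


def test_raw_split_substitutes_tokens():
    task = TaskSpec(task_type="raw", repeat_count=5,
                    raw_args="--seed {job} -o {out}")
    bundle = split_raw(task)
    assert len(bundle.jobs) == 5
    assert bundle.jobs[2].document["arguments"] == "--seed 2 -o job_2.out"
    single = split_raw(TaskSpec(task_type="raw", repeat_count=1, raw_args="-o {out}"))
    assert len(single.jobs) == 1


def test_raw_template_requires_output_token():
    with pytest.raises(TaskValidationError, match=r"\{out\}"):
        split_raw(TaskSpec(task_type="raw", repeat_count=2, raw_args="--seed {job}"))


def test_splitting_is_deterministic():
    task = repeat_task(10)
    a = split_repeats(task, 3)
    b = split_repeats(task, 3)
    assert [j.document for j in a.jobs] == [j.document for j in b.jobs]
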