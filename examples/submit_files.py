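"""Deployment path: instead of running locally, write one standard
submit-description file per job, ready for a real scheduler queue."""

from pathlib import Path

from simfarm import GlobalConfig, TaskSpec, run_task
from simfarm.backend import BackendConfig, parse_submit_description
from simfarm.balance import LoadBalanceConfig
from simfarm.fixtures import get_model

config = GlobalConfig(
    balance=LoadBalanceConfig(t_target=900.0, override_one_per_job=True),
    backend=BackendConfig(backend="submit_files_only"),
    work_dir=Path("scratch/example_submit"),
)
task = TaskSpec(
    task_type="stochastic_repeat",
    model=get_model("birth_death"),
    name="to_pool",
    repeat_count=3,
    t_end=10.0,
    n_points=11,
)

result = run_task(task, config)
sub = result.task_dir / "job_0.sub"
print("submit description for job 0:")
print(sub.read_text())
desc = parse_submit_description(sub.read_text())
print(f"parsed back: executable={Path(desc.executable).name}, "
      f"{len(desc.input_files)} input file(s), queue x{desc.queue_count}")
print("\nEach job ships its self-contained job document (model + task fragment")
print("+ seed), so any pool node can run it with no shared state.")
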