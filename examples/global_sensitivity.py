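"""Optimization-based global sensitivity analysis: for each model parameter,
one bounded maximization and one bounded minimization of the target's scaled
sensitivity coefficient — two parallel jobs per parameter."""

from pathlib import Path

from simfarm import GlobalConfig, TaskSpec, run_task
from simfarm.backend import BackendConfig
from simfarm.balance import LoadBalanceConfig
from simfarm.fixtures import get_model

config = GlobalConfig(
    balance=LoadBalanceConfig(t_target=0.2),
    backend=BackendConfig(max_parallel=2),
    work_dir=Path("scratch/example_sensitivity"),
)
task = TaskSpec(
    task_type="sensitivity",
    model=get_model("birth_death"),
    name="sens",
    target_spec="A",
    target_mode="steady_state",  # steady state of A is k/d
    sensitivity_parameters=[("k", 8.0, 12.0), ("d", 0.8, 1.2)],  # original ±20%
    algorithm="local_search",
)

result = run_task(task, config)
print(f"{len(task.sensitivity_parameters)} parameters -> "
      f"{len(result.bundle.jobs)} parallel jobs (one max + one min each)")
print("\nsensitivity report:")
for line in result.artifacts["sensitivity_report"].read_text().splitlines():
    print(" ", line)
print("\nBecause the steady state is exactly k/d, the scaled sensitivity of A")
print("is +1 to k and −1 to d everywhere in the box: max = min for both, so")
print("each parameter's importance (max − min) is 0 — the target responds")
print("proportionally, with no parameter-set dependence.")
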