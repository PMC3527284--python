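"""Parameter estimation with repeated stochastic restarts: fit a rate
constant to a synthetic noisy dataset with many particle-swarm runs split
across jobs, then keep the best solution."""

from pathlib import Path

from simfarm import GlobalConfig, TaskSpec, run_task
from simfarm.backend import BackendConfig
from simfarm.balance import LoadBalanceConfig
from simfarm.fixtures import get_model, make_estimation_dataset

import yaml

dataset_tsv, truth = make_estimation_dataset("dimerization", noise_sd=0.01,
                                             n_points=21, seed=4)
config = GlobalConfig(
    balance=LoadBalanceConfig(t_target=2.0),
    backend=BackendConfig(max_parallel=2),
    work_dir=Path("scratch/example_fit"),
)
task = TaskSpec(
    task_type="parameter_estimation_repeat",
    model=get_model("dimerization"),  # 2A -> B with unknown rate k
    name="fit",
    repeat_count=10,
    optimization_parameters=[("k", 1e-4, 0.1)],
    dataset_tsv=dataset_tsv,
    algorithm="particle_swarm",
    algorithm_settings={"swarm_size": 10, "iterations": 30},
    base_seed=4,
)

result = run_task(task, config)
best = yaml.safe_load(result.artifacts["best_result"].read_text())
k_hat = best["best_parameters"]["k"]
print(f"{task.repeat_count} restarts ran as {len(result.bundle.jobs)} job(s)")
print(f"true k      = {truth['k']}")
print(f"recovered k = {k_hat:.6f}  "
      f"({100 * abs(k_hat - truth['k']) / truth['k']:.3f}% relative error)")
print(f"best SSR    = {best['best_value']:.6g}")
print("\nThe best-of-restarts fit recovers the generator's rate constant; the")
print("updated model document with k substituted is at", result.artifacts["best_model"])
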