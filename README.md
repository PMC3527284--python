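# simfarm

Split biochemical-model simulation and analysis tasks into independent,
load-balanced parallel jobs; run them on a local pool that emulates a
Condor-style batch scheduler (or write standard submit-description files for
a real one); and collate the per-job outputs into exactly the artifacts a
serial run would have produced.

Many common systems-biology computations are embarrassingly parallel:
repeated Gillespie stochastic simulations, parameter scans, repeated
stochastic optimizations and parameter estimations, and optimization-based
global sensitivity analysis. The work of parallelizing them is not in the
simulations but in the orchestration — deciding how many repeats to put in
each job, writing a self-contained job description per job, tracking the
batch-queue lifecycle (idle, running, held, evicted), diagnosing failures
from log files, and merging per-job outputs without changing the answer.
`simfarm` packages that orchestration for people who run such workloads and
want the splitting/balancing/collation logic to be testable and exact.

## What it computes

**Task splitting.** Seven task types map onto job bundles with simple
arithmetic: a global sensitivity analysis over *P* parameters becomes 2·*P*
jobs (one bounded maximization and one bounded minimization of the target's
scaled sensitivity coefficient (pᵢ/T)·∂T/∂pᵢ per parameter); *n* repeats at
*r* repeats per job become ⌈n/r⌉ jobs; a scan grid splits into contiguous,
non-overlapping chunks whose sizes differ by at most one; an algorithm sweep
becomes one job per (algorithm, settings); raw mode substitutes `{job}` and
`{out}` tokens into a user template, one repeat per job.

**Load balancing.** Given a target per-job runtime *t* (default 900 s, set
by the administrator), the balancer times one repeat (wall clock, abandoned
and flagged if it exceeds the benchmark budget) and assigns
⌊t / t_single⌋ repeats per job, never fewer than one; a repeat slower than
*t*, or the one-per-job override, forces a single repeat per job. Flooring
keeps each job's predicted runtime at or below *t*, which bounds the work
lost when a job is evicted from an opportunistic node.

**Execution.** The `local_pool` backend runs jobs on a bounded worker pool
with the batch-queue lifecycle (created → idle → running →
completed/failed/evicted; held for malformed submissions that never start).
Evicted jobs are re-queued and restart from scratch — there is no
checkpointing — and every attempt's CPU time is accounted. The
`submit_files_only` backend writes one standard `key = value … queue`
submit-description file per job for real deployment.

**Collation.** Stochastic jobs emit partial moments (n, Σx, Σx² per time
point per species), merged exactly into ensemble means and sample standard
deviations, so any chunking of the same repeats gives identical results.
Scan chunks concatenate byte-identically to the serial output. Optimization
tasks reduce by best-of selection (ties to the lowest job index), and the
winning parameters are substituted back into a model document.

**Accounting.** Every task appends a usage record (job count, CPU hours
summed over all attempts, wall-clock hours) and its speed-up factor,
defined as CPU time / wall-clock time.

The simulation engine underneath is intentionally small: mass-action
reaction networks (native structured-text documents or an SBML Level 3 core
subset), deterministic time courses via adaptive LSODA integration, exact
Gillespie direct-method realizations, steady states by long-time
integration, and two bounded optimizers (seed-deterministic global-best
particle swarm; deterministic bounded Nelder–Mead).

## A worked example

```sh
python examples/stochastic_ensemble.py
```

```
200 repeats ran as 1 parallel job(s) of up to 365 repeats each
speed-up factor (CPU/wall): 0.98

collated ensemble summary (head):
  Time	A_mean	A_sd
  0	0	0
  1	6.505	2.678778504
  2	8.65	3.081391711
  3	9.2	3.042413747
```

The task runs 200 Gillespie realizations of the immigration–death network
∅→A (rate k = 10), A→∅ (rate d·A, d = 1). The balancer measured one repeat,
found 365 of them fit in the 0.5 s per-job target, and therefore packed all
200 into a single job; on a desk machine with no queueing the speed-up
factor is ≈1, as it should be. The collated table gives the ensemble mean
and standard deviation of the particle number of A per time point: the mean
relaxes towards the stationary value k/d = 10, and since the stationary law
is Poisson(10), the SD approaches √10 ≈ 3.16.

The other examples each show one capability: `parameter_scan.py` (chunked
scan, serial-identical output), `global_sensitivity.py` (2 jobs per
parameter, max/min/importance report), `fit_repeats.py` (best-of-restarts
parameter recovery), `submit_files.py` (submit-description files for a real
pool).

There is also a thin CLI over the same library calls:

```sh
simfarm validate task.yaml
simfarm submit task.yaml --config config.yaml
simfarm status  work/<task>/
simfarm results work/<task>/
simfarm stats   --work-dir work/
```

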