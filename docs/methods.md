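# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `simfarm`, in the order a task flows through the system.

## Reaction networks and simulation

A model is a set of species with non-negative initial amounts (particle
numbers), mass-action reactions whose rate constants are named parameters,
and a compartment volume V (default 1, arbitrary units). Kinetics are
restricted to mass action on purpose: the package's subject is the
orchestration around the simulations, and mass action is enough to exercise
every path (linear and nonlinear, open and closed, oscillating) while
keeping the engine small and exactly testable. Arbitrary rate-law parsing
is out of scope.

Deterministic time courses integrate d n/dt assembled from the
stoichiometry, with reaction flux k·Πₛ nₛ^mₛ / V^(order−1), using LSODA
(adaptive step, rtol 1e−8, atol 1e−10) on a uniform output grid starting at
t = 0. A non-finite state aborts with the first bad time point named.

Stochastic realizations use the exact Gillespie direct method. Propensities
count distinct reactant combinations: k·Πₛ C(nₛ, mₛ) / V^(order−1), i.e.
n(n−1)/2 for an order-2 self-reaction; for first-order networks this
coincides with the deterministic rate, so SSA ensemble means converge to
the ODE solution (a property the tests check at 3 standard errors). Output
follows the standard reporting convention for jump processes:
piecewise-constant left interpolation onto the same uniform grid, which is
what makes per-repeat grids align across jobs for exact collation. A
trajectory is a pure function of (model, t_end, n_points, seed).

Steady states are found by long-time integration with a doubling horizon
until ‖dn/dt‖ < 1e−9 (iteration-capped), not by Newton's method —
simplicity wins at fixture scale, at the cost of failing (explicitly) on
systems with no attracting steady state.

Target quantities are arithmetic expressions over species amounts and
parameters, evaluated at the final time or at steady state in a restricted
namespace (no builtins beyond abs/min/max/exp/log/sqrt).

## Optimizers

Two bounded-box optimizers are shipped deliberately — one stochastic, one
deterministic — because the orchestration patterns (repeat-and-select-best,
one-job-per-algorithm) are what matter, not algorithm variety.

* `particle_swarm`: global-best PSO with the constriction-standard
  coefficients (inertia 0.729, cognitive = social = 1.494), positions
  clamped to the box, fully determined by its seed.
* `local_search`: scipy's Nelder–Mead started from the box center, wrapped
  so every probed point is clamped into the box; deterministic, seed
  ignored.

Maximization negates the objective. A shared wrapper counts evaluations and
records the monotone best-so-far trace, exportable as two-column TSV for
progress charts. Iteration caps and swarm sizes are configuration, not
inference; defaults (swarm 20, 100 iterations; Nelder–Mead maxiter 400,
xatol/fatol 1e−8) suit the small fixture problems.

## Task splitting

Job-count identities: sensitivity → 2·P jobs ordered (param 0 max, param 0
min, param 1 max, …); repeats → ⌈n/r⌉ with all jobs full except the last
(the remainder job is placed last for predictability); scan → contiguous
half-open index chunks with sizes differing by at most 1, larger chunks
first, clamped (with a logged warning) if more chunks than grid points are
requested; algorithm sweep → one job per entry, duplicates rejected; raw →
one job per repeat with `{job}`/`{out}` substituted, the output token
mandatory. Random scan grids are materialized once, seeded from the task's
base seed, before splitting, so every chunk embeds concrete values.

Each job document is self-contained structured text (the serialized model,
the task fragment, the seed, the output filename `job_<index>.out`), so a
job can run on any node with no shared state.

The sensitivity objective follows the optimization-based global-sensitivity
approach: for parameter i, maximize and minimize the scaled sensitivity
coefficient (pᵢ/T)·∂T/∂pᵢ over the full parameter box, the derivative
estimated by central differences with relative step 1e−3 (falling back to
the unscaled derivative where T = 0, where the scaling is undefined). A
parameter's importance is then max − min; this range definition is this
package's documented convention.

### Seeding

`Job.seed = base_seed + job_index` identifies each job and drives per-job
randomness (sensitivity and algorithm-sweep optimizations). Repeats,
however, are seeded by global repeat index — `SeedSequence((base_seed,
repeat_index))`, reduced to 31 bits — *not* by job. This is a deliberate
design choice: it makes the simulated ensemble a function of the task
alone, so any chunking of the same repeats collates to identical results
and the whole task is replayable after re-balancing. Seeding repeats from
the job seed would tie results to the (timing-dependent) split.

## Load balancing

`t_target` (seconds, default 900) is the administrator-set ideal per-job
runtime, trading per-job submission/transfer overhead against lost
parallelism; it should be tuned per installation. The benchmark times one
repeat by wall clock — the quantity the trade-off is actually about — and
abandons it past `benchmark_cap` (default `t_target`), returning the cap
flagged as timed out. Packing uses ⌊t/t_single⌋, never below 1: flooring
(not rounding) keeps predicted job time ≤ t, bounding eviction losses.
Timed-out benchmarks, single repeats slower than t, and the explicit
override all force one repeat per job. The benchmark repeat is a pure
measurement and is never counted toward the task's repeats.

## Execution backend

The local pool emulates the batch-queue lifecycle on a bounded thread pool:
created → idle → running → {completed, evicted, failed}, evicted → idle
(requeue), idle → held for documents that fail pre-start validation — held
is the terminal state of a pre-execution failure and such jobs never
execute. Per-job Condor-style event logs (submit/execute/evict/terminate
records with exit status) are what the failure classifier parses. Exit
status is 0 on success, non-zero when the work raises; completed jobs with
non-zero status are marked failed at poll time.

Eviction is injected probabilistically per attempt for testing (a float
rate, or a per-attempt schedule such as `[1.0]` = always evict the first
attempt, never later — a stationary rate of 1 would never terminate and is
rejected). An evicted attempt's output is discarded but its CPU time is
kept, matching the no-checkpointing restart-from-scratch model. Per-attempt
CPU time is measured with the per-thread CPU clock; wall clock with a
monotonic timer. The poll interval of a real deployment is configuration;
the local pool polls as futures complete.

Serial/parallel equivalence holds by construction for deterministic job
documents: each job writes only its own files, so the output set is
independent of `max_parallel` (asserted byte-wise in the tests).

## Collation

Stochastic jobs ship partial moments (n, Σx, Σx² per time point per
species) rather than raw repeats: transfer size is bounded for
million-repeat tasks while the merge stays exact. Pooled mean = Σx/Σn;
pooled SD uses the sample divisor n−1 by default (population divisor n
available via configuration, `sd_divisor`); a single repeat reports SD = 0.
Variance is computed from pooled sums as (Σx² − n·mean²)/(n−1) with a clamp
at 0 against negative rounding residue. Raw per-repeat output can still be
produced by splitting one repeat per job.

Scan concatenation requires identical chunk headers and streams data rows
in job order — byte-identical to the serial file because workers format
values identically (`%.10g`). Best-of selection breaks ties by lowest job
index. `best_algorithms` returns every algorithm within a tolerance
(default 0, exact ties) of the extremal value.

## Accounting

CPU hours sum every attempt of every job (eviction reruns are real cost);
wall clock runs from submission to end and includes any queueing. The
speed-up factor is CPU hours / wall-clock hours; the identity
speedup·wall = cpu holds exactly. Records append to a flat TSV store from
which summary statistics are recomputed on demand — a relational store
would only serve multi-user features that are out of scope.

## Fixtures and the synthetic dataset generator

The catalog holds five small networks with oracled behaviour: first-order
decay (closed form), immigration–death (Poisson(k/d) stationary law, k/d =
10 by default), reversible isomerization (conservation), irreversible
dimerization (order-2 combinatorics), and a 3-species Lotka-type
predator–prey oscillator standing in for oscillating signalling models.
They are structurally analogous toys, not reproductions of published
biology: the claims under test (splitting arithmetic, balancing rules,
collation exactness) do not depend on model identity, and passing tests on
these fixtures therefore says nothing about any particular published
model's dynamics.

`make_estimation_dataset` simulates a fixture deterministically and adds
i.i.d. Gaussian noise of the stated SD (default study condition for the
recovery check: dimerization, noise SD 0.01 on amounts of order 10–100, 21
time points), returning the TSV and the true parameters. It emulates a
clean, uniformly-sampled, fully-observed time course; real data with
missing species, irregular sampling or structured noise is beyond what the
recovery test demonstrates.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
properties are sharp while the whole suite stays fast: 1,000 repeats for
the chunking-invisibility check (exactness is size-independent), 2,000
seeds for the stationary-moment check (SE ≈ 0.07 on a mean of 10), a
100-point scan in 4 chunks, and 20 estimation restarts with a 10-particle,
30-iteration swarm on a 1-D fit. Cluster-scale figures (hundreds of jobs,
speed-ups ≫ 1) depend on a real pool and are represented by the arithmetic
identities and the speed-up definition instead.

## Known limitations

No hybrid deterministic/stochastic solvers, events, assignments or delays;
no arbitrary kinetic laws; no ClassAd evaluation, priorities or
checkpointing in the backend; no real scheduler submission (submit files
are written and parsed, not queued); notification is a pluggable sink (log,
file, callback), not an e-mail transport. The thread-based local pool
shares the GIL, so CPU-bound jobs gain little wall-clock from
`max_parallel` > 1 — it is a lifecycle emulator and correctness harness,
not a performance backend.
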