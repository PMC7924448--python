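# Methods

This note documents the models implemented by `spectaskflow`, the design
choices made where the design was genuinely open, and what the test suite
does and does not demonstrate.

## Sequential task flow and dependency inference

Tasks are inserted by a single thread with an access list of
`(DataHandle, AccessMode)` pairs. Dependency inference is the classic
epoch scheme: each handle tracks its last writer and the readers since that
write. A `READ` depends on the last writer; a `WRITE` (and, conservatively,
a `MAYBE_WRITE`) depends on the last writer and on every reader of the
current epoch, then starts a new epoch. Readers within an epoch are
mutually unordered. Duplicate edges are collapsed; insertion order is by
construction a topological order, which every engine exploits.

Payloads obey a value-semantics contract: deep-copyable, comparable, and
mutated in place by task bodies (`Box` wraps immutable scalars). Copy tasks
deep-copy payloads; select tasks deep-copy the duplicate back over the
original. This contract is what makes "bitwise equal to the sequential
execution" a testable statement.

## Speculation construction

Uncertain tasks (at least one `MAYBE_WRITE`; body returns a did-write flag)
drive the construction:

* **Fresh chain.** If none of the task's data has a live duplicate — or
  all related groups are already dead — the task runs on the true data,
  copy tasks snapshot its maybe-written data, and a parentless group
  starts. The snapshots are what later tasks speculate over.
* **Chained insertion.** Otherwise the task is inserted twice: the
  original on the true data (behind its predecessors) and a speculative
  twin on the registered duplicates. For each maybe-written datum a
  *second-level* snapshot of the working duplicate is taken before the twin
  can write it and becomes the new registry entry, so the *next* level
  speculates over this task without waiting for it: that is why the degree
  of parallelism grows with the length of an uncertain chain. One select
  per written datum commits the duplicate on success. Data the twin only
  reads and that has no duplicate is shared with the original.
* **Certain tasks on duplicated data** get the same twin/select treatment
  (with fresh duplicates for written data not yet duplicated) and then
  *drop* every registry entry they touched: a certain task terminates the
  speculation chain, so a deliberately inserted normal task restarts the
  speculation process — this is the `spec_depth` mechanism of the MC flow.

Design choice — **registry entries always hold a pre-write snapshot**. If
the registry pointed at the duplicate the twin writes, every downstream twin
reading that datum would serialize behind the writing twin and chains would
lose their concurrency. The snapshot equals the written duplicate exactly
when the chain is valid (no upstream write), so correctness is unaffected.

Design choice — **optimistic activation defaults**. Originals that have
twins start disabled; twins, copies and selects start enabled. Group
failure (an uncertain task wrote, or a policy declined speculation) flips
them: originals on, twins/copies/selects off, recursively through successor
groups. The dependency structure guarantees every decision lands in time:
an original is always gated behind the previous level's select, which
depends on the twin whose did-write outcome decides that level. Twin
cancellation is best-effort only — a twin already running completes and its
(duplicate-only) output is simply never selected.

Groups are linked by parent/successor references with a pending-parent
counter rather than by list merging; failure and success propagate along
the links. The speculation decision is a pluggable policy evaluated when
the first runtime-created task of a group becomes ready (always-enabled by
default; always-disabled and a ready-vs-workers threshold are provided).

## Execution engines

* **Sequential**: insertion order on one worker; the ground-truth oracle.
* **Parallel**: real worker threads consuming a FIFO ready queue (ordered
  by insertion index); completion callbacks run under the runtime lock.
  This engine exercises the genuine cancellation races.
* **Simulated**: deterministic discrete-event list scheduling in abstract
  time units — greedy, earliest-free worker, ties by insertion index. At
  any timestamp all end events are processed before new starts, so a
  cancellation arriving at time T stops a task that would start at T (it
  then contributes zero duration) but not one started earlier. Bodies
  execute at task start, which respects dependency order because a
  successor's start is never processed before its predecessors' ends.

Copies and selects default to zero duration, user tasks to one unit,
matching the unit-cost theory with negligible copies/selects. Greedy list
scheduling is not anomaly-free in general (more workers can in principle
lengthen a schedule); the monotonicity of makespan in worker count is
therefore asserted only on the structured families used in the tests, not
claimed universally.

## Speedup theory

`predictive_gain` evaluates `D_N = Σ t·i·P_{i+1}·Π_{j≤i}(1−P_j)` with
`P_{N+1}=1`; `eager_gain` evaluates `F(N) = t·Σ(1−P_i)` (identical to the
recursion `F(N)=F(N−1)+t(1−P_N)`). For uniform `P=1/2` the eager speedup
is `2(N+1)/(N+2)`, which reaches 2 only in the limit of long chains; the
implementation follows the formula and treats 2 as that limit. The
Monte-Carlo estimator draws outcome vectors and averages the realized gain
(`i·t` when the first writer is task `i+1`, `N·t` when none writes); the
simulated executor reproduces exactly this realized gain outcome-by-outcome
on forced-mask chains, tying the theory to the runtime. Reference-table
comparisons round to the displayed precision; the two cells that are exact
binary ties (0.3125, 0.9375) follow round-half-to-even, which is how such
tables display them.

## Monte Carlo application

The system is `D` domains of `P` particles in a cubic box; the energy is
the pairwise Lennard-Jones potential in reduced units (ε = σ = k_B = 1),
with no cutoff and no periodic images — the box only bounds proposals.
The energy lives in a symmetric `D×D` matrix (diagonal = intra-domain), so
moving one domain touches one row/column: `update_energy` costs
`O(P·(D−1)·P)` instead of `O((DP)²)`, and the matrix is exactly the
maybe-written datum of each step task. Incremental updates keep the
orientation of the full computation so a null move is bit-identical.

A move redistributes a domain's particles uniformly in the box; acceptance
is `min(1, exp(−ΔE/T))` on the total energy. Draw order is fixed: move
coordinates first, acceptance uniform last. **Every step (sweep, domain)
owns a private RNG stream** spawned from the master seed via
`SeedSequence`; the stream is registered as data of the step's task. A
single shared stream would be advanced by predecessors, so a speculative
twin (which copies data *before* the predecessor runs) would draw its
predecessor's numbers; per-step streams make the twin's draws identical to
the original's and the whole flow bitwise reproducible. The sequential
references (`run_mc`, `run_remc`) consume the same spawn tree through the
same `attempt_move` kernel, which is what the bitwise-equivalence tests
compare against.

`spec_depth` S makes every S-th step a certain task (so S=1 is the
unspeculated baseline and S=D restarts speculation once per sweep). REMC
runs one such chain per replica — independent until an exchange — and
inserts, every `exchange_period` sweeps, one certain task per neighbour
pair that swaps domains and energies in place when the Metropolis test on
the energy difference (at the lower-indexed replica's temperature) accepts;
pair parity alternates between phases. Exchange tasks of one phase share
one phase stream, which orders them exactly as the sequential loop draws.

Defaults mirror the reference experiment where stated: 5 domains × 2,000
particles, 5 replicas, exchange every 3 sweeps, speculation always enabled.
Where no value is stated, one realistic choice was fixed once: reduced
density 0.05 (box edge `(DP/ρ)^{1/3}`), temperature 2.0 reduced units, a
geometric temperature ladder with ratio 1.5, and 10 sweeps for interactive
runs. Acceptance and exchange rates are strongly regime-dependent
(density, temperature, move size), so no particular rate is asserted.

## What the synthetic programs do and do not show

The random-program generator builds task graphs over integer `Box` payloads
whose bodies (and did-write decisions) are deterministic functions of the
values they read. Passing the equivalence sweep therefore demonstrates
that the speculation algebra — duplication, twin substitution, select
commits, failure cascades, cancellation races — preserves sequential
semantics for arbitrary access patterns and outcomes. It does not say
anything about performance on real hardware, about workloads whose bodies
are nondeterministic or mutate data they did not declare, or about payload
types violating the value-semantics contract. The simulated-clock
makespans are a scheduling model (unit-cost tasks, free copies/selects),
not wall-clock predictions.

## Numerical and degenerate-input choices

Coincident particles raise an explicit error (the potential is singular)
with the offending pair's indices. Energy bookkeeping is validated against
full recomputation at 1e-9 relative on randomized systems; after full MC
trajectories a 1e-6 relative drift tolerance applies. `wait_remain` on the
threaded engine runs the graph to completion (which satisfies its
postcondition); the sequential and simulated engines stop early. Task
durations must be nonnegative; zero-duration tasks are legal and are used
for copies and selects.

## Known limitations

* Eager speculation (re-speculating inside a failed chain) is implemented
  only as theory; the runtime builds the predictive construction.
* `atomic_write` / commute access modes, dynamic dependency arrays and
  on-the-fly DAG modification are out of scope.
* Group failure is tracked at group granularity: one write fails the whole
  group even if some duplicates are still valid.
* The threaded engine targets correctness under concurrency, not
  throughput; Python-level locking serializes the scheduler.
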