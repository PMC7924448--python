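"""Metropolis Monte Carlo and replica-exchange MC over a speculative task flow.

The physical system is a set of *domains* (groups of particles) in a cubic
box; the energy is the pairwise Lennard-Jones potential ``4ε[(σ/r)¹² −
(σ/r)⁶]`` in reduced units (ε = σ = k_B = 1), kept as a symmetric
domain×domain matrix whose entry (i, j) sums all cross pairs between domains
i and j and whose diagonal holds intra-domain sums.  A proposed move
redistributes one domain's particles uniformly in the box; only that
domain's row/column of the matrix is recomputed, and the move is accepted
with the Metropolis probability ``min(1, exp(−ΔE/T))``.

Each MC *step* (one domain update of one sweep) is also available as a task:
it maybe-writes the energy matrix, the moved domain and its own RNG-state
datum, and reads all other domains.  Whether the step writes is exactly
whether the move is accepted, so chains of steps are chains of uncertain
tasks and the speculation machinery can execute them concurrently.  Every
``spec_depth``-th step is inserted as a certain task, restarting the
speculation process.

Randomness contract: every step owns its own RNG stream, spawned
deterministically from the master seed (`numpy` ``SeedSequence``).  The
stream is declared as data of the step's task, so the speculative twin draws
the identical numbers from a copied stream and speculative execution is
*bitwise* equal to the sequential reference for any worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .dag_core import AccessMode, DataHandle, Runtime, TaskHandle, UsageError, payload_equal
from . import executor as _executor


class EnergyError(ArithmeticError):
    """Coincident particles make the Lennard-Jones potential singular."""


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass
class MCConfig:
    """Monte-Carlo run description.

    Defaults mirror the reference experiment: five domains of 2,000
    particles each, speculation restarting once per sweep.  ``density`` is
    the reduced particle density fixing the box edge (``box`` overrides it).
    """

    num_domains: int = 5
    particles_per_domain: int = 2000
    temperature: float = 2.0
    num_loops: int = 10
    spec_depth: int = 5
    seed: int = 0
    density: float = 0.05
    box: Optional[float] = None

    def __post_init__(self):
        if self.num_domains < 1 or self.particles_per_domain < 1:
            raise UsageError("need at least one domain and one particle")
        if self.temperature <= 0:
            raise UsageError("temperature must be positive")
        if self.spec_depth < 1:
            raise UsageError("spec_depth must be >= 1")
        if self.box is None:
            n_total = self.num_domains * self.particles_per_domain
            self.box = float((n_total / self.density) ** (1.0 / 3.0))


@dataclass
class REMCConfig:
    """Replica-exchange (parallel-tempering) run description.

    ``temperatures`` defaults to a geometric ladder starting at
    ``base_temperature``; exchanges happen every ``exchange_period`` sweeps,
    alternating odd–even and even–odd neighbour pairs.
    """

    num_replicas: int = 5
    num_domains: int = 5
    particles_per_domain: int = 2000
    base_temperature: float = 2.0
    temperature_ratio: float = 1.5
    temperatures: Optional[tuple[float, ...]] = None
    num_loops: int = 9
    exchange_period: int = 3
    spec_depth: int = 5
    seed: int = 0
    density: float = 0.05
    box: Optional[float] = None

    def __post_init__(self):
        if self.num_replicas < 2:
            raise UsageError("replica exchange needs at least two replicas")
        if self.exchange_period < 1:
            raise UsageError("exchange_period must be >= 1")
        if self.temperatures is None:
            self.temperatures = tuple(
                self.base_temperature * self.temperature_ratio**k
                for k in range(self.num_replicas)
            )
        self.temperatures = tuple(float(t) for t in self.temperatures)
        if len(self.temperatures) != self.num_replicas:
            raise UsageError("need one temperature per replica")
        if any(t <= 0 for t in self.temperatures):
            raise UsageError("temperatures must be strictly positive")
        if self.box is None:
            n_total = self.num_domains * self.particles_per_domain
            self.box = float((n_total / self.density) ** (1.0 / 3.0))

    def replica_mc_config(self, r: int) -> MCConfig:
        return MCConfig(
            num_domains=self.num_domains,
            particles_per_domain=self.particles_per_domain,
            temperature=self.temperatures[r],
            num_loops=self.num_loops,
            spec_depth=self.spec_depth,
            seed=self.seed,
            density=self.density,
            box=self.box,
        )


# ---------------------------------------------------------------------------
# system state
# ---------------------------------------------------------------------------

@dataclass
class ParticleDomain:
    """One group of particles: P×3 coordinates in box units."""

    id: int
    positions: np.ndarray


@dataclass
class SystemState:
    domains: list[ParticleDomain]
    box: float
    energy: np.ndarray

    @property
    def positions(self) -> list[np.ndarray]:
        return [d.positions for d in self.domains]

    def total_energy(self) -> float:
        return total_energy(self.energy)

    def copy(self) -> "SystemState":
        return SystemState(
            [ParticleDomain(d.id, d.positions.copy()) for d in self.domains],
            self.box,
            self.energy.copy(),
        )


def states_equal(a: SystemState, b: SystemState) -> bool:
    """Bitwise equality of positions and energy matrices."""
    return (
        len(a.domains) == len(b.domains)
        and all(
            payload_equal(x.positions, y.positions)
            for x, y in zip(a.domains, b.domains)
        )
        and payload_equal(a.energy, b.energy)
    )


# ---------------------------------------------------------------------------
# energy kernels
# ---------------------------------------------------------------------------

def _lj_from_sq(r2: np.ndarray, where: str) -> float:
    if r2.size == 0:
        return 0.0
    if np.any(r2 == 0.0):
        idx = tuple(int(k) for k in np.argwhere(r2 == 0.0)[0])
        raise EnergyError(f"coincident particles in {where} at pair index {idx}")
    inv6 = 1.0 / (r2 * r2 * r2)
    return float(np.sum(4.0 * (inv6 * inv6 - inv6)))


def _positions_of(domain) -> np.ndarray:
    return domain.positions if isinstance(domain, ParticleDomain) else np.asarray(domain)


def pair_energy(a, b, i: int = -1, j: int = -1) -> float:
    """Summed Lennard-Jones energy over all cross pairs of two domains."""
    pa, pb = _positions_of(a), _positions_of(b)
    return _lj_from_sq(cdist(pa, pb, "sqeuclidean"), f"domains ({i},{j})")


def intra_energy(a, i: int = -1) -> float:
    """Summed Lennard-Jones energy over particle pairs within one domain."""
    pa = _positions_of(a)
    if len(pa) < 2:
        return 0.0
    return _lj_from_sq(pdist(pa, "sqeuclidean"), f"domain {i}")


def compute_energy(domains: Sequence, box: Optional[float] = None) -> np.ndarray:
    """Full O(P²) pairwise evaluation into the symmetric domain-pair matrix.

    Entry (i, j) is the summed cross energy of domains i and j; the diagonal
    holds intra-domain energies.  ``box`` is accepted for interface symmetry;
    interactions are open-boundary (no periodic images, no cutoff).
    """
    if len(domains) < 1:
        raise UsageError("need at least one domain")
    D = len(domains)
    mat = np.zeros((D, D))
    for i in range(D):
        mat[i, i] = intra_energy(domains[i], i)
        for j in range(i + 1, D):
            e = pair_energy(domains[i], domains[j], i, j)
            mat[i, j] = mat[j, i] = e
    return mat


def total_energy(matrix: np.ndarray) -> float:
    """Half-sum of off-diagonal entries plus the diagonal sum."""
    diag = float(np.trace(matrix))
    return diag + (float(matrix.sum()) - diag) / 2.0


def update_energy(
    energy: np.ndarray,
    new_positions: np.ndarray,
    index: int,
    domains: Sequence,
    box: Optional[float] = None,
) -> np.ndarray:
    """Energy matrix after moving one domain: only its row/column changes.

    Returns a new matrix; entries not involving ``index`` are untouched.
    """
    D = energy.shape[0]
    if not (0 <= index < D):
        raise UsageError(f"domain index {index} out of range (D={D})")
    out = energy.copy()
    out[index, index] = intra_energy(new_positions, index)
    for j in range(D):
        if j == index:
            continue
        # keep compute_energy's (i < j) orientation so the summation order —
        # and hence the float result — is reproduced exactly
        if j < index:
            e = pair_energy(domains[j], new_positions, j, index)
        else:
            e = pair_energy(new_positions, domains[j], index, j)
        out[index, j] = out[j, index] = e
    return out


# ---------------------------------------------------------------------------
# moves and acceptance
# ---------------------------------------------------------------------------

def move_domain(
    temperature: float,
    domain,
    rng_state: np.random.Generator,
    box: float,
) -> np.ndarray:
    """Propose new positions: uniform redistribution of the particles.

    The proposal ignores the temperature (it only enters the acceptance
    test); the argument is kept for interface symmetry with the acceptance
    step.  The original domain is left unmodified.
    """
    pos = _positions_of(domain)
    return rng_state.uniform(0.0, box, size=pos.shape)


def metropolis_probability(new_energy: float, old_energy: float, temperature: float) -> float:
    """min(1, exp(−(new−old)/T)) with k_B = 1."""
    if temperature <= 0:
        raise UsageError("temperature must be positive")
    delta = new_energy - old_energy
    if delta <= 0:
        return 1.0
    return float(np.exp(-delta / temperature))


def attempt_move(
    energy: np.ndarray,
    positions: Sequence[np.ndarray],
    index: int,
    rng: np.random.Generator,
    temperature: float,
    box: float,
    force_reject: bool = False,
) -> bool:
    """One MC step on domain ``index``; mutates ``energy`` and the domain in place.

    Draw order is fixed (move first, acceptance uniform last) so that the
    identical stream yields the identical step under any execution regime.
    ``force_reject`` still performs all computations and draws but never
    accepts (the all-reject reference mode).
    """
    new_pos = move_domain(temperature, positions[index], rng, box)
    candidate = update_energy(energy, new_pos, index, positions, box)
    u = rng.random()
    prob = metropolis_probability(total_energy(candidate), total_energy(energy), temperature)
    accept = (not force_reject) and (u <= prob)
    if accept:
        positions[index][...] = new_pos
        energy[...] = candidate
    return accept


# ---------------------------------------------------------------------------
# RNG stream layout
# ---------------------------------------------------------------------------

def mc_streams(seed: int, num_loops: int, num_domains: int):
    """Deterministic stream tree for one MC chain.

    Returns ``(init_gen, step_gens)`` where ``step_gens[(loop, domain)]`` is
    the private generator of that step.
    """
    children = np.random.SeedSequence(seed).spawn(1 + num_loops * num_domains)
    init_gen = np.random.default_rng(children[0])
    step_gens = {
        (l, d): np.random.default_rng(children[1 + l * num_domains + d])
        for l in range(num_loops)
        for d in range(num_domains)
    }
    return init_gen, step_gens


def remc_streams(seed: int, num_replicas: int, num_loops: int, num_domains: int, num_phases: int):
    """Stream tree for replica exchange: per-replica step streams plus one
    generator per exchange phase (drawn in pair order within the phase)."""
    top = np.random.SeedSequence(seed).spawn(num_replicas + 1)
    per_replica = []
    for r in range(num_replicas):
        children = top[r].spawn(1 + num_loops * num_domains)
        init_gen = np.random.default_rng(children[0])
        step_gens = {
            (l, d): np.random.default_rng(children[1 + l * num_domains + d])
            for l in range(num_loops)
            for d in range(num_domains)
        }
        per_replica.append((init_gen, step_gens))
    phase_gens = [
        np.random.default_rng(s) for s in top[num_replicas].spawn(max(num_phases, 1))
    ]
    return per_replica, phase_gens


def init_system(config: MCConfig, init_gen: Optional[np.random.Generator] = None) -> SystemState:
    """Random initial configuration: particles uniform in the box."""
    if init_gen is None:
        init_gen, _ = mc_streams(config.seed, config.num_loops, config.num_domains)
    domains = [
        ParticleDomain(
            d,
            init_gen.uniform(0.0, config.box, size=(config.particles_per_domain, 3)),
        )
        for d in range(config.num_domains)
    ]
    energy = compute_energy(domains, config.box)
    return SystemState(domains, config.box, energy)


# ---------------------------------------------------------------------------
# sequential reference algorithms
# ---------------------------------------------------------------------------

@dataclass
class MCStats:
    attempts: int = 0
    accepted: int = 0
    energy_trajectory: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def accept_ratio(self) -> float:
        return self.accepted / self.attempts if self.attempts else 0.0

    def to_dict(self) -> dict:
        return {
            "attempts": self.attempts,
            "accepted": self.accepted,
            "accept_ratio": self.accept_ratio,
            "energy_trajectory": self.energy_trajectory,
            "seed": self.seed,
        }


def run_mc(config: MCConfig, all_reject: bool = False) -> tuple[SystemState, MCStats]:
    """Sequential reference Metropolis MC (the ground truth for the task flow).

    Per sweep, per domain: propose, update the energy row, Metropolis test,
    accept or reject.  Fully reproducible from the seed.
    """
    init_gen, step_gens = mc_streams(config.seed, config.num_loops, config.num_domains)
    state = init_system(config, init_gen)
    stats = MCStats(seed=config.seed)
    positions = state.positions
    for l in range(config.num_loops):
        for d in range(config.num_domains):
            accepted = attempt_move(
                state.energy,
                positions,
                d,
                step_gens[(l, d)],
                config.temperature,
                config.box,
                force_reject=all_reject,
            )
            stats.attempts += 1
            stats.accepted += int(accepted)
        stats.energy_trajectory.append(state.total_energy())
    return state, stats


def exchange_list(iteration: int, num_replicas: int) -> list[tuple[int, int]]:
    """Neighbour pairs for one exchange phase (0-based replica indices).

    Odd iterations pair odd–even replicas ((1,2), (3,4), … in 1-based
    numbering), even iterations pair even–odd ((2,3), (4,5), …).
    """
    start = 0 if iteration % 2 == 1 else 1
    return [(s, s + 1) for s in range(start, num_replicas - 1, 2)]


@dataclass
class REMCStats:
    mc: list[MCStats] = field(default_factory=list)
    exchange_attempts: dict = field(default_factory=dict)
    exchange_accepts: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def exchange_rate(self) -> float:
        att = sum(self.exchange_attempts.values())
        return sum(self.exchange_accepts.values()) / att if att else 0.0

    def to_dict(self) -> dict:
        return {
            "mc": [m.to_dict() for m in self.mc],
            "exchange_attempts": {str(k): v for k, v in self.exchange_attempts.items()},
            "exchange_accepts": {str(k): v for k, v in self.exchange_accepts.items()},
            "exchange_rate": self.exchange_rate,
            "seed": self.seed,
        }


def _exchange_decision(
    e_low: float, e_high: float, t_low: float, u: float
) -> bool:
    """Swap decision: Metropolis on the energy difference at the lower-indexed
    replica's temperature."""
    return u <= metropolis_probability(e_low, e_high, t_low)


def run_remc(config: REMCConfig, all_reject: bool = False) -> tuple[list[SystemState], REMCStats]:
    """Sequential reference replica-exchange MC.

    Each sweep advances every replica by one MC sweep; every
    ``exchange_period`` sweeps neighbouring replicas attempt to swap
    configurations and energies, alternating pair parity between phases.
    """
    R = config.num_replicas
    num_phases = config.num_loops // config.exchange_period
    per_replica, phase_gens = remc_streams(
        config.seed, R, config.num_loops, config.num_domains, num_phases
    )
    states = []
    stats = REMCStats(seed=config.seed, mc=[MCStats(seed=config.seed) for _ in range(R)])
    for r in range(R):
        init_gen, _ = per_replica[r]
        states.append(init_system(config.replica_mc_config(r), init_gen))
    for l in range(config.num_loops):
        for r in range(R):
            _, step_gens = per_replica[r]
            positions = states[r].positions
            for d in range(config.num_domains):
                accepted = attempt_move(
                    states[r].energy,
                    positions,
                    d,
                    step_gens[(l, d)],
                    config.temperatures[r],
                    config.box,
                    force_reject=all_reject,
                )
                stats.mc[r].attempts += 1
                stats.mc[r].accepted += int(accepted)
            stats.mc[r].energy_trajectory.append(states[r].total_energy())
        if (l + 1) % config.exchange_period == 0:
            phase = (l + 1) // config.exchange_period
            gen = phase_gens[phase - 1]
            for s, s1 in exchange_list(phase, R):
                u = gen.random()
                ok = _exchange_decision(
                    states[s].total_energy(),
                    states[s1].total_energy(),
                    config.temperatures[s],
                    u,
                )
                key = (s, s1)
                stats.exchange_attempts[key] = stats.exchange_attempts.get(key, 0) + 1
                if ok:
                    stats.exchange_accepts[key] = stats.exchange_accepts.get(key, 0) + 1
                    states[s], states[s1] = states[s1], states[s]
    return states, stats


# ---------------------------------------------------------------------------
# task-flow builds
# ---------------------------------------------------------------------------

def _step_body(index, other_ids, temperature, box, all_reject):
    def body(energy, dom, rng, *others):
        positions: list = [None] * (len(others) + 1)
        positions[index] = dom
        for j, arr in zip(other_ids, others):
            positions[j] = arr
        return attempt_move(
            energy, positions, index, rng, temperature, box, force_reject=all_reject
        )

    return body


def _insert_step_tasks(
    runtime: Runtime,
    energy_h: DataHandle,
    dom_hs: list[DataHandle],
    step_gens: dict,
    *,
    num_loops: int,
    spec_depth: int,
    temperature: float,
    box: float,
    all_reject: bool,
    step_offset: int = 0,
    tag: str = "",
) -> list[TaskHandle]:
    D = len(dom_hs)
    handles = []
    for l in range(num_loops):
        for d in range(D):
            step_index = step_offset + l * D + d
            certain = (step_index + 1) % spec_depth == 0
            rng_h = runtime.register_data(step_gens[(l, d)], name=f"rng{tag}[{l},{d}]")
            mode = AccessMode.WRITE if certain else AccessMode.MAYBE_WRITE
            other_ids = [j for j in range(D) if j != d]
            accesses = [(energy_h, mode), (dom_hs[d], mode), (rng_h, mode)]
            accesses += [(dom_hs[j], AccessMode.READ) for j in other_ids]
            handles.append(
                runtime.insert_task(
                    accesses,
                    _step_body(d, other_ids, temperature, box, all_reject),
                    uncertain=not certain,
                    duration=1.0,
                    name=f"mc{tag}[{l},{d}]" + ("!" if certain else ""),
                )
            )
    return handles


@dataclass
class MCTaskflow:
    """An MC simulation expressed as a speculative task flow."""

    config: MCConfig
    runtime: Runtime
    energy_handle: DataHandle
    domain_handles: list[DataHandle]
    step_handles: list[TaskHandle]
    all_reject: bool = False

    def final_state(self) -> SystemState:
        domains = [
            ParticleDomain(i, h.payload) for i, h in enumerate(self.domain_handles)
        ]
        return SystemState(domains, self.config.box, self.energy_handle.payload)

    def stats(self) -> MCStats:
        st = MCStats(seed=self.config.seed)
        for h in self.step_handles:
            st.attempts += 1
            st.accepted += int(bool(h.value))
        return st

    def run(self, executor: str = "parallel", num_workers: int = 1):
        """Execute the flow and return (final state, stats, trace)."""
        if executor == "sequential":
            trace = _executor.run_sequential(self.runtime)
        elif executor == "parallel":
            trace = _executor.run_parallel(self.runtime, num_workers)
        elif executor == "simulated":
            trace = _executor.run_simulated(self.runtime, num_workers)
        else:
            raise UsageError(f"unknown executor {executor!r}")
        return self.final_state(), self.stats(), trace


def build_mc_taskflow(
    config: MCConfig,
    runtime: Optional[Runtime] = None,
    all_reject: bool = False,
) -> MCTaskflow:
    """Build the task flow of Metropolis MC: one task per (sweep, domain).

    Each task maybe-writes the energy matrix, its domain and its private RNG
    stream, and reads every other domain; every ``spec_depth``-th step is a
    certain task that restarts speculation.  Executing the flow on any
    engine with any worker count reproduces :func:`run_mc` bit for bit.
    """
    runtime = runtime or Runtime()
    init_gen, step_gens = mc_streams(config.seed, config.num_loops, config.num_domains)
    state = init_system(config, init_gen)
    energy_h = runtime.register_data(state.energy, name="energy")
    dom_hs = [
        runtime.register_data(d.positions, name=f"dom{d.id}") for d in state.domains
    ]
    step_handles = _insert_step_tasks(
        runtime,
        energy_h,
        dom_hs,
        step_gens,
        num_loops=config.num_loops,
        spec_depth=config.spec_depth,
        temperature=config.temperature,
        box=config.box,
        all_reject=all_reject,
    )
    return MCTaskflow(config, runtime, energy_h, dom_hs, step_handles, all_reject)


def _exchange_body(pair, d_count, t_low):
    def body(e_low, e_high, rng, *doms):
        u = rng.random()
        if _exchange_decision(total_energy(e_low), total_energy(e_high), t_low, u):
            low, high = doms[:d_count], doms[d_count:]
            for a, b in zip(low, high):
                tmp = a.copy()
                a[...] = b
                b[...] = tmp
            tmp = e_low.copy()
            e_low[...] = e_high
            e_high[...] = tmp
            return True
        return False

    return body


@dataclass
class REMCTaskflow:
    """Replica-exchange MC as one big speculative task flow."""

    config: REMCConfig
    runtime: Runtime
    energy_handles: list[DataHandle]
    domain_handles: list[list[DataHandle]]
    step_handles: list[list[TaskHandle]]
    exchange_handles: list[tuple[tuple[int, int], int, TaskHandle]]  # (pair, phase, task)

    def final_states(self) -> list[SystemState]:
        return [
            SystemState(
                [ParticleDomain(i, h.payload) for i, h in enumerate(doms)],
                self.config.box,
                e.payload,
            )
            for e, doms in zip(self.energy_handles, self.domain_handles)
        ]

    def stats(self) -> REMCStats:
        st = REMCStats(
            seed=self.config.seed,
            mc=[MCStats(seed=self.config.seed) for _ in range(self.config.num_replicas)],
        )
        for r, handles in enumerate(self.step_handles):
            for h in handles:
                st.mc[r].attempts += 1
                st.mc[r].accepted += int(bool(h.value))
        for pair, _phase, h in self.exchange_handles:
            st.exchange_attempts[pair] = st.exchange_attempts.get(pair, 0) + 1
            if h.value:
                st.exchange_accepts[pair] = st.exchange_accepts.get(pair, 0) + 1
        return st

    def run(self, executor: str = "parallel", num_workers: int = 1):
        if executor == "sequential":
            trace = _executor.run_sequential(self.runtime)
        elif executor == "parallel":
            trace = _executor.run_parallel(self.runtime, num_workers)
        elif executor == "simulated":
            trace = _executor.run_simulated(self.runtime, num_workers)
        else:
            raise UsageError(f"unknown executor {executor!r}")
        return self.final_states(), self.stats(), trace


def build_remc_taskflow(
    config: REMCConfig,
    runtime: Optional[Runtime] = None,
    all_reject: bool = False,
) -> REMCTaskflow:
    """Build the replica-exchange task flow.

    Replica sweeps are independent uncertain-task chains (parallel across
    replicas); each exchange phase inserts one certain task per neighbour
    pair that swaps domain and energy payloads in place when the Metropolis
    test on the energy difference accepts.  The swap outcome of the
    sequential reference :func:`run_remc` is reproduced bit for bit.
    """
    runtime = runtime or Runtime()
    R = config.num_replicas
    num_phases = config.num_loops // config.exchange_period
    per_replica, phase_gens = remc_streams(
        config.seed, R, config.num_loops, config.num_domains, num_phases
    )
    energy_hs: list[DataHandle] = []
    dom_hs: list[list[DataHandle]] = []
    for r in range(R):
        init_gen, _ = per_replica[r]
        state = init_system(config.replica_mc_config(r), init_gen)
        energy_hs.append(runtime.register_data(state.energy, name=f"E[{r}]"))
        dom_hs.append(
            [
                runtime.register_data(d.positions, name=f"dom[{r},{d.id}]")
                for d in state.domains
            ]
        )
    step_handles: list[list[TaskHandle]] = [[] for _ in range(R)]
    exchange_handles = []
    phase_rng_handles: dict[int, DataHandle] = {}
    for l in range(config.num_loops):
        for r in range(R):
            _, step_gens = per_replica[r]
            gens = {(0, d): step_gens[(l, d)] for d in range(config.num_domains)}
            step_handles[r].extend(
                _insert_step_tasks(
                    runtime,
                    energy_hs[r],
                    dom_hs[r],
                    gens,
                    num_loops=1,
                    spec_depth=config.spec_depth,
                    temperature=config.temperatures[r],
                    box=config.box,
                    all_reject=all_reject,
                    step_offset=l * config.num_domains,
                    tag=f"r{r}",
                )
            )
        if (l + 1) % config.exchange_period == 0:
            phase = (l + 1) // config.exchange_period
            if phase not in phase_rng_handles:
                phase_rng_handles[phase] = runtime.register_data(
                    phase_gens[phase - 1], name=f"xrng[{phase}]"
                )
            for s, s1 in exchange_list(phase, R):
                accesses = [
                    (energy_hs[s], AccessMode.WRITE),
                    (energy_hs[s1], AccessMode.WRITE),
                    (phase_rng_handles[phase], AccessMode.WRITE),
                ]
                accesses += [(h, AccessMode.WRITE) for h in dom_hs[s]]
                accesses += [(h, AccessMode.WRITE) for h in dom_hs[s1]]
                th = runtime.insert_task(
                    accesses,
                    _exchange_body((s, s1), config.num_domains, config.temperatures[s]),
                    duration=0.0,
                    name=f"swap[{phase},{s}-{s1}]",
                )
                exchange_handles.append(((s, s1), phase, th))
    return REMCTaskflow(config, runtime, energy_hs, dom_hs, step_handles, exchange_handles)
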