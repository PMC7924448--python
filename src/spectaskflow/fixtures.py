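"""Reproducible fixtures: random task programs and canned graph topologies.

A *program* here is a builder function that can be applied to any
:class:`~spectaskflow.dag_core.Runtime` — speculative or plain — so the same
logical computation can be executed under different regimes and its final
payloads compared.  Bodies are deterministic functions of the payload values
they receive, and uncertain bodies decide their did-write flag from those
values too, which is what makes cross-executor bitwise comparison meaningful.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from .dag_core import AccessMode, Box, DataHandle, Runtime, TaskHandle


# ---------------------------------------------------------------------------
# deterministic task bodies
# ---------------------------------------------------------------------------

def _normal_body(coeffs: tuple[int, ...], n_written: int):
    """Write an affine combination of all inputs into each written payload."""

    def body(*payloads):
        vals = [p.value for p in payloads]
        acc = sum(c * v for c, v in zip(coeffs, vals)) % 1_000_003
        for p in payloads[:n_written]:
            p.value = (acc + p.value) % 1_000_003
        return acc

    return body


def _uncertain_body(coeffs: tuple[int, ...], n_written: int, write_mod: int):
    """Write iff the input combination hits a residue class; report the flag."""

    def body(*payloads):
        vals = [p.value for p in payloads]
        acc = sum(c * v for c, v in zip(coeffs, vals)) % 1_000_003
        if acc % write_mod == 0:
            for p in payloads[:n_written]:
                p.value = (acc + 7 * p.value) % 1_000_003
            return True
        return False

    return body


def _forced_body(writes: bool, delta: int = 13):
    """Uncertain body with a hard-wired outcome (for forced write masks)."""

    def body(*payloads):
        if writes:
            for p in payloads:
                p.value = p.value * 3 + delta
            return True
        return False

    return body


# ---------------------------------------------------------------------------
# random programs
# ---------------------------------------------------------------------------

def random_program(
    seed: int,
    n_tasks: int = 12,
    n_data: int = 4,
    uncertain_prob: float = 0.4,
    write_mod: int = 2,
) -> Callable[[Runtime], list[DataHandle]]:
    """Build a random STF program over ``n_data`` Box payloads.

    Returns a builder; applying it to a runtime inserts ``n_tasks`` tasks
    with random access lists (each task touches 1..3 data) and returns the
    data handles for payload comparison.  Roughly ``uncertain_prob`` of the
    tasks are uncertain; their write decision depends on the values they see,
    so different speculation regimes exercise both outcomes.
    """
    rng = np.random.default_rng(seed)
    plan = []
    for _ in range(n_tasks):
        k = int(rng.integers(1, min(3, n_data) + 1))
        idx = rng.choice(n_data, size=k, replace=False)
        uncertain = bool(rng.random() < uncertain_prob)
        if uncertain:
            n_written = int(rng.integers(1, k + 1))
            modes = [AccessMode.MAYBE_WRITE] * n_written + [AccessMode.READ] * (k - n_written)
        else:
            n_written = int(rng.integers(0, k + 1))
            modes = [AccessMode.WRITE] * n_written + [AccessMode.READ] * (k - n_written)
        coeffs = tuple(int(c) for c in rng.integers(1, 97, size=k))
        duration = float(rng.integers(1, 4))
        plan.append((list(map(int, idx)), modes, n_written, coeffs, uncertain, duration))

    def build(runtime: Runtime) -> list[DataHandle]:
        handles = [runtime.register_data(Box(17 * i + 3), name=f"x{i}") for i in range(n_data)]
        for idx, modes, n_written, coeffs, uncertain, duration in plan:
            accesses = [(handles[i], m) for i, m in zip(idx, modes)]
            if uncertain:
                body = _uncertain_body(coeffs, n_written, write_mod)
            else:
                body = _normal_body(coeffs, n_written)
            runtime.insert_task(accesses, body, uncertain=uncertain, duration=duration)
        return handles

    return build


# ---------------------------------------------------------------------------
# canned topologies from the worked examples
# ---------------------------------------------------------------------------

def four_task_chain_program(
    b_writes: bool,
    durations: Optional[dict] = None,
) -> Callable[[Runtime], tuple[DataHandle, list[TaskHandle]]]:
    """A(write x) → B(maybe-write x) → C(write x) → D(write x).

    The classic single-uncertain-task scenario: with speculation on, the
    runtime adds a copy in front of B, a speculative twin C' and a select,
    for 7 tasks in total.  ``durations`` maps ``{"A","B","C","D"}`` to
    abstract costs (A and D default to 0 so the two closed-form makespans
    ``copy + max(B+C, C')`` / ``copy + max(B, C') + select`` are exposed
    directly).
    """
    dur = {"A": 0.0, "B": 1.0, "C": 1.0, "D": 0.0}
    dur.update(durations or {})

    def build(runtime: Runtime):
        x = runtime.register_data(Box(1), name="x")

        def a_body(xv):
            xv.value = 5

        def c_body(xv):
            xv.value = xv.value * 2 + 1

        def d_body(xv):
            xv.value = xv.value + 100

        tasks = [
            runtime.insert_task([(x, AccessMode.WRITE)], a_body, duration=dur["A"], name="A"),
            runtime.insert_task(
                [(x, AccessMode.MAYBE_WRITE)],
                _forced_body(b_writes),
                uncertain=True,
                duration=dur["B"],
                name="B",
            ),
            runtime.insert_task([(x, AccessMode.WRITE)], c_body, duration=dur["C"], name="C"),
            runtime.insert_task([(x, AccessMode.WRITE)], d_body, duration=dur["D"], name="D"),
        ]
        return x, tasks

    return build


def uncertain_chain_program(
    write_mask: Sequence[bool],
    task_duration: float = 1.0,
) -> Callable[[Runtime], tuple[DataHandle, list[TaskHandle]]]:
    """N consecutive uncertain tasks on one datum, then a final certain task.

    ``write_mask[i]`` forces whether uncertain task ``i`` writes.  This is
    the graph family behind the predictive speedup theory: with enough
    workers and speculation on, the simulated makespan per realized mask
    equals ``(N + 1 - gain)`` task durations, where ``gain`` is the saved
    duration the theory assigns to that outcome.
    """
    write_mask = list(write_mask)

    def build(runtime: Runtime):
        x = runtime.register_data(Box(2), name="x")

        def final_body(xv):
            xv.value = xv.value * 5 + 1

        tasks = []
        for i, w in enumerate(write_mask):
            tasks.append(
                runtime.insert_task(
                    [(x, AccessMode.MAYBE_WRITE)],
                    _forced_body(bool(w), delta=11 + i),
                    uncertain=True,
                    duration=task_duration,
                    name=f"U{i}",
                )
            )
        tasks.append(
            runtime.insert_task(
                [(x, AccessMode.WRITE)], final_body, duration=task_duration, name="F"
            )
        )
        return x, tasks

    return build


def speculation_consumer_program(
    extra_mode: AccessMode,
) -> Callable[[Runtime], tuple[DataHandle, DataHandle]]:
    """B(maybe-write x); E(write y); C touching both x and y.

    When C *writes* y, the twin C' needs an extra copy of y plus an extra
    select; when C only *reads* y, both C and C' share y concurrently and no
    extra duplicate is created.
    """

    def build(runtime: Runtime):
        x = runtime.register_data(Box(1), name="x")
        y = runtime.register_data(Box(2), name="y")
        runtime.insert_task([(x, AccessMode.WRITE)], lambda b: b.__setattr__("value", 3), name="A")
        runtime.insert_task(
            [(x, AccessMode.MAYBE_WRITE)], _forced_body(False), uncertain=True, name="B"
        )
        runtime.insert_task([(y, AccessMode.WRITE)], lambda b: b.__setattr__("value", 9), name="E")
        if extra_mode is AccessMode.WRITE:
            def c_body(xv, yv):
                yv.value = yv.value + xv.value
                xv.value = xv.value * 2
        else:
            def c_body(xv, yv):
                xv.value = xv.value * 2 + yv.value
        runtime.insert_task(
            [(x, AccessMode.WRITE), (y, extra_mode)], c_body, name="C"
        )
        return x, y

    return build
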