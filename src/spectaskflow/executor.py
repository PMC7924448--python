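"""Execution engines: sequential reference, thread pool, simulated clock.

All three engines run the *same* graph with the same speculation semantics
and must leave every payload bitwise identical (value-semantics contract).
The sequential engine is the ground-truth oracle; the threaded engine
exercises the real best-effort-cancellation races; the simulated engine is a
deterministic discrete-event list scheduler producing hardware-independent
makespans in abstract time units.

Scheduling policy everywhere: greedy, earliest-free worker, FIFO ties broken
by task insertion index.  A task cancelled before it starts contributes zero
duration; one disabled after starting runs to completion ("too late").
"""

from __future__ import annotations

import heapq
import json
import threading
import time
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

from . import speculation as _spec
from .dag_core import (
    Activation,
    InternalError,
    Runtime,
    TaskNode,
    TaskState,
    UsageError,
)


@dataclass
class SimEvent:
    """One discrete event of the simulated clock (start or end of a task)."""

    time: float
    task: TaskNode
    kind: str  # "start" | "end"


@dataclass
class TraceRecord:
    task_id: int
    name: str
    role: str
    worker: int
    start: float
    end: float
    activation: str
    ran: bool
    group: Optional[int]

    def to_dict(self) -> dict:
        return {
            "task": self.task_id,
            "name": self.name,
            "role": self.role,
            "worker": self.worker,
            "start": self.start,
            "end": self.end,
            "activation": self.activation,
            "ran": self.ran,
            "group": self.group,
        }


@dataclass
class RunTrace:
    """Per-task execution records plus the resulting makespan."""

    records: list[TraceRecord] = field(default_factory=list)
    makespan: float = 0.0

    def to_json(self, **kw) -> str:
        return json.dumps(
            {"makespan": self.makespan, "records": [r.to_dict() for r in self.records]},
            **kw,
        )

    def record_for(self, node: TaskNode) -> TraceRecord:
        for r in self.records:
            if r.task_id == node.id:
                return r
        raise KeyError(node.id)


def _invoke(node: TaskNode) -> Any:
    """Run a task body: system tasks close over handles, user tasks get payloads."""
    if node.system:
        return node.body()
    return node.body(*[h.payload for h, _ in node.accesses])


def _finish(runtime: Runtime, node: TaskNode, ran: bool, result: Any) -> None:
    """Mark a task DONE and fire the speculation callbacks (under the lock)."""
    node.ran = ran
    node.result = result if ran else None
    node.state = TaskState.DONE
    if node.uncertain:
        if ran:
            _spec.on_uncertain_complete(runtime, node, result)
        else:
            node.did_write = False


def _record(trace, node, worker, start, end):
    trace.records.append(
        TraceRecord(
            node.id,
            node.name,
            node.role.value,
            worker,
            start,
            end,
            node.activation.value,
            node.ran,
            node.group.id if node.group is not None else None,
        )
    )
    trace.makespan = max(trace.makespan, end)


# ---------------------------------------------------------------------------
# sequential reference engine
# ---------------------------------------------------------------------------

def run_sequential(
    runtime: Runtime, until: Optional[Callable[[], bool]] = None
) -> RunTrace:
    """Execute enabled tasks in insertion order on a single worker.

    Insertion order is a topological order, so each task's predecessors are
    complete when it runs.  Uncertain-task results drive group activation
    exactly as in parallel runs; this is the ground-truth oracle for payload
    equivalence.
    """
    trace = RunTrace(makespan=runtime._seq_clock)
    clock = runtime._seq_clock
    for node in runtime.graph.nodes:
        if node.state is TaskState.DONE:
            continue
        if until is not None and until():
            break
        node.state = TaskState.READY
        _spec.on_task_ready(runtime, node, _spec.SchedulerState(1, 1))
        node.state = TaskState.RUNNING
        ran = node.activation is Activation.ENABLED
        result = _invoke(node) if ran else None
        start = clock
        clock += node.duration if ran else 0.0
        _finish(runtime, node, ran, result)
        _record(trace, node, 0, start, clock)
    runtime._seq_clock = clock
    return trace


# ---------------------------------------------------------------------------
# threaded worker-pool engine
# ---------------------------------------------------------------------------

def run_parallel(
    runtime: Runtime,
    num_workers: int,
    until: Optional[Callable[[], bool]] = None,
) -> RunTrace:
    """Execute the graph on ``num_workers`` independent worker threads.

    Workers consume a shared FIFO ready queue (ordered by insertion index);
    completion callbacks run under the runtime lock and may enable/disable
    tasks (best-effort cancellation included).  The engine runs the graph to
    completion; final payloads equal the sequential run's.
    """
    if num_workers < 1:
        raise UsageError("num_workers must be >= 1")
    graph = runtime.graph
    trace = RunTrace()
    cv = threading.Condition(runtime.lock)
    pending: dict[int, int] = {}
    ready: list[int] = []  # heap on task id == FIFO by insertion
    state = {"left": 0, "error": None}
    t0 = time.perf_counter()

    with cv:
        nodes_by_id = graph.nodes_by_id
        for node in graph.nodes:
            if node.state is TaskState.DONE:
                continue
            state["left"] += 1
            n_pending = sum(
                1
                for p in graph.preds[node.id]
                if nodes_by_id[p].state is not TaskState.DONE
            )
            pending[node.id] = n_pending
        for nid, cnt in sorted(pending.items()):
            if cnt == 0:
                _push_ready(runtime, ready, nodes_by_id[nid], num_workers)

    def worker(widx: int) -> None:
        while True:
            with cv:
                while not ready and state["left"] > 0 and state["error"] is None:
                    cv.wait()
                if state["left"] == 0 or state["error"] is not None:
                    cv.notify_all()
                    return
                nid = heapq.heappop(ready)
                node = nodes_by_id[nid]
                node.state = TaskState.RUNNING
                ran = node.activation is Activation.ENABLED
            start = time.perf_counter() - t0
            try:
                result = _invoke(node) if ran else None
            except Exception as exc:  # surface body errors to the caller
                with cv:
                    state["error"] = exc
                    cv.notify_all()
                return
            with cv:
                _finish(runtime, node, ran, result)
                end = time.perf_counter() - t0
                _record(trace, node, widx, start, end)
                state["left"] -= 1
                for sid in sorted(graph.succs[nid]):
                    if sid in pending:
                        pending[sid] -= 1
                        if pending[sid] == 0:
                            _push_ready(runtime, ready, nodes_by_id[sid], num_workers)
                cv.notify_all()

    threads = [
        threading.Thread(target=worker, args=(w,), name=f"stf-worker-{w}")
        for w in range(num_workers)
    ]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    if state["error"] is not None:
        raise state["error"]
    if state["left"] != 0:  # pragma: no cover
        raise InternalError("worker pool exited with tasks pending (deadlock?)")
    return trace


def _push_ready(runtime: Runtime, ready_heap: list[int], node: TaskNode, workers: int) -> None:
    node.state = TaskState.READY
    _spec.on_task_ready(
        runtime, node, _spec.SchedulerState(len(ready_heap) + 1, workers)
    )
    heapq.heappush(ready_heap, node.id)


# ---------------------------------------------------------------------------
# simulated-clock (discrete-event) engine
# ---------------------------------------------------------------------------

def run_simulated(
    runtime: Runtime,
    num_workers: int,
    until: Optional[Callable[[], bool]] = None,
) -> RunTrace:
    """Deterministic list-scheduling simulation in abstract time units.

    Bodies still run (instantaneously, in dependency order) so did-write
    outcomes and activation changes are real.  At any timestamp all end
    events are processed before new starts, so a cancellation landing at
    time T stops a task that would have started at T (it then contributes
    zero duration) but is too late for one already started.
    """
    if num_workers < 1:
        raise UsageError("num_workers must be >= 1")
    graph = runtime.graph
    nodes_by_id = graph.nodes_by_id
    trace = RunTrace(makespan=runtime._sim_clock)
    pending: dict[int, int] = {}
    ready: list[int] = []  # heap: FIFO by insertion index
    running: list[tuple[float, int, int]] = []  # (end, task id, worker)
    free: list[tuple[float, int]] = [(runtime._sim_clock, w) for w in range(num_workers)]
    heapq.heapify(free)

    def push_ready(node: TaskNode) -> None:
        node.state = TaskState.READY
        _spec.on_task_ready(
            runtime, node, _spec.SchedulerState(len(ready) + 1, num_workers)
        )
        heapq.heappush(ready, node.id)

    todo = 0
    for node in graph.nodes:
        if node.state is TaskState.DONE:
            continue
        todo += 1
        pending[node.id] = sum(
            1 for p in graph.preds[node.id] if nodes_by_id[p].state is not TaskState.DONE
        )
    for nid in sorted(pending):
        if pending[nid] == 0:
            push_ready(nodes_by_id[nid])

    now = runtime._sim_clock
    results: dict[int, Any] = {}
    while todo > 0:
        if until is not None and until():
            break
        # 1. finish everything ending now (ordered by insertion index)
        ended = [e for e in running if e[0] <= now]
        if ended:
            for e in sorted(ended, key=lambda e: (e[0], e[1])):
                running.remove(e)
                node = nodes_by_id[e[1]]
                _finish(runtime, node, node.ran, results.pop(e[1], None))
                todo -= 1
                for sid in sorted(graph.succs[e[1]]):
                    if sid in pending:
                        pending[sid] -= 1
                        if pending[sid] == 0:
                            push_ready(nodes_by_id[sid])
            continue  # re-check: finishing may have readied 0-duration tasks
        # 2. start ready tasks on workers free at `now`
        started = False
        while ready and free and free[0][0] <= now:
            _, widx = heapq.heappop(free)
            nid = heapq.heappop(ready)
            node = nodes_by_id[nid]
            node.state = TaskState.RUNNING
            ran = node.activation is Activation.ENABLED
            node.ran = ran  # _finish re-asserts; needed for trace/duration
            if ran:
                results[nid] = _invoke(node)
            dur = node.duration if ran else 0.0
            end = now + dur
            heapq.heappush(free, (end, widx))
            running.append((end, nid, widx))
            _record(trace, node, widx, now, end)
            started = True
        if started:
            continue
        # 3. advance the clock to the next event
        candidates = [e[0] for e in running]
        if ready:
            candidates.extend(t for t, _ in free)
        future = [c for c in candidates if c > now]
        if not future:  # pragma: no cover - todo>0 implies progress
            raise InternalError("simulated scheduler stalled")
        now = min(future)
    runtime._sim_clock = max(runtime._sim_clock, trace.makespan)
    return trace
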