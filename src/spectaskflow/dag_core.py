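"""Sequential-task-flow (STF) core: data handles, tasks, automatic dependencies.

In the STF model a single thread inserts tasks, declaring for each task how it
accesses each datum (``READ``, ``WRITE`` or ``MAYBE_WRITE``).  The runtime
derives the dependency DAG from those declarations so that any parallel
execution produces exactly the result of the sequential one.  ``MAYBE_WRITE``
marks data a task *may* modify; a task with at least one such access is an
*uncertain* task and must report, at completion, whether it actually wrote.
Uncertain tasks are the entry point of the speculation machinery (see
:mod:`spectaskflow.speculation`).

Payloads obey a value-semantics contract: they must be deep-copyable and
comparable, and task bodies mutate written payloads *in place* (use
:class:`Box` to wrap immutable scalars).
"""

from __future__ import annotations

import copy as _copylib
import threading
from enum import Enum
from typing import Any, Callable, Optional, Sequence


class AccessMode(Enum):
    READ = "read"
    WRITE = "write"
    MAYBE_WRITE = "maybe_write"


class TaskState(Enum):
    INSERTED = "inserted"
    READY = "ready"
    RUNNING = "running"
    DONE = "done"


class Activation(Enum):
    ENABLED = "enabled"
    DISABLED = "disabled"


class TaskRole(Enum):
    NORMAL = "normal"
    UNCERTAIN = "uncertain"
    COPY = "copy"
    SPECULATIVE = "speculative"
    SELECT = "select"


class ConfigurationError(ValueError):
    """A datum or runtime option violates the value-semantics contract."""


class UsageError(ValueError):
    """The API was called with inconsistent arguments."""


class InternalError(RuntimeError):
    """Invariant violation inside the runtime (a bug, not a user error)."""


class Box:
    """Mutable cell for immutable payloads (ints, floats, bools, strings).

    Task bodies receive payload objects and must write in place; a ``Box``
    makes that possible for scalars: ``box.value = 42``.
    """

    __slots__ = ("value",)

    def __init__(self, value: Any):
        self.value = value

    def __eq__(self, other: Any) -> bool:
        return isinstance(other, Box) and self.value == other.value

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Box({self.value!r})"


def payload_equal(a: Any, b: Any) -> bool:
    """Structural equality for payloads, including numpy arrays and Generators."""
    import numpy as np

    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return (
            isinstance(a, np.ndarray)
            and isinstance(b, np.ndarray)
            and a.shape == b.shape
            and a.dtype == b.dtype
            and bool(np.array_equal(a, b))
        )
    if isinstance(a, np.random.Generator) and isinstance(b, np.random.Generator):
        return payload_equal(a.bit_generator.state, b.bit_generator.state)
    if isinstance(a, Box) and isinstance(b, Box):
        return payload_equal(a.value, b.value)
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(payload_equal(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return (
            type(a) is type(b)
            and len(a) == len(b)
            and all(payload_equal(x, y) for x, y in zip(a, b))
        )
    return bool(a == b)


class DataHandle:
    """A registered datum: identity, current payload and access history.

    ``last_writer`` and ``readers_since_last_write`` implement the classic
    read-after-write / write-after-read / write-after-write ordering; the
    reader list is emptied whenever a new writer is recorded.
    """

    __slots__ = ("id", "name", "payload", "last_writer", "readers_since_last_write")

    def __init__(self, id: int, payload: Any, name: Optional[str] = None):
        self.id = id
        self.name = name or f"d{id}"
        self.payload = payload
        self.last_writer: Optional[TaskNode] = None
        self.readers_since_last_write: list[TaskNode] = []

    def __repr__(self) -> str:  # pragma: no cover
        return f"DataHandle({self.name})"

    def __hash__(self) -> int:
        return self.id


class TaskNode:
    """One node of the task DAG.

    ``did_write`` is only ever set on uncertain tasks, at completion.  ``ran``
    records whether the body was actually invoked (a DISABLED task completes
    for dependency purposes but its body acts as an empty function).
    """

    __slots__ = (
        "id",
        "name",
        "accesses",
        "body",
        "uncertain",
        "role",
        "duration",
        "state",
        "activation",
        "did_write",
        "result",
        "group",
        "twin",
        "ran",
        "system",
    )

    def __init__(
        self,
        id: int,
        accesses: Sequence[tuple[DataHandle, AccessMode]],
        body: Callable[..., Any],
        *,
        uncertain: bool = False,
        role: TaskRole = TaskRole.NORMAL,
        duration: float = 1.0,
        name: Optional[str] = None,
        system: bool = False,
    ):
        # id is provisional until graph insertion (runtime-created helper
        # tasks may be inserted ahead of the user task that triggered them)
        self.id = id
        self.name = name
        self.accesses = list(accesses)
        self.body = body
        self.uncertain = uncertain
        self.role = role
        self.duration = duration
        self.state = TaskState.INSERTED
        self.activation = Activation.ENABLED
        self.did_write: Optional[bool] = None
        self.result: Any = None
        self.group = None  # SpeculativeTaskGroup or None
        self.twin: Optional[TaskNode] = None
        self.ran = False
        # system tasks (copy/select) receive handles, user tasks receive payloads
        self.system = system

    @property
    def handles(self) -> list[DataHandle]:
        return [h for h, _ in self.accesses]

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaskNode({self.name}, {self.role.value})"

    def __hash__(self) -> int:
        return self.id


class TaskGraph:
    """Insertion-ordered task list plus the dependency edge set.

    Every edge goes from a lower to a higher insertion index, so insertion
    order is always a topological order.
    """

    def __init__(self) -> None:
        self.nodes: list[TaskNode] = []
        self.edges: set[tuple[int, int]] = set()
        self.preds: dict[int, set[int]] = {}
        self.succs: dict[int, set[int]] = {}

    def add_node(self, node: TaskNode) -> None:
        self.nodes.append(node)
        self.preds.setdefault(node.id, set())
        self.succs.setdefault(node.id, set())

    def add_edge(self, pred: TaskNode, succ: TaskNode) -> None:
        if pred.id == succ.id:
            return
        if pred.id > succ.id:  # pragma: no cover - guarded by construction
            raise InternalError("edge against insertion order")
        key = (pred.id, succ.id)
        if key in self.edges:
            return  # duplicate edges are collapsed
        self.edges.add(key)
        self.preds[succ.id].add(pred.id)
        self.succs[pred.id].add(succ.id)

    def node_by_id(self, nid: int) -> TaskNode:
        return self.nodes_by_id[nid]

    @property
    def nodes_by_id(self) -> dict[int, TaskNode]:
        return {n.id: n for n in self.nodes}

    def __len__(self) -> int:
        return len(self.nodes)


def compute_dependencies(task: TaskNode, graph: TaskGraph) -> list[tuple[TaskNode, TaskNode]]:
    """Compute and record the dependency edges of ``task``.

    READ depends on the datum's last writer; WRITE and MAYBE_WRITE depend on
    the last writer and on every reader since that write (MAYBE_WRITE is
    ordered exactly like WRITE, conservatively).  Handle histories are updated:
    a MAYBE_WRITE records the task as a writer for ordering purposes.
    """
    edges: list[tuple[TaskNode, TaskNode]] = []

    def _edge(pred: TaskNode, succ: TaskNode) -> None:
        if pred is succ:
            return
        before = (pred.id, succ.id) in graph.edges
        graph.add_edge(pred, succ)
        if not before:
            edges.append((pred, succ))

    for handle, mode in task.accesses:
        if mode is AccessMode.READ:
            if handle.last_writer is not None:
                _edge(handle.last_writer, task)
        else:
            if handle.last_writer is not None:
                _edge(handle.last_writer, task)
            for reader in handle.readers_since_last_write:
                _edge(reader, task)
    # second pass: update histories once all edges are drawn
    for handle, mode in task.accesses:
        if mode is AccessMode.READ:
            handle.readers_since_last_write.append(task)
        else:
            handle.last_writer = task
            handle.readers_since_last_write = []
    return edges


class TaskHandle:
    """What ``insert_task`` returns: wait for the task and fetch its result.

    For a task that received a speculative twin, the *effective* result is the
    original's if the original actually ran (speculation failed or disabled)
    and the twin's otherwise.
    """

    def __init__(self, runtime: "Runtime", node: TaskNode):
        self._runtime = runtime
        self.node = node

    def wait(self) -> None:
        self._runtime._run_default(
            until=lambda: self._resolved(),
        )

    def _resolved(self) -> bool:
        n = self.node
        if n.state is not TaskState.DONE:
            return False
        if n.twin is not None and not n.ran:
            return n.twin.state is TaskState.DONE
        return True

    @property
    def value(self) -> Any:
        if not self._resolved():
            self.wait()
        n = self.node
        if n.ran or n.twin is None:
            return n.result
        return n.twin.result

    def get_value(self) -> Any:
        return self.value


class Runtime:
    """STF runtime: data registration, task insertion, waits, graph export.

    Parameters
    ----------
    speculation:
        When False, MAYBE_WRITE is treated as a plain conservative WRITE and
        no copy/speculative/select tasks are ever created (the baseline
        task-based execution).
    speculation_policy:
        Callable ``(group, scheduler_state) -> GroupState`` consulted when the
        first runtime-created task of a speculative group becomes ready.
        Defaults to always-enabled.
    copy_duration, select_duration:
        Abstract-time cost of runtime-created copy and select tasks (default
        0, matching the unit-cost theory where copies/selects are negligible).
    default_duration:
        Duration of user tasks that do not specify one.
    """

    def __init__(
        self,
        *,
        speculation: bool = True,
        speculation_policy: Optional[Callable] = None,
        copy_duration: float = 0.0,
        select_duration: float = 0.0,
        default_duration: float = 1.0,
        executor: str = "sequential",
        num_workers: int = 1,
    ):
        from . import speculation as _spec

        self.graph = TaskGraph()
        self.speculation_enabled = speculation
        self.speculation_policy = speculation_policy or _spec.always_enabled
        self.copy_duration = float(copy_duration)
        self.select_duration = float(select_duration)
        self.default_duration = float(default_duration)
        self.registry: dict[int, Any] = {}  # handle id -> DuplicateEntry
        self.groups: list[Any] = []  # SpeculativeTaskGroup, insertion order
        self.lock = threading.RLock()
        self._next_data_id = 0
        self._next_task_id = 0
        self._data: dict[int, DataHandle] = {}
        self._default_executor = executor
        self._default_workers = num_workers
        self._sim_clock = 0.0
        self._seq_clock = 0.0

    # ------------------------------------------------------------------ data
    def register_data(self, payload: Any, name: Optional[str] = None) -> DataHandle:
        """Register a datum and return a fresh handle with empty history."""
        try:
            _copylib.deepcopy(payload)
        except Exception as exc:
            raise ConfigurationError(
                f"payload of type {type(payload).__name__} is not deep-copyable"
            ) from exc
        handle = DataHandle(self._next_data_id, payload, name)
        self._next_data_id += 1
        self._data[handle.id] = handle
        return handle

    # ----------------------------------------------------------------- tasks
    def insert_task(
        self,
        accesses: Sequence[tuple[DataHandle, AccessMode]],
        body: Callable[..., Any],
        *,
        uncertain: bool = False,
        duration: Optional[float] = None,
        name: Optional[str] = None,
    ) -> TaskHandle:
        """Insert a task; dependencies are derived from its access list.

        Uncertain tasks (``uncertain=True``) must declare at least one
        MAYBE_WRITE access and their body must return a boolean did-write
        flag.  Insertion of uncertain tasks and of normal tasks touching
        duplicated data is delegated to the speculation machinery.
        """
        from . import speculation as _spec

        accesses = list(accesses)
        seen_ids = set()
        for item in accesses:
            if not (isinstance(item, tuple) and len(item) == 2):
                raise UsageError("accesses must be (DataHandle, AccessMode) pairs")
            handle, mode = item
            if not isinstance(mode, AccessMode):
                raise UsageError(f"not an AccessMode: {mode!r}")
            if self._data.get(handle.id) is not handle:
                raise UsageError(f"handle {handle!r} was not registered with this runtime")
            if handle.id in seen_ids:
                raise UsageError(f"handle {handle!r} appears twice in the access list")
            seen_ids.add(handle.id)
        has_maybe = any(m is AccessMode.MAYBE_WRITE for _, m in accesses)
        if uncertain and not has_maybe:
            raise UsageError("an uncertain task needs at least one MAYBE_WRITE access")
        if has_maybe and not uncertain:
            raise UsageError("MAYBE_WRITE access is only legal on uncertain tasks")

        if duration is None:
            duration = self.default_duration
        if duration < 0:
            raise UsageError("task duration must be nonnegative")
        node = self._new_node(
            accesses,
            body,
            uncertain=uncertain,
            role=TaskRole.UNCERTAIN if uncertain else TaskRole.NORMAL,
            duration=duration,
            name=name,
        )
        with self.lock:
            if not self.speculation_enabled:
                self._internal_insert(node)
            elif uncertain:
                _spec.insert_uncertain_task(self, node)
            else:
                _spec.insert_guarded_normal_task(self, node)
        return TaskHandle(self, node)

    def _new_node(self, accesses, body, **kw) -> TaskNode:
        return TaskNode(-1, accesses, body, **kw)

    def _internal_insert(self, node: TaskNode) -> None:
        """Plain STF insertion: assign the insertion index, compute
        dependencies and append to the graph."""
        node.id = self._next_task_id
        self._next_task_id += 1
        if node.name is None:
            node.name = f"t{node.id}"
        self.graph.add_node(node)
        compute_dependencies(node, self.graph)

    # ----------------------------------------------------------------- waits
    def _run_default(self, until=None):
        from . import executor as _exec

        kind = self._default_executor
        if kind == "sequential":
            return _exec.run_sequential(self, until=until)
        if kind == "parallel":
            return _exec.run_parallel(self, self._default_workers, until=until)
        if kind == "simulated":
            return _exec.run_simulated(self, self._default_workers, until=until)
        raise UsageError(f"unknown executor {kind!r}")

    def set_executor(self, kind: str, num_workers: int = 1) -> None:
        if kind not in ("sequential", "parallel", "simulated"):
            raise UsageError(f"unknown executor {kind!r}")
        self._default_executor = kind
        self._default_workers = num_workers

    def remaining(self) -> int:
        return sum(1 for n in self.graph.nodes if n.state is not TaskState.DONE)

    def wait_all(self):
        """Block until every inserted task is DONE."""
        return self._run_default()

    def wait_remain(self, n: int):
        """Block until at most ``n`` tasks are not DONE."""
        if n < 0:
            raise UsageError("wait_remain needs n >= 0")
        return self._run_default(until=lambda: self.remaining() <= n)

    def task_wait(self, handle: TaskHandle) -> Any:
        """Wait for one task and return its (twin-aware) result."""
        return handle.value

    # ---------------------------------------------------------------- export
    def export_dot(self) -> str:
        return export_dot(self.graph)


_ROLE_SHAPE = {
    TaskRole.NORMAL: "box",
    TaskRole.UNCERTAIN: "diamond",
    TaskRole.COPY: "note",
    TaskRole.SPECULATIVE: "octagon",
    TaskRole.SELECT: "invtriangle",
}


def export_dot(graph: TaskGraph) -> str:
    """Emit the task graph as deterministic Graphviz DOT text.

    One node per task, labelled with its id, role and current activation; one
    edge per dependency.
    """
    lines = ["digraph taskflow {"]
    for node in graph.nodes:
        label = f"{node.name}\\n{node.role.value}\\n{node.activation.value}"
        shape = _ROLE_SHAPE[node.role]
        lines.append(f'  n{node.id} [label="{label}", shape={shape}];')
    for pred, succ in sorted(graph.edges):
        lines.append(f"  n{pred} -> n{succ};")
    lines.append("}")
    return "\n".join(lines) + "\n"
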