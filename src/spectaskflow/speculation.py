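"""Copy/speculative/select task construction and speculative task groups.

An *uncertain* task declares MAYBE_WRITE accesses and only reveals at
completion whether it wrote.  At insertion time the runtime therefore builds,
next to the pessimistic original chain, an optimistic *speculative* path:

* a **copy task** duplicates each datum an uncertain task may write, *before*
  the uncertain task runs;
* a later task touching duplicated data is inserted twice — once as the
  **original** (reading/writing the true data, behind the uncertain task) and
  once as a **speculative twin** operating on the duplicates, which can run
  concurrently with the uncertain task;
* a **select task** per written datum acts as a switch: when enabled it
  overwrites the original payload with the speculative duplicate's value.

All tasks sharing a speculation fate form a :class:`SpeculativeTaskGroup`
(STG).  If *any* uncertain task of a group writes, the speculation of every
downstream group has failed: twins are cancelled best-effort, originals are
enabled and selects are disabled.  If every uncertain task reports no-write,
originals stay disabled and the selects commit the speculative values.

Activation defaults are optimistic (speculation is expected to be on):
originals that have twins start DISABLED, twins/copies/selects start ENABLED,
and failure events flip them.  The construction guarantees that every such
decision is made before the affected task can start: an original is always
gated, through the data dependencies, behind the previous level's select,
which itself depends on the twin whose did-write outcome decides the group.

Consecutive uncertain tasks follow the chained strategy: the twin of level
``k`` operates on the *previous* level's duplicate, and a second-level copy of
that duplicate is taken before the twin may write it, so the next level can
speculate in turn.  The degree of parallelism then grows with the number of
consecutive uncertain tasks.
"""

from __future__ import annotations

import copy as _copylib
from enum import Enum
from typing import Iterable, Optional

from .dag_core import (
    AccessMode,
    Activation,
    DataHandle,
    InternalError,
    Runtime,
    TaskNode,
    TaskRole,
    TaskState,
)


class GroupState(Enum):
    UNDEFINED = "undefined"
    ENABLED = "enabled"
    DISABLED = "disabled"


class DuplicateEntry:
    """Registry record: ``original`` currently has the live duplicate ``duplicate``.

    ``used_in_read`` flips when a speculative twin consumes the duplicate in
    READ mode; such entries are dropped as soon as a task accesses the
    original in non-READ mode (Algorithm-3/4 cleaning rule).
    """

    __slots__ = ("original", "duplicate", "producing_copy_task", "group", "used_in_read")

    def __init__(self, original, duplicate, producing_copy_task, group):
        self.original = original
        self.duplicate = duplicate
        self.producing_copy_task = producing_copy_task
        self.group = group
        self.used_in_read = False


class SpeculativeTaskGroup:
    """Linked lists of copy/uncertain/original/speculative/select tasks.

    ``state`` is the runtime speculation decision (undefined until the first
    runtime-created task of the group becomes ready).  ``failed`` means the
    speculative path of this group is dead — because an upstream uncertain
    task wrote, or because speculation was disabled.  ``outcome`` is the
    effective did-write of this group's own uncertain step (``False`` from
    birth for groups whose main task is a certain one).
    """

    def __init__(self, runtime: Runtime, parents: Iterable["SpeculativeTaskGroup"] = ()):
        self.id = len(runtime.groups)
        self.copy_tasks: list[TaskNode] = []
        self.uncertain_tasks: list[TaskNode] = []
        self.original_tasks: list[TaskNode] = []
        self.speculative_tasks: list[TaskNode] = []
        self.select_tasks: list[TaskNode] = []
        self.parents: list[SpeculativeTaskGroup] = list(parents)
        self.successors: list[SpeculativeTaskGroup] = []
        for p in self.parents:
            p.successors.append(self)
        self.state = GroupState.UNDEFINED
        self.failed = False
        self.outcome: Optional[bool] = None
        self.resolved = False
        self._parents_pending = 0
        runtime.groups.append(self)

    # ---- status helpers -------------------------------------------------
    @property
    def speculation_dead(self) -> bool:
        """True when no future task may speculate over this group's duplicates."""
        return self.failed or self.state is GroupState.DISABLED or self.outcome is True

    def all_tasks(self) -> list[TaskNode]:
        return (
            self.copy_tasks
            + self.uncertain_tasks
            + self.original_tasks
            + self.speculative_tasks
            + self.select_tasks
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"STG(#{self.id}, state={self.state.value}, failed={self.failed})"


# --------------------------------------------------------------------------
# speculation decision policies
# --------------------------------------------------------------------------

class SchedulerState:
    """Snapshot handed to the speculation-decision policy."""

    __slots__ = ("num_ready", "num_workers")

    def __init__(self, num_ready: int, num_workers: int):
        self.num_ready = num_ready
        self.num_workers = num_workers


def always_enabled(group: SpeculativeTaskGroup, state: SchedulerState) -> GroupState:
    """Default policy: speculation is always enabled."""
    return GroupState.ENABLED


def always_disabled(group: SpeculativeTaskGroup, state: SchedulerState) -> GroupState:
    """Baseline policy: never speculate; execution equals the plain task run."""
    return GroupState.DISABLED


def threshold_policy(group: SpeculativeTaskGroup, state: SchedulerState) -> GroupState:
    """Enable speculation only when the scheduler is starved for parallelism."""
    if state.num_ready < state.num_workers:
        return GroupState.ENABLED
    return GroupState.DISABLED


def decide_speculation(runtime: Runtime, group: SpeculativeTaskGroup, state: SchedulerState) -> GroupState:
    """Fix a group's speculation state using the runtime's policy.

    Disabling turns every copy/speculative/select task of the group into a
    no-op, re-enables the originals, and kills all successor groups (their
    duplicates were never produced).
    """
    if group.state is not GroupState.UNDEFINED:
        return group.state
    decision = runtime.speculation_policy(group, state)
    if not isinstance(decision, GroupState):
        raise InternalError(f"policy returned {decision!r}, not a GroupState")
    group.state = decision
    if decision is GroupState.DISABLED:
        _abandon(group)
    return decision


def on_task_ready(runtime: Runtime, node: TaskNode, state: SchedulerState) -> None:
    """Executor hook: a task became ready.

    Used to trigger the speculation decision when the first runtime-created
    task (normally the first copy) of an undecided group becomes ready.
    """
    g = node.group
    if (
        g is not None
        and g.state is GroupState.UNDEFINED
        and node.role in (TaskRole.COPY, TaskRole.SPECULATIVE, TaskRole.SELECT)
    ):
        decide_speculation(runtime, g, state)


# --------------------------------------------------------------------------
# activation propagation
# --------------------------------------------------------------------------

def _try_disable(node: TaskNode) -> bool:
    """Best-effort cancellation: no-op when the task already started."""
    if node.state in (TaskState.RUNNING, TaskState.DONE):
        return False  # too late
    node.activation = Activation.DISABLED
    return True


def _abandon(group: SpeculativeTaskGroup) -> None:
    """Speculation declined at runtime: fall back to the original path."""
    group.failed = True
    for t in group.copy_tasks + group.speculative_tasks + group.select_tasks:
        _try_disable(t)
    for t in group.original_tasks:
        t.activation = Activation.ENABLED
    for s in group.successors:
        _fail(s)


def _fail(group: SpeculativeTaskGroup) -> None:
    """An upstream uncertain task wrote: this group's speculation is invalid."""
    if group.failed:
        return
    group.failed = True
    for t in group.speculative_tasks + group.select_tasks + group.copy_tasks:
        _try_disable(t)
    for t in group.original_tasks:
        # structurally guaranteed to not have started yet (gated behind the
        # deciding select/uncertain task in the dependency graph)
        t.activation = Activation.ENABLED
    for s in group.successors:
        _fail(s)


def _parent_ok(group: SpeculativeTaskGroup) -> None:
    group._parents_pending -= 1
    _maybe_resolve(group)


def _maybe_resolve(group: SpeculativeTaskGroup) -> None:
    """Propagate once both the upstream chain and the own outcome are known."""
    if group.resolved or group.failed:
        return
    if group.outcome is None or group._parents_pending > 0:
        return
    group.resolved = True
    if group.outcome:
        # this group's uncertain step wrote: everything speculating over it dies
        for s in group.successors:
            _fail(s)
    else:
        for s in group.successors:
            _parent_ok(s)


def _refresh_from_parents(group: SpeculativeTaskGroup) -> None:
    """Initialize upstream bookkeeping (parents may already be resolved)."""
    for p in group.parents:
        if p.failed or (p.resolved and p.outcome):
            _fail(group)
            return
    group._parents_pending = sum(
        1 for p in group.parents if not (p.resolved and p.outcome is False)
    )
    _maybe_resolve(group)


def on_uncertain_complete(runtime: Runtime, node: TaskNode, did_write: bool) -> None:
    """Executor hook: an enabled uncertain task finished and reported.

    Drives group failure/success propagation exactly once per task.
    """
    if not isinstance(did_write, bool):
        from .dag_core import UsageError

        raise UsageError(
            f"uncertain task {node.name} must return a boolean did-write flag, "
            f"got {did_write!r}"
        )
    if node.did_write is not None:
        raise InternalError(f"{node!r} reported its did-write flag twice")
    node.did_write = did_write
    group = node.group
    if group is None:  # speculation-free runtime
        return
    if group.failed:
        # fallback path is running; downstream groups were already failed
        return
    if node.role is TaskRole.SPECULATIVE or node.twin is None:
        # the task acting as this group's effective uncertain step
        group.outcome = did_write
        _maybe_resolve(group)
    else:  # pragma: no cover - an enabled original with a live twin is a bug
        raise InternalError("original with twin ran although its group had not failed")


# --------------------------------------------------------------------------
# duplicate / twin / select construction helpers
# --------------------------------------------------------------------------

def _copy_body(src: DataHandle, dst: DataHandle):
    def body() -> None:
        dst.payload = _copylib.deepcopy(src.payload)

    return body


def _select_body(original: DataHandle, duplicate: DataHandle):
    def body() -> None:
        original.payload = _copylib.deepcopy(duplicate.payload)

    return body


def _make_duplicate(
    runtime: Runtime,
    src: DataHandle,
    group: SpeculativeTaskGroup,
    *,
    registry_original: Optional[DataHandle] = None,
) -> DuplicateEntry:
    """Create a duplicate handle of ``src`` and the copy task producing it.

    ``registry_original`` is the user-visible handle the entry stands for
    (``src`` itself may already be a duplicate in chained speculation).
    """
    orig = registry_original or src
    dup = runtime.register_data(None, name=f"{orig.name}'")
    copy_task = runtime._new_node(
        [(src, AccessMode.READ), (dup, AccessMode.WRITE)],
        _copy_body(src, dup),
        role=TaskRole.COPY,
        duration=runtime.copy_duration,
        name=f"copy({src.name})",
        system=True,
    )
    runtime._internal_insert(copy_task)
    copy_task.group = group
    group.copy_tasks.append(copy_task)
    return DuplicateEntry(orig, dup, copy_task, group)


def create_select_tasks(
    runtime: Runtime,
    group: SpeculativeTaskGroup,
    pairs: Iterable[tuple[DataHandle, DataHandle]],
) -> list[TaskNode]:
    """One select per (original, duplicate) pair: enabled, it does ``x = x'``.

    The dependency computation makes each select depend on the last writer of
    the original (the original task of the group) and on the producing
    speculative twin (last writer of the duplicate).
    """
    selects = []
    for original, duplicate in pairs:
        sel = runtime._new_node(
            [(original, AccessMode.WRITE), (duplicate, AccessMode.READ)],
            _select_body(original, duplicate),
            role=TaskRole.SELECT,
            duration=runtime.select_duration,
            name=f"select({original.name})",
            system=True,
        )
        runtime._internal_insert(sel)
        sel.group = group
        group.select_tasks.append(sel)
        selects.append(sel)
    return selects


def _insert_twin(
    runtime: Runtime,
    original: TaskNode,
    dup_map: dict[int, DataHandle],
    group: SpeculativeTaskGroup,
) -> TaskNode:
    """Insert the speculative twin of ``original`` operating on duplicates.

    Data without a duplicate are shared in READ mode between the original and
    the twin (they can be used concurrently).
    """
    accesses = [(dup_map.get(h.id, h), mode) for h, mode in original.accesses]
    twin = runtime._new_node(
        accesses,
        original.body,
        uncertain=original.uncertain,
        role=TaskRole.SPECULATIVE,
        duration=original.duration,
        name=f"{original.name}'",
    )
    runtime._internal_insert(twin)
    twin.group = group
    group.speculative_tasks.append(twin)
    original.twin = twin
    twin.twin = original
    return twin


def _clean_read_duplicates(runtime: Runtime, task: TaskNode) -> None:
    """Drop registry entries whose duplicate was only consumed in READ mode
    when ``task`` accesses the original in non-READ mode."""
    for h, mode in task.accesses:
        if mode is AccessMode.READ:
            continue
        entry = runtime.registry.get(h.id)
        if entry is not None and entry.used_in_read:
            del runtime.registry[h.id]


def _drop_entries(runtime: Runtime, handles: Iterable[DataHandle]) -> None:
    for h in handles:
        runtime.registry.pop(h.id, None)


def _related_groups(runtime: Runtime, task: TaskNode) -> list[SpeculativeTaskGroup]:
    groups: dict[int, SpeculativeTaskGroup] = {}
    for h, _ in task.accesses:
        entry = runtime.registry.get(h.id)
        if entry is not None:
            groups[entry.group.id] = entry.group
    return [groups[k] for k in sorted(groups)]


# --------------------------------------------------------------------------
# task insertion (Algorithms 3 and 4)
# --------------------------------------------------------------------------

def insert_uncertain_task(runtime: Runtime, task: TaskNode) -> SpeculativeTaskGroup:
    """Insert an uncertain task, creating duplicates/twin/selects as needed.

    Two regimes:

    * no related live group (or a dead one): duplicates of the MAYBE_WRITE
      data are created for *future* tasks to speculate over, the task itself
      runs on the true data, and a fresh parentless group starts;
    * related live groups exist: the task is inserted both as the original
      (on the true data, behind its predecessors) and as a speculative twin
      operating on the registered duplicates, with one select per written
      datum; second-level duplicates keep the chain open for the next level.
    """
    _clean_read_duplicates(runtime, task)
    related = _related_groups(runtime, task)

    if not related or any(g.speculation_dead for g in related):
        _drop_entries(runtime, task.handles)
        group = SpeculativeTaskGroup(runtime)
        new_entries = []
        for h, mode in task.accesses:
            if mode is AccessMode.MAYBE_WRITE:
                new_entries.append(_make_duplicate(runtime, h, group))
        runtime._internal_insert(task)
        task.group = group
        group.uncertain_tasks.append(task)
        # the root uncertain task of a chain runs unconditionally
        task.activation = Activation.ENABLED
        for entry in new_entries:
            runtime.registry[entry.original.id] = entry
        _refresh_from_parents(group)
        return group

    group = SpeculativeTaskGroup(runtime, parents=related)
    dup_map: dict[int, DataHandle] = {}
    post_entries: list[DuplicateEntry] = []
    consumed: list[DataHandle] = []
    for h, mode in task.accesses:
        entry = runtime.registry.get(h.id)
        if mode is AccessMode.MAYBE_WRITE:
            if entry is not None:
                dup_map[h.id] = entry.duplicate
            else:
                e = _make_duplicate(runtime, h, group)
                dup_map[h.id] = e.duplicate
            # snapshot the working duplicate before the twin can write it, so
            # the next level speculates over this task without waiting for it
            post_entries.append(
                _make_duplicate(runtime, dup_map[h.id], group, registry_original=h)
            )
        elif mode is AccessMode.WRITE:
            if entry is not None:
                dup_map[h.id] = entry.duplicate
                consumed.append(h)
            else:
                e = _make_duplicate(runtime, h, group)  # l2
                dup_map[h.id] = e.duplicate
        else:  # READ
            if entry is not None:
                dup_map[h.id] = entry.duplicate
                entry.used_in_read = True
            # else: shared between original and twin, no duplicate needed

    runtime._internal_insert(task)
    task.group = group
    group.uncertain_tasks.append(task)
    group.original_tasks.append(task)
    task.activation = Activation.DISABLED  # optimistic: the twin stands in

    _insert_twin(runtime, task, dup_map, group)

    pairs = [
        (h, dup_map[h.id])
        for h, mode in task.accesses
        if mode is not AccessMode.READ
    ]
    create_select_tasks(runtime, group, pairs)

    for h in consumed:
        runtime.registry.pop(h.id, None)
    for entry in post_entries:
        runtime.registry[entry.original.id] = entry
    _refresh_from_parents(group)
    return group


def insert_guarded_normal_task(runtime: Runtime, task: TaskNode) -> Optional[SpeculativeTaskGroup]:
    """Insert a certain task, speculating over it when its data is duplicated.

    Plain insertion when none of its data has a live duplicate, or when a
    related group is already known dead (the duplicates are then dropped).
    Otherwise the task gets a speculative twin reading the duplicates (and
    writing fresh ``l2`` duplicates for written data not yet duplicated) plus
    one select per written datum.  All registry entries for the task's data
    are dropped afterwards: a certain task terminates the speculation chain,
    so a later uncertain task restarts a fresh speculation process.
    """
    _clean_read_duplicates(runtime, task)
    touched = [h for h, _ in task.accesses if h.id in runtime.registry]
    if not touched:
        runtime._internal_insert(task)
        return None
    related = _related_groups(runtime, task)
    if any(g.speculation_dead for g in related):
        # we already know the speculation has failed
        _drop_entries(runtime, task.handles)
        runtime._internal_insert(task)
        return None

    group = SpeculativeTaskGroup(runtime, parents=related)
    dup_map: dict[int, DataHandle] = {}
    for h, mode in task.accesses:
        entry = runtime.registry.get(h.id)
        if mode is AccessMode.READ:
            if entry is not None:
                dup_map[h.id] = entry.duplicate
                entry.used_in_read = True
        else:  # WRITE
            if entry is not None:
                dup_map[h.id] = entry.duplicate
            else:
                e = _make_duplicate(runtime, h, group)  # l2
                dup_map[h.id] = e.duplicate

    runtime._internal_insert(task)
    task.group = group
    group.original_tasks.append(task)
    task.activation = Activation.DISABLED

    _insert_twin(runtime, task, dup_map, group)

    pairs = [
        (h, dup_map[h.id])
        for h, mode in task.accesses
        if mode is not AccessMode.READ
    ]
    create_select_tasks(runtime, group, pairs)

    # a certain task always "writes": its fate is decided purely upstream
    group.outcome = False
    _drop_entries(runtime, task.handles)
    _refresh_from_parents(group)
    return group
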