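"""Insert tasks with declared data accesses and let the runtime order them.

Builds a tiny sequential-task-flow program: tasks declare READ/WRITE access
on registered data, the runtime derives the dependency DAG, and any executor
reproduces the sequential result.
"""

from spectaskflow import AccessMode, Box, Runtime, export_dot, run_parallel

rt = Runtime()
x = rt.register_data(Box(1), name="x")
y = rt.register_data(Box(0), name="y")

rt.insert_task([(x, AccessMode.WRITE)], lambda b: b.__setattr__("value", 10), name="init")
# two independent readers of x may run concurrently
rt.insert_task([(x, AccessMode.READ), (y, AccessMode.WRITE)],
               lambda xv, yv: yv.__setattr__("value", xv.value + 5), name="add")
h = rt.insert_task([(x, AccessMode.READ)], lambda xv: xv.value * 2, name="double")

trace = run_parallel(rt, num_workers=2)
print("final x =", x.payload.value, "| final y =", y.payload.value)
print("result of the 'double' task:", h.value)
print(f"{len(rt.graph.nodes)} tasks, {len(rt.graph.edges)} dependency edges")
print(export_dot(rt.graph))
# x stays 10, y becomes 15 and the read-only task returns 20; the DOT text
# shows the DAG the runtime derived from the access declarations alone.
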