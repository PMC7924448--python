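"""Hardware-independent makespans from the discrete-event executor.

Reproduces the two closed-form durations of the single-uncertain-task graph:
with speculation, D = copy + max(B + C, C') when B writes, and
D = copy + max(B, C') + select when it does not.
"""

from spectaskflow import Runtime, run_simulated
from spectaskflow.fixtures import four_task_chain_program

c, b, g, s = 1.0, 3.0, 2.0, 1.0  # copy, B, C (and twin), select durations

for b_writes in (True, False):
    rt = Runtime(copy_duration=c, select_duration=s)
    four_task_chain_program(b_writes, {"B": b, "C": g})(rt)
    trace = run_simulated(rt, num_workers=2)
    closed = c + max(b + g, g) if b_writes else c + max(b, g) + s
    print(f"B writes: {b_writes!s:5}  simulated makespan = {trace.makespan:g}  "
          f"closed form = {closed:g}")

# Baseline without speculation for comparison: B then C in sequence.
rt = Runtime(speculation=False)
four_task_chain_program(True, {"B": b, "C": g})(rt)
print("no speculation        makespan =", run_simulated(rt, 2).makespan)
# Speculation turns the B->C chain of cost 5 into max-of-parallel-paths.
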