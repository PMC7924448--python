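"""Speculate over a task that only *may* write its data.

An uncertain task declares MAYBE_WRITE and reports at completion whether it
wrote.  The runtime inserts a copy task, a speculative twin of the follower
and a select switch; when the uncertain task reports no-write, the twin's
result is committed and the follower's body is never invoked.
"""

from spectaskflow import AccessMode, Box, Runtime, run_parallel

for b_writes in (False, True):
    rt = Runtime()
    x = rt.register_data(Box(1), name="x")
    rt.insert_task([(x, AccessMode.WRITE)], lambda b: b.__setattr__("value", 3), name="A")

    def maybe(b, writes=b_writes):
        if writes:
            b.value += 100
            return True   # did write
        return False      # untouched

    rt.insert_task([(x, AccessMode.MAYBE_WRITE)], maybe, uncertain=True, name="B")
    follower = rt.insert_task(
        [(x, AccessMode.WRITE)], lambda b: b.__setattr__("value", b.value * 2), name="C"
    )
    run_parallel(rt, num_workers=2)

    c = follower.node
    path = "original C" if c.ran else "speculative twin C'"
    print(f"B wrote: {b_writes!s:5}  final x = {x.payload.value:4}  "
          f"executed path: {path}")
# Without a write, x = 6 comes from C' computed concurrently with B and
# committed by the select; with a write, speculation fails and the original
# C runs on the true value (103 * 2 = 206).
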