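"""Expected-gain and speedup models for speculation over uncertain-task chains.

Setting: ``N`` consecutive uncertain tasks followed by one normal task, all
of cost ``t``, negligible copies/selects, and at least ``N`` workers.  Task
``i`` writes its data with probability ``P_i`` (the normal task, index
``N+1``, always writes: ``P_{N+1} = 1``).

*Predictive* speculation speculates along the no-write path once; the first
write invalidates the rest of the chain.  If the first writer is task
``i+1`` (tasks ``1..i`` did not write) the saved duration is ``i*t``; if no
task writes it is ``N*t``.  The expected gain is

    D_N = sum_{i=1..N} t * i * P_{i+1} * prod_{j<=i} (1 - P_j)

and the expected speedup ``S = (N+1)t / ((N+1)t - D_N)``.

*Eager* speculation restarts after every failure, so every individual
no-write contributes ``t``:

    F(N) = t * sum_{i=1..N} (1 - P_i),    S = (N+1)t / ((N+1)t - F(N)).

For uniform ``P = 1/2``, ``F(N) = N t / 2`` and the eager speedup
``2(N+1)/(N+2)`` tends to 2 as the chain grows.  The eager scheme needs
``(N^2+N)/2 - N`` speculative tasks and is evaluated here only as theory.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .dag_core import UsageError


@dataclass(frozen=True)
class TheoryParams:
    """N consecutive uncertain tasks with write probabilities and unit cost.

    ``probs`` has length N; entry ``i`` is the probability that uncertain
    task ``i+1`` writes.  The trailing normal task's probability is fixed to
    one and never stored.
    """

    N: int
    probs: tuple[float, ...]
    t: float = 1.0

    def __post_init__(self):
        if self.N < 1:
            raise UsageError("need at least one uncertain task (N >= 1)")
        if len(self.probs) != self.N:
            raise UsageError(f"probs has length {len(self.probs)}, expected N={self.N}")
        if any(not (0.0 <= p <= 1.0) for p in self.probs):
            raise UsageError("write probabilities must lie in [0, 1]")
        if not self.t > 0:
            raise UsageError("task cost t must be positive")

    @classmethod
    def uniform(cls, N: int, p: float, t: float = 1.0) -> "TheoryParams":
        return cls(N, (float(p),) * N, t)


@dataclass(frozen=True)
class SpeedupResult:
    """Expected saved duration (units of t) and the dimensionless speedup."""

    gain: float
    speedup: float


def predictive_gain(params: TheoryParams) -> float:
    """Expected saved duration D_N of predictive speculation."""
    probs = list(params.probs) + [1.0]  # P_{N+1} = 1
    total = 0.0
    survive = 1.0  # prod_{j<=i} (1 - P_j)
    for i in range(1, params.N + 1):
        survive *= 1.0 - probs[i - 1]
        total += params.t * i * probs[i] * survive
    return total


def predictive_speedup(params: TheoryParams) -> float:
    """Expected speedup of predictive speculation, S = (N+1)t / ((N+1)t - D_N)."""
    full = (params.N + 1) * params.t
    return full / (full - predictive_gain(params))


def predictive(params: TheoryParams) -> SpeedupResult:
    return SpeedupResult(predictive_gain(params), predictive_speedup(params))


def eager_gain(params: TheoryParams) -> float:
    """Expected saved duration F(N) of eager (restart-on-failure) speculation."""
    return params.t * sum(1.0 - p for p in params.probs)


def eager_speedup(params: TheoryParams) -> float:
    full = (params.N + 1) * params.t
    return full / (full - eager_gain(params))


def eager(params: TheoryParams) -> SpeedupResult:
    return SpeedupResult(eager_gain(params), eager_speedup(params))


def eager_task_count(N: int) -> int:
    """Number of speculative tasks the eager scheme requires: (N²+N)/2 − N."""
    if N < 1:
        raise UsageError("N must be >= 1")
    return (N * N + N) // 2 - N


def realized_gain(write_mask: Sequence[bool], t: float = 1.0) -> float:
    """Saved duration of the predictive scheme for one concrete outcome.

    ``i*t`` when the first writing task has 0-based index ``i`` (i.e. it is
    task ``i+1`` and tasks ``1..i`` did not write); ``N*t`` when none writes.
    """
    for i, wrote in enumerate(write_mask):
        if wrote:
            return i * t
    return len(write_mask) * t


def mc_gain_estimate(
    params: TheoryParams,
    reps: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the predictive gain: (mean, standard error).

    Draws ``reps`` independent write/no-write outcome vectors and averages
    the realized saved duration; unbiased for :func:`predictive_gain`.
    """
    if reps < 1:
        raise UsageError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    writes = rng.random((reps, params.N)) < np.asarray(params.probs)
    any_write = writes.any(axis=1)
    first = np.argmax(writes, axis=1)  # 0 when no write; masked below
    gains = np.where(any_write, first, params.N).astype(float) * params.t
    mean = float(gains.mean())
    se = float(gains.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return mean, se


# ---------------------------------------------------------------------------
# reference-table helpers
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero to ``ndigits`` decimals."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def gain_speedup_table(
    probs: Sequence[float] = (0.25, 0.5, 0.75),
    n_max: int = 7,
    t: float = 1.0,
    mc_reps: int = 0,
    seed: Optional[int] = None,
) -> list[dict]:
    """Predictive gain/speedup rows for uniform write probabilities.

    Returns one dict per (probability, quantity) row with values for
    N = 1..n_max; with ``mc_reps > 0`` adds a sampled-gain row (and its
    standard errors) per probability.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise UsageError(f"probability {p} outside [0, 1]")
        gains, speeds, mc_means, mc_ses = [], [], [], []
        for n in range(1, n_max + 1):
            params = TheoryParams.uniform(n, p, t)
            gains.append(predictive_gain(params))
            speeds.append(predictive_speedup(params))
            if mc_reps:
                m, s = mc_gain_estimate(params, mc_reps, rng)
                mc_means.append(m)
                mc_ses.append(s)
        rows.append({"quantity": "gain", "p": p, "values": gains})
        rows.append({"quantity": "speedup", "p": p, "values": speeds})
        if mc_reps:
            rows.append({"quantity": "gain_mc", "p": p, "values": mc_means})
            rows.append({"quantity": "gain_mc_se", "p": p, "values": mc_ses})
    return rows
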