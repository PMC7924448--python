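"""Serialization glue: run traces, XYZ particle files, stats CSV, flat configs."""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .dag_core import UsageError
from .executor import RunTrace
from .mc_sim import ParticleDomain, SystemState


def trace_to_json(trace: RunTrace, path: Union[str, Path, None] = None, **meta) -> str:
    """Serialize a run trace (plus optional metadata such as seed/config)."""
    payload = {
        "makespan": trace.makespan,
        **meta,
        "records": [r.to_dict() for r in trace.records],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_xyz(
    path: Union[str, Path, io.TextIOBase],
    domains: Sequence[ParticleDomain],
    comment: str = "",
) -> None:
    """Write domains as XYZ text; the element column encodes the domain index."""
    lines = []
    total = sum(len(d.positions) for d in domains)
    lines.append(str(total))
    lines.append(comment)
    for d in domains:
        for x, y, z in d.positions:
            lines.append(f"D{d.id} {x:.17g} {y:.17g} {z:.17g}")
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_xyz(path: Union[str, Path]) -> list[ParticleDomain]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise UsageError(f"{path}: empty XYZ file")
    count = int(lines[0].strip())
    rows = lines[2 : 2 + count]
    by_domain: dict[int, list[list[float]]] = {}
    for row in rows:
        tag, x, y, z = row.split()
        idx = int(tag.lstrip("D"))
        by_domain.setdefault(idx, []).append([float(x), float(y), float(z)])
    return [
        ParticleDomain(i, np.array(by_domain[i])) for i in sorted(by_domain)
    ]


def stats_to_csv(path: Union[str, Path], trajectory: Sequence[float], accept_ratio: float) -> None:
    """Per-sweep total energy plus the overall accept ratio."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["loop", "accept_ratio", "total_energy"])
        for i, e in enumerate(trajectory):
            w.writerow([i + 1, f"{accept_ratio:.6f}", f"{e:.17g}"])


def table_rows_to_csv(rows: list[dict], n_max: int, path=None) -> str:
    """CSV of gain/speedup rows produced by ``gain_speedup_table``."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["quantity", "p"] + [f"N={n}" for n in range(1, n_max + 1)])
    for row in rows:
        w.writerow(
            [row["quantity"], row["p"]] + [f"{v:.6g}" for v in row["values"]]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_config(path: Union[str, Path]) -> dict:
    """Flat ``key = value`` configuration file; values typed by literal parsing."""
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise UsageError(f"bad config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = _parse_value(value)
    return out


def _parse_value(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    if "," in value:
        return tuple(_parse_value(v.strip()) for v in value.split(","))
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        pass
    return value


def write_config(path: Union[str, Path], config: dict) -> None:
    lines = []
    for key, value in config.items():
        if isinstance(value, (tuple, list)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
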