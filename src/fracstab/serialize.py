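"""JSON/CSV serialization of reports, region grids and trajectories.

Floats are written with ``repr`` (shortest round-trip form, 17 significant
digits where needed) so every file re-reads bit-for-bit and identical runs
produce byte-identical output.
"""

from __future__ import annotations

import csv
import io
import json
from typing import Any

import numpy as np

from . import __version__
from .chain import RegionGrid
from .orders import StabilityReport
from .solver import Trajectory

__all__ = [
    "report_to_json",
    "region_to_csv",
    "region_from_csv",
    "trajectory_to_csv",
]


def _header_comments(config: dict[str, Any] | None) -> list[str]:
    lines = [f"# fracstab version: {__version__}"]
    if config:
        for key in sorted(config):
            lines.append(f"# config {key}: {config[key]!r}")
    return lines


def report_to_json(
    report: StabilityReport,
    config: dict[str, Any] | None = None,
    polynomial=None,
) -> str:
    """Serialize a stability report (plus the resolved run config) to JSON."""
    payload: dict[str, Any] = {"fracstab_version": __version__}
    if config is not None:
        payload["config"] = {k: config[k] for k in sorted(config)}
    payload["report"] = report.to_dict()
    if polynomial is not None:
        payload["polynomial_terms"] = [[e, c] for e, c in polynomial.terms]
    return json.dumps(payload, indent=2, default=_json_default) + "\n"


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def region_to_csv(grid: RegionGrid, config: dict[str, Any] | None = None) -> str:
    """Flatten a region grid to CSV: axis1, axis2, min_arg, imfos, verdict."""
    buf = io.StringIO()
    for line in _header_comments(config):
        buf.write(line + "\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([grid.axis1, grid.axis2, "min_arg", "imfos", "verdict"])
    for i, v1 in enumerate(grid.axis1_values):
        for j, v2 in enumerate(grid.axis2_values):
            writer.writerow(
                [repr(float(v1)), repr(float(v2)),
                 repr(float(grid.min_arg[i, j])), repr(float(grid.imfos[i, j])),
                 grid.verdict[i, j]]
            )
    return buf.getvalue()


def region_from_csv(text: str) -> RegionGrid:
    """Rebuild a RegionGrid from :func:`region_to_csv` output (exact round-trip)."""
    rows = [
        line for line in text.splitlines() if line and not line.startswith("#")
    ]
    reader = csv.reader(rows)
    header = next(reader)
    axis1_name, axis2_name = header[0], header[1]
    records = list(reader)
    axis1_values = sorted({float(r[0]) for r in records})
    axis2_values = sorted({float(r[1]) for r in records})
    i_of = {v: i for i, v in enumerate(axis1_values)}
    j_of = {v: j for j, v in enumerate(axis2_values)}
    shape = (len(axis1_values), len(axis2_values))
    min_arg = np.empty(shape)
    imfos = np.empty(shape)
    verdict = np.empty(shape, dtype=object)
    for r in records:
        i, j = i_of[float(r[0])], j_of[float(r[1])]
        min_arg[i, j] = float(r[2])
        imfos[i, j] = float(r[3])
        verdict[i, j] = r[4]
    return RegionGrid(axis1_name, axis2_name,
                      np.array(axis1_values), np.array(axis2_values),
                      min_arg, imfos, verdict.astype(str))


def trajectory_to_csv(traj: Trajectory, config: dict[str, Any] | None = None) -> str:
    """Time series as CSV with columns t, x1, ..., xd."""
    buf = io.StringIO()
    for line in _header_comments(config):
        buf.write(line + "\n")
    writer = csv.writer(buf, lineterminator="\n")
    dim = traj.states.shape[1]
    writer.writerow(["t"] + [f"x{i + 1}" for i in range(dim)])
    for t, row in zip(traj.times, traj.states):
        writer.writerow([repr(float(t))] + [repr(float(v)) for v in row])
    return buf.getvalue()
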