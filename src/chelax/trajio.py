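"""Extended-XYZ trajectory I/O and table/report rendering.

The trajectory dialect is plain extended XYZ: for each frame, line 1 is the
ion count, line 2 a comment of the form ``box="Lx Ly Lz" time=<ps>``, then
one ``<species> x y z`` row per ion.  Coordinates are written with 4
decimals, so a write -> read round trip preserves them to 3 decimals and a
read -> write round trip is byte-identical.
"""

from __future__ import annotations

import io
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .analysis import ChelationStats
from .bd import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "render_report"]

_COMMENT_RE = re.compile(
    r'box="\s*([-\d.eE+]+)\s+([-\d.eE+]+)\s+([-\d.eE+]+)\s*"\s+time=([-\d.eE+]+)'
)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the extended-XYZ dialect."""
    boxes = trajectory.box_per_frame()
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            b = boxes[f]
            fh.write(f"{trajectory.n_ions}\n")
            fh.write(
                f'box="{b[0]:.4f} {b[1]:.4f} {b[2]:.4f}" '
                f"time={trajectory.times[f]:.4f}\n"
            )
            frame = trajectory.frames[f]
            for s, xyz in zip(trajectory.species, frame):
                fh.write(f"{s} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`.

    Malformed frame headers or truncated frames raise ``ValueError`` naming
    the offending line number.
    """
    path = Path(path)
    species: list[str] | None = None
    frames: list[np.ndarray] = []
    boxes: list[list[float]] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if i + 1 >= n_lines:
            raise ValueError(f"{path}:{i + 1}: frame header without comment line")
        m = _COMMENT_RE.search(lines[i + 1])
        if not m:
            raise ValueError(
                f"{path}:{i + 2}: comment line must contain "
                f'box="Lx Ly Lz" time=<ps>, got {lines[i + 1]!r}'
            )
        boxes.append([float(m.group(k)) for k in (1, 2, 3)])
        times.append(float(m.group(4)))
        frame_species: list[str] = []
        coords = np.empty((n, 3))
        for j in range(n):
            lineno = i + 2 + j
            if lineno >= n_lines or not lines[lineno].strip():
                raise ValueError(
                    f"{path}:{lineno + 1}: frame declares {n} ions but the "
                    "file ends early"
                )
            parts = lines[lineno].split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno + 1}: expected '<species> x y z', got "
                    f"{lines[lineno]!r}"
                )
            frame_species.append(parts[0])
            try:
                coords[j] = [float(v) for v in parts[1:]]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno + 1}: non-numeric coordinate in "
                    f"{lines[lineno]!r}"
                ) from None
        if species is None:
            species = frame_species
        elif frame_species != species:
            raise ValueError(
                f"{path}:{i + 3}: ion ordering differs from the first frame"
            )
        frames.append(coords)
        i += 2 + n
    if species is None:
        raise ValueError(f"{path}: file contains no frames")
    boxes_arr = np.array(boxes)
    box = boxes_arr[0] if np.allclose(boxes_arr, boxes_arr[0]) else boxes_arr
    return Trajectory(
        species=species,
        frames=np.stack(frames),
        box=box,
        times=np.array(times),
        provenance={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_COLUMNS = [
    "Average distance (A)",
    "Average minimum distance (A)",
    "Average dwell fraction",
]


def _rows(stats: ChelationStats) -> list[tuple[str, str, str, str]]:
    rows = []
    for name, s in stats.species.items():
        rows.append(
            (
                name,
                f"{s.avg_distance:.2f} ({s.sd_distance:.2f})",
                f"{s.avg_min_distance:.2f} ({s.sd_min_distance:.2f})",
                f"{s.avg_dwell_fraction:.2f} ({s.sd_dwell_fraction:.2f})",
            )
        )
    return rows


def render_report(stats: ChelationStats, format: str = "markdown") -> str:
    """Render a species summary table with "mean (sd)" cells.

    Columns follow the conventional counter-ion report layout: average
    distance, average minimum distance, dwell fraction (all spreads in
    parentheses, 2 decimals).  ``format`` is markdown, csv or json.
    """
    if not stats.species:
        raise ValueError("no species statistics to render")
    if format == "json":
        return json.dumps(stats.as_dict(), indent=2, sort_keys=True)
    rows = _rows(stats)
    if format == "csv":
        buf = io.StringIO()
        buf.write("species," + ",".join(c.replace(",", ";") for c in _COLUMNS) + "\n")
        for row in rows:
            buf.write(",".join(f'"{c}"' if " " in c else c for c in row) + "\n")
        return buf.getvalue()
    if format == "markdown":
        out = [
            "| Counter ion | " + " | ".join(_COLUMNS) + " |",
            "|---" * (len(_COLUMNS) + 1) + "|",
        ]
        for row in rows:
            out.append("| " + " | ".join(row) + " |")
        out.append("")
        out.append(
            f"Spreads in parentheses are population standard deviations "
            f"({stats.mode} aggregation); dwell threshold "
            f"{stats.threshold:.1f} A."
        )
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown report format {format!r}")
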