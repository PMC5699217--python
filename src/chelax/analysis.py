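"""Ion-to-surface distance series, dwell-time fractions, ensemble statistics.

The central observable is the distance from an ion to the van der Waals
surface of the fixed macromolecule:

    d(ion) = min over atoms a of ( ||ion - a||_minimum-image - vdW_radius(a) )

i.e. the distance to the envelope of atom-centred vdW spheres.  It can be
slightly negative when an ion overlaps the surface.  From the per-frame
series of these distances we derive, per ion, the mean distance, the minimum
distance, and the dwell fraction — the fraction of frames in which the ion
sits within a cutoff (3.0 A by default, boundary inclusive) of the surface.
Species-level summaries aggregate the per-ion values over replicate runs,
either pooling all ions of all runs ("pooled") or averaging per-run means
("per_run").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .bd import Trajectory
    from .topology import Structure

__all__ = [
    "IonSurfaceSeries",
    "SpeciesStats",
    "ChelationStats",
    "ion_surface_distance",
    "surface_distances",
    "distance_series",
    "dwell_fraction",
    "summarize",
]

DEFAULT_DWELL_THRESHOLD = 3.0  # A from the vdW surface


def _min_image(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return diff
    return diff - box * np.round(diff / box)


def surface_distances(
    points: np.ndarray,
    structure: "Structure",
    box: Sequence[float] | None = None,
) -> np.ndarray:
    """Distance from each point to the structure's vdW surface (A).

    Vectorised over points; with ``box`` given (edge lengths of an
    orthorhombic periodic cell) every point-atom pair uses the minimum-image
    convention.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if structure.n_atoms == 0:  # defensive; Structure forbids this
        raise ValueError("structure has no atoms")
    b = None if box is None else np.asarray(box, dtype=float).reshape(3)
    diff = pts[:, None, :] - structure.coords[None, :, :]
    diff = _min_image(diff, b)
    r = np.sqrt((diff * diff).sum(axis=-1))
    return (r - structure.radii[None, :]).min(axis=1)


def ion_surface_distance(
    ion_position: Sequence[float],
    structure: "Structure",
    box: Sequence[float] | None = None,
) -> float:
    """Distance (A) from one ion to the vdW surface of the macromolecule."""
    return float(surface_distances(np.asarray(ion_position), structure, box)[0])


@dataclass
class IonSurfaceSeries:
    """Per-ion distance-to-surface time series for one run.

    ``distances`` has shape (n_ions, n_frames); all ions of a run share the
    frame axis.  ``species`` labels each ion; ``run_id`` identifies the
    replicate the series came from.
    """

    distances: np.ndarray
    species: list[str]
    run_id: str = ""

    def __post_init__(self) -> None:
        self.distances = np.atleast_2d(np.asarray(self.distances, dtype=float))
        self.species = list(self.species)
        if self.distances.shape[0] != len(self.species):
            raise ValueError("one species label per ion is required")
        if self.distances.shape[1] == 0:
            raise ValueError("series must contain at least one frame")

    @property
    def n_ions(self) -> int:
        return self.distances.shape[0]

    @property
    def n_frames(self) -> int:
        return self.distances.shape[1]

    def for_species(self, name: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.species) if s == name]
        return self.distances[idx]


def distance_series(
    trajectory: "Trajectory",
    structure: "Structure",
    species: str | Iterable[str] | None = None,
    chunk_frames: int = 256,
) -> IonSurfaceSeries:
    """Distance-to-surface series for every (selected) ion of a trajectory.

    ``species`` may be one label, an iterable of labels, or None for all
    ions.  Frame order is preserved.  Raises if a requested species is not
    present, naming the species that are.
    """
    labels = list(trajectory.species)
    if species is None:
        sel = np.arange(len(labels))
    else:
        wanted = [species] if isinstance(species, str) else list(species)
        available = sorted(set(labels))
        missing = [w for w in wanted if w not in labels]
        if missing:
            raise ValueError(
                f"species {missing} not present in trajectory; available: "
                f"{available}"
            )
        sel = np.array([i for i, s in enumerate(labels) if s in wanted])
    frames = trajectory.frames
    n_frames = frames.shape[0]
    out = np.empty((len(sel), n_frames))
    boxes = trajectory.box_per_frame()
    const_box = np.allclose(boxes, boxes[0])
    for start in range(0, n_frames, chunk_frames):
        stop = min(start + chunk_frames, n_frames)
        chunk = frames[start:stop][:, sel, :]  # (f, k, 3)
        diff = chunk[:, :, None, :] - structure.coords[None, None, :, :]
        if const_box:
            b = boxes[0]
            diff -= b * np.round(diff / b)
        else:
            b = boxes[start:stop][:, None, None, :]
            diff -= b * np.round(diff / b)
        r = np.sqrt((diff * diff).sum(axis=-1))
        out[:, start:stop] = (r - structure.radii[None, None, :]).min(axis=2).T
    return IonSurfaceSeries(
        distances=out,
        species=[labels[i] for i in sel],
        run_id=str(trajectory.provenance.get("run_id", "")),
    )


def dwell_fraction(
    series: Sequence[float] | np.ndarray,
    threshold: float = DEFAULT_DWELL_THRESHOLD,
) -> float:
    """Fraction of frames in which the ion is within ``threshold`` of the
    surface (boundary inclusive)."""
    d = np.asarray(series, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty distance series")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return float(np.count_nonzero(d <= threshold) / d.size)


@dataclass(frozen=True)
class SpeciesStats:
    """Summary row for one ion species: means with (population) spreads."""

    avg_distance: float
    sd_distance: float
    avg_min_distance: float
    sd_min_distance: float
    avg_dwell_fraction: float
    sd_dwell_fraction: float
    n_ions: int
    n_runs: int

    def as_dict(self) -> dict:
        return {
            "avg_distance": self.avg_distance,
            "sd_distance": self.sd_distance,
            "avg_min_distance": self.avg_min_distance,
            "sd_min_distance": self.sd_min_distance,
            "avg_dwell_fraction": self.avg_dwell_fraction,
            "sd_dwell_fraction": self.sd_dwell_fraction,
            "n_ions": self.n_ions,
            "n_runs": self.n_runs,
        }


@dataclass
class ChelationStats:
    """Species-level chelation summary over one or more replicate runs."""

    species: dict[str, SpeciesStats]
    mode: str
    threshold: float

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "species": {k: v.as_dict() for k, v in self.species.items()},
        }


def _per_ion_values(run: IonSurfaceSeries, threshold: float) -> dict[str, np.ndarray]:
    """(mean, min, dwell) per ion, grouped by species, for one run."""
    means = run.distances.mean(axis=1)
    mins = run.distances.min(axis=1)
    dwells = (run.distances <= threshold).mean(axis=1)
    out: dict[str, np.ndarray] = {}
    for name in sorted(set(run.species)):
        idx = [i for i, s in enumerate(run.species) if s == name]
        out[name] = np.stack([means[idx], mins[idx], dwells[idx]], axis=1)
    return out


def summarize(
    runs: IonSurfaceSeries | Sequence[IonSurfaceSeries],
    threshold: float = DEFAULT_DWELL_THRESHOLD,
    mode: str = "pooled",
) -> ChelationStats:
    """Aggregate per-ion statistics over replicate runs.

    mode="pooled": per-ion (mean distance, min distance, dwell fraction)
    values of all ions of all runs are pooled; the reported spread is the
    population standard deviation over that pool.

    mode="per_run": per-run means of the per-ion values are computed first;
    the report is the mean over runs with the population standard deviation
    over the run means (the spread between independent replicates).
    """
    if isinstance(runs, IonSurfaceSeries):
        runs = [runs]
    if len(runs) == 0:
        raise ValueError("at least one run is required")
    if mode not in {"pooled", "per_run"}:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    per_run = [_per_ion_values(run, threshold) for run in runs]
    all_species = sorted({name for run in per_run for name in run})
    stats: dict[str, SpeciesStats] = {}
    for name in all_species:
        blocks = [run[name] for run in per_run if name in run]
        if mode == "pooled":
            pool = np.concatenate(blocks, axis=0)  # (total ions, 3)
            mean = pool.mean(axis=0)
            sd = pool.std(axis=0, ddof=0)
            n_ions = pool.shape[0]
        else:
            run_means = np.stack([b.mean(axis=0) for b in blocks])  # (runs, 3)
            mean = run_means.mean(axis=0)
            sd = run_means.std(axis=0, ddof=0)
            n_ions = int(sum(b.shape[0] for b in blocks))
        stats[name] = SpeciesStats(
            avg_distance=float(mean[0]),
            sd_distance=float(sd[0]),
            avg_min_distance=float(mean[1]),
            sd_min_distance=float(sd[1]),
            avg_dwell_fraction=float(mean[2]),
            sd_dwell_fraction=float(sd[2]),
            n_ions=n_ions,
            n_runs=len(blocks),
        )
    return ChelationStats(species=stats, mode=mode, threshold=float(threshold))
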