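"""Radial distribution functions of ion species around the solute.

g(r) is the ratio of the observed ion density in a spherical shell at
distance r from the reference to the ideal uniform density N/V.  With one
reference point per frame the estimator is

    g(r_bin) = counts_bin / sum_frames [ N_sel * 4 pi r_c^2 dr / V_frame ],

where r_c is the bin centre and the denominator uses the instantaneous box
volume of each frame (constant for BD input, ready for NPT input).  Two
reference modes are supported and labelled in the result: the solute's
geometric centre ("com") or the nearest solute atom centre ("nearest-atom",
for surface-resolved curves).  Replicate runs are combined by per-bin
averaging of g with summed counts, and a windowed self-comparison flags
non-stationary (non-converged) trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .bd import Trajectory
    from .topology import Structure

__all__ = [
    "RDFResult",
    "WindowConvergence",
    "compute_rdf",
    "average_rdf",
    "window_convergence",
]


@dataclass
class RDFResult:
    """Binned g(r) with raw counts and normalisation metadata."""

    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    reference: str
    n_frames: int
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.g.shape[0] != self.bin_edges.shape[0] - 1:
            raise ValueError("one g value per bin required")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.species = tuple(self.species)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def same_binning(self, other: "RDFResult") -> bool:
        return (
            self.bin_edges.shape == other.bin_edges.shape
            and bool(np.allclose(self.bin_edges, other.bin_edges))
            and self.reference == other.reference
        )


def _reference_distances(
    frames: np.ndarray,
    boxes: np.ndarray,
    structure: "Structure",
    reference: str,
) -> np.ndarray:
    """Minimum-image reference->ion distances, flattened over frames/ions."""
    if reference == "com":
        ref = structure.centroid()
        diff = frames - ref[None, None, :]
        diff -= boxes[:, None, :] * np.round(diff / boxes[:, None, :])
        return np.sqrt((diff * diff).sum(axis=-1)).ravel()
    if reference == "nearest-atom":
        out = np.empty(frames.shape[:2])
        chunk = max(1, 200_000 // max(1, structure.n_atoms))
        for start in range(0, frames.shape[0], chunk):
            stop = min(start + chunk, frames.shape[0])
            d = frames[start:stop][:, :, None, :] - structure.coords[None, None, :, :]
            b = boxes[start:stop][:, None, None, :]
            d -= b * np.round(d / b)
            out[start:stop] = np.sqrt((d * d).sum(axis=-1)).min(axis=2)
        return out.ravel()
    raise ValueError(f"unknown reference mode {reference!r}")


def compute_rdf(
    trajectory: "Trajectory",
    structure: "Structure",
    species: str | Iterable[str] | None = None,
    bin_width: float = 0.1,
    r_max: float | None = None,
    reference: str = "com",
) -> RDFResult:
    """g(r) of the selected ion species around the solute reference point.

    ``r_max`` defaults to half the smallest box edge and may not exceed it
    (minimum-image distances are only complete below L/2).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    boxes = trajectory.box_per_frame()
    half_min_edge = float(boxes.min()) / 2.0
    if r_max is None:
        r_max = half_min_edge
    if r_max > half_min_edge + 1e-9:
        raise ValueError(
            f"r_max {r_max} A exceeds half the smallest box edge "
            f"({half_min_edge:.3f} A)"
        )
    labels = list(trajectory.species)
    if species is None:
        wanted = sorted(set(labels))
    else:
        wanted = [species] if isinstance(species, str) else list(species)
    sel = [i for i, s in enumerate(labels) if s in wanted]
    if not sel:
        raise ValueError(
            f"no ions of species {wanted} in trajectory; available: "
            f"{sorted(set(labels))}"
        )
    frames = trajectory.frames[:, sel, :]
    n_frames = frames.shape[0]
    n_sel = len(sel)
    n_bins = int(np.ceil(r_max / bin_width - 1e-9))
    edges = bin_width * np.arange(n_bins + 1)
    dist = _reference_distances(frames, boxes, structure, reference)
    counts, _ = np.histogram(dist, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    volumes = boxes.prod(axis=1)  # per-frame box volume
    inv_v_sum = float(np.sum(1.0 / volumes))
    ideal = n_sel * 4.0 * np.pi * centers**2 * bin_width * inv_v_sum
    g = np.where(ideal > 0, counts / np.maximum(ideal, 1e-300), 0.0)
    return RDFResult(
        bin_edges=edges,
        g=g,
        counts=counts,
        reference=reference,
        n_frames=n_frames,
        species=tuple(sorted(set(labels[i] for i in sel))),
    )


def average_rdf(results: Sequence[RDFResult]) -> RDFResult:
    """Run-averaged RDF: per-bin mean of g, counts and frames summed.

    All inputs must share binning and reference mode; the average is
    invariant under permutation of its inputs.
    """
    if len(results) == 0:
        raise ValueError("need at least one RDF to average")
    first = results[0]
    for r in results[1:]:
        if not first.same_binning(r):
            raise ValueError("cannot average RDFs with different binning or reference")
    g = np.mean([r.g for r in results], axis=0)
    counts = np.sum([r.counts for r in results], axis=0)
    return RDFResult(
        bin_edges=first.bin_edges.copy(),
        g=g,
        counts=counts,
        reference=first.reference,
        n_frames=int(sum(r.n_frames for r in results)),
        species=first.species,
    )


@dataclass
class WindowConvergence:
    """Per-window RDFs and their divergence from the full-window RDF.

    ``divergences[i] = max_bins |g_window_i - g_full|``; ``converged`` is
    True when the penultimate window (the largest strict sub-window) agrees
    with the full window within ``tolerance``.
    """

    windows: list[tuple[int, int]]
    results: list[RDFResult]
    divergences: list[float]
    tolerance: float
    converged: bool


def window_convergence(
    trajectory: "Trajectory",
    structure: "Structure",
    species: str | Iterable[str] | None = None,
    windows: Sequence[tuple[int, int]] | None = None,
    bin_width: float = 0.1,
    r_max: float | None = None,
    reference: str = "com",
    tolerance: float = 0.1,
) -> WindowConvergence:
    """Compare RDFs over increasingly long windows of the trajectory.

    Default windows are the first third, first two thirds, and the full
    trajectory.  A stationary (equilibrated) trajectory shows no significant
    difference between the longer windows; a drifting one does.
    """
    n = trajectory.n_frames
    if windows is None:
        if n < 3:
            raise ValueError("need at least 3 frames for default windows")
        windows = [(0, n // 3), (0, 2 * n // 3), (0, n)]
    windows = [(int(a), int(b)) for a, b in windows]
    for (a, b) in windows:
        if not (0 <= a < b <= n):
            raise ValueError(f"window ({a}, {b}) outside trajectory of {n} frames")
    prev_len = 0
    for (a, b) in windows:
        if b - a < prev_len:
            raise ValueError("windows must be increasing in length")
        prev_len = b - a
    results = [
        compute_rdf(
            trajectory.window(a, b), structure, species,
            bin_width=bin_width, r_max=r_max, reference=reference,
        )
        for (a, b) in windows
    ]
    full = results[-1]
    divergences = [float(np.abs(r.g - full.g).max()) for r in results]
    pen = divergences[-2] if len(divergences) >= 2 else 0.0
    return WindowConvergence(
        windows=list(windows),
        results=results,
        divergences=divergences,
        tolerance=float(tolerance),
        converged=bool(pen <= tolerance),
    )
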