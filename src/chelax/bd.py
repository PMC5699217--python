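"""Overdamped Brownian dynamics of point ions around a frozen macromolecule.

The propagator is the Euler–Maruyama discretisation of overdamped Langevin
dynamics,

    x <- x + (D / kT) F dt + sqrt(2 D dt) xi,      xi ~ N(0, 1) per coordinate,

with all energies expressed in units of kT so the drift term reduces to
``D * F * dt`` with F in kT/A.  Forces are

* screened Coulomb (Yukawa) between every ion and every charged solute site
  and between ion pairs:  u(r) = lB * q_i q_j * exp(-r/lambda) / r, where
  lB is the Bjerrum length (7.1 A in water at 300 K) scaled by an optional
  dielectric factor and lambda is the Debye screening length;
* a purely repulsive shifted-truncated Lennard-Jones (WCA) core that
  prevents ion/site overlap.

All pair distances use the minimum-image convention in an orthorhombic
periodic box; the solute is frozen.  An optional square binding well
(centred on a solute site) is handled by a Metropolis accept/reject step on
the proposed displacement, which samples the discontinuous well potential
exactly (the Gaussian proposal is symmetric); with no other forces the
stationary distribution of the well is therefore exactly Boltzmann.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .builder import IonSet
from .topology import Structure

__all__ = [
    "BindingWell",
    "BDParams",
    "Trajectory",
    "TimestepError",
    "bjerrum_length",
    "simulate",
    "square_well_occupancy",
]

# Bjerrum length lB = e^2 / (4 pi eps0 eps_r kB T), evaluated in Angstrom.
_E = 1.602176634e-19  # C
_EPS0 = 8.8541878128e-12  # F/m
_KB = 1.380649e-23  # J/K


def bjerrum_length(temperature: float = 300.0, eps_r: float = 78.5) -> float:
    """Bjerrum length in Angstrom (7.10 A in water at 300 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    metres = _E * _E / (4.0 * math.pi * _EPS0 * eps_r * _KB * temperature)
    return metres * 1e10


class TimestepError(RuntimeError):
    """A single step displaced an ion further than a quarter box edge."""


@dataclass(frozen=True)
class BindingWell:
    """Square attractive well centred on one solute site.

    ``site_index`` indexes ``structure.coords``; ``radius`` (A) is the well
    boundary measured from that site's centre; ``depth`` (kT, >= 0) is the
    energy gained inside the well.
    """

    site_index: int
    radius: float
    depth: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("well radius must be > 0")
        if self.depth < 0:
            raise ValueError("well depth must be >= 0")


@dataclass
class BDParams:
    """Parameters of a Brownian-dynamics run.

    Dynamics: ``timestep`` (ps), ``n_steps``, ``save_interval`` (steps per
    saved frame), ``box_edges`` (A), ``seed``.  Interactions:
    ``screening_length`` (Debye length, A; default 8 A, roughly 0.12 M ionic
    strength), ``dielectric_scaling`` (multiplies the Bjerrum coupling),
    ``lj_epsilon`` (kT) and ``lj_sigma`` (A) for the WCA core, and an
    optional :class:`BindingWell`.  ``diffusion`` optionally overrides the
    per-ion diffusion coefficients by species label (A^2/ps).
    ``provenance`` is free-form metadata (e.g. the protocol of the study a
    run emulates) and never affects the dynamics.
    """

    box_edges: Sequence[float]
    n_steps: int
    timestep: float = 0.01  # ps
    save_interval: int = 10
    temperature: float = 300.0  # K
    screening_length: float = 8.0  # A
    dielectric_scaling: float = 1.0
    lj_epsilon: float = 1.0  # kT
    lj_sigma: float = 3.0  # A
    binding_well: BindingWell | None = None
    diffusion: dict[str, float] | None = None
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.box_edges = np.asarray(self.box_edges, dtype=float).reshape(3)
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if np.any(self.box_edges <= 0):
            raise ValueError("box edges must be positive")
        if self.screening_length <= 0:
            raise ValueError("screening length must be > 0")


@dataclass
class Trajectory:
    """Frames of ion coordinates with per-frame box and time metadata.

    ``frames`` has shape (n_frames, n_ions, 3) in A, coordinates wrapped
    into the primary box; ``box`` is either one (3,) edge vector shared by
    all frames or a (n_frames, 3) array; ``times`` (ps) is one entry per
    frame.  ``provenance`` records seed and parameters.
    """

    species: list[str]
    frames: np.ndarray
    box: np.ndarray
    times: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_ions, 3)")
        self.species = list(self.species)
        if len(self.species) != self.frames.shape[1]:
            raise ValueError("one species label per ion required")
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        if self.times.shape[0] != self.frames.shape[0]:
            raise ValueError("one time per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_ions(self) -> int:
        return self.frames.shape[1]

    def box_per_frame(self) -> np.ndarray:
        """Box edges as a (n_frames, 3) array regardless of storage."""
        if self.box.ndim == 1:
            return np.broadcast_to(self.box, (self.n_frames, 3))
        return self.box

    def window(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory of frames [start, stop)."""
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(
                f"window [{start}, {stop}) outside trajectory of "
                f"{self.n_frames} frames"
            )
        box = self.box if self.box.ndim == 1 else self.box[start:stop]
        return Trajectory(
            species=list(self.species),
            frames=self.frames[start:stop],
            box=box,
            times=self.times[start:stop],
            provenance=dict(self.provenance),
        )


def _pair_forces(
    x: np.ndarray,
    q: np.ndarray,
    sites: np.ndarray,
    site_q: np.ndarray,
    box: np.ndarray,
    coupling: float,
    lam: float,
    eps: float,
    sigma: float,
    r_cut: float,
) -> np.ndarray:
    """Total force (kT/A) on each ion from solute sites and other ions."""
    n = x.shape[0]
    F = np.zeros((n, 3))
    sigma2 = sigma * sigma
    wca_cut2 = (2.0 ** (1.0 / 3.0)) * sigma2  # (2^(1/6) sigma)^2

    def accumulate(diff: np.ndarray, qq: np.ndarray, self_pairs: bool) -> np.ndarray:
        # diff: (n, m, 3) minimum-image separations x_i - y_j
        r2 = (diff * diff).sum(axis=-1)
        if self_pairs:
            np.fill_diagonal(r2, np.inf)
        r2 = np.maximum(r2, 1e-12)
        r = np.sqrt(r2)
        coef = np.zeros_like(r2)
        if coupling != 0.0:
            mask = r < r_cut
            yuk = coupling * qq * np.exp(-r / lam) * (1.0 / r2 + 1.0 / (lam * r))
            coef += np.where(mask, yuk / r, 0.0)
        if eps > 0.0:
            mask = r2 < wca_cut2
            sr2 = sigma2 / r2
            sr6 = sr2 * sr2 * sr2
            wca = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
            coef += np.where(mask, wca, 0.0)
        return np.einsum("ij,ijk->ik", coef, diff)

    if sites.shape[0] > 0:
        d = x[:, None, :] - sites[None, :, :]
        d -= box * np.round(d / box)
        F += accumulate(d, q[:, None] * site_q[None, :], self_pairs=False)
    if n > 1:
        d = x[:, None, :] - x[None, :, :]
        d -= box * np.round(d / box)
        F += accumulate(d, q[:, None] * q[None, :], self_pairs=True)
    return F


def simulate(structure: Structure, ions: IonSet, params: BDParams) -> Trajectory:
    """Propagate ions by Euler–Maruyama Brownian dynamics; return frames.

    The solute is frozen; ion coordinates are wrapped into the primary box
    in every saved frame.  Bitwise reproducible for a given seed.  Raises
    :class:`TimestepError` if any single-step displacement exceeds a
    quarter of the smallest box edge.
    """
    box = np.asarray(params.box_edges, dtype=float).reshape(3)
    x = ions.positions.copy()
    x -= box * np.floor(x / box)  # wrap into [0, box)
    n = ions.n_ions
    if n == 0:
        raise ValueError("no ions to simulate")
    q = ions.charges.copy()
    D = ions.diffusion.copy()
    if params.diffusion:
        for i, lbl in enumerate(ions.labels):
            if lbl in params.diffusion:
                D[i] = params.diffusion[lbl]
    if np.any(D <= 0):
        raise ValueError("all diffusion coefficients must be > 0")
    dt = params.timestep
    drift = (D * dt)[:, None]
    noise_amp = np.sqrt(2.0 * D * dt)[:, None]
    coupling = bjerrum_length(params.temperature) * params.dielectric_scaling
    if not np.any(structure.charges != 0) and not np.any(q != 0):
        coupling = 0.0
    lam = params.screening_length
    r_cut = 0.5 * float(box.min())
    max_disp = 0.25 * float(box.min())
    well = params.binding_well
    if well is not None:
        if not (0 <= well.site_index < structure.n_atoms):
            raise ValueError("binding well site index out of range")
        well_center = structure.coords[well.site_index]
        well_r2 = well.radius * well.radius
    interacting = coupling != 0.0 or params.lj_epsilon > 0.0
    rng = np.random.default_rng(params.seed)

    n_saved = params.n_steps // params.save_interval
    frames = np.empty((n_saved, n, 3))
    times = np.empty(n_saved)
    k = 0
    for step in range(1, params.n_steps + 1):
        if interacting:
            F = _pair_forces(
                x, q, structure.coords, structure.charges, box,
                coupling, lam, params.lj_epsilon, params.lj_sigma, r_cut,
            )
            disp = drift * F + noise_amp * rng.standard_normal((n, 3))
        else:
            disp = noise_amp * rng.standard_normal((n, 3))
        if np.abs(disp).max() > max_disp:
            raise TimestepError(
                f"step {step}: displacement {np.abs(disp).max():.2f} A "
                f"exceeds a quarter box edge ({max_disp:.2f} A); reduce the "
                "timestep"
            )
        x_new = x + disp
        if well is not None:
            d_old = x - well_center
            d_old -= box * np.round(d_old / box)
            d_new = x_new - well_center
            d_new -= box * np.round(d_new / box)
            in_old = (d_old * d_old).sum(axis=1) <= well_r2
            in_new = (d_new * d_new).sum(axis=1) <= well_r2
            dU = well.depth * (in_old.astype(float) - in_new.astype(float))
            accept = (dU <= 0.0) | (rng.random(n) < np.exp(-np.maximum(dU, 0.0)))
            x_new = np.where(accept[:, None], x_new, x)
        x = x_new - box * np.floor(x_new / box)
        if step % params.save_interval == 0:
            frames[k] = x
            times[k] = step * dt
            k += 1
    return Trajectory(
        species=list(ions.labels),
        frames=frames,
        box=box.copy(),
        times=times,
        provenance={
            "seed": params.seed,
            "timestep_ps": dt,
            "n_steps": params.n_steps,
            "save_interval": params.save_interval,
            "temperature_K": params.temperature,
            "screening_length_A": lam,
            "dielectric_scaling": params.dielectric_scaling,
            "lj_epsilon_kT": params.lj_epsilon,
            "lj_sigma_A": params.lj_sigma,
            **({"protocol": params.provenance} if params.provenance else {}),
        },
    )


def square_well_occupancy(
    well_radius: float, well_depth: float, box_volume: float
) -> float:
    """Equilibrium probability that one ideal ion sits inside a square well.

    For a well of volume V_b = (4/3) pi r^3 and depth epsilon (kT) in a box
    of volume V, Boltzmann weighting gives

        p = V_b e^eps / (V_b e^eps + (V - V_b)),

    exactly, for a single non-interacting ion.  Depth 0 reduces to V_b/V.
    """
    if well_depth < 0:
        raise ValueError("well depth must be >= 0")
    v_b = 4.0 / 3.0 * math.pi * well_radius**3
    if not (0 < v_b < box_volume):
        raise ValueError("well volume must be positive and below box volume")
    w = v_b * math.exp(well_depth)
    return w / (w + (box_volume - v_b))
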