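"""System composition arithmetic and initial ion placement.

Molarity <-> ion-count conversion uses the simulation-box volume directly
(count = c * N_A * V, with V in A^3), rounding to the nearest integer.
Charge neutrality is enforced by topping the composition up with a
designated monovalent neutralizer (Cl- by default).  Initial configurations
place every counter ion on a shell a fixed distance (8.00 A by default)
from the solute's van der Waals surface, with a minimum ion-ion separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import ion_surface_distance, surface_distances
from .topology import Structure

__all__ = [
    "AVOGADRO",
    "IonSpecies",
    "DEFAULT_SPECIES",
    "Composition",
    "IonSet",
    "ion_count_for_concentration",
    "concentration_from_count",
    "neutralize",
    "place_ions_on_shell",
    "PlacementError",
]

AVOGADRO = 6.02214e23  # mol^-1

#: litres per cubic Angstrom
_L_PER_A3 = 1e-27


@dataclass(frozen=True)
class IonSpecies:
    """An ion species: label, valence (e), diffusion coefficient, radius.

    The diffusion coefficients are standard dilute-solution values at 300 K
    in A^2/ps; radii are the vdW values used for reporting and placement.
    """

    name: str
    valence: int
    diffusion: float = 0.1  # A^2/ps
    radius: float = 2.0  # A


DEFAULT_SPECIES: dict[str, IonSpecies] = {
    "Ca": IonSpecies("Ca", +2, diffusion=0.079, radius=2.31),
    "Na": IonSpecies("Na", +1, diffusion=0.133, radius=2.27),
    "Cl": IonSpecies("Cl", -1, diffusion=0.203, radius=1.75),
    "K": IonSpecies("K", +1, diffusion=0.196, radius=2.75),
    "Mg": IonSpecies("Mg", +2, diffusion=0.071, radius=1.73),
}


def ion_count_for_concentration(concentration: float, box_volume: float) -> int:
    """Ion count matching a molar concentration in a box of given volume.

    ``concentration`` in mol/L, ``box_volume`` in A^3.  Rounds to the
    nearest integer, ties away from zero — e.g. 0.115 M in 460,000 A^3
    gives 32 ions, 0.115 M in 75,000 A^3 gives 5.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if box_volume <= 0:
        raise ValueError("box volume must be > 0")
    exact = concentration * AVOGADRO * box_volume * _L_PER_A3
    return int(math.floor(exact + 0.5))


def concentration_from_count(count: int, box_volume: float) -> float:
    """Molar concentration of ``count`` ions in a box of ``box_volume`` A^3."""
    if box_volume <= 0:
        raise ValueError("box volume must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (AVOGADRO * box_volume * _L_PER_A3)


@dataclass
class Composition:
    """Integer ion counts per species, charge-neutral with the solute.

    ``counts`` maps species name -> count (includes any auto-added
    neutralizer); ``valences`` maps species name -> valence.
    """

    counts: dict[str, int]
    valences: dict[str, int]
    solute_charge: int = 0

    def __post_init__(self) -> None:
        for name, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {name}")
            if name not in self.valences:
                raise ValueError(f"no valence given for {name}")

    @property
    def total_ion_charge(self) -> int:
        return sum(n * self.valences[s] for s, n in self.counts.items())

    @property
    def is_neutral(self) -> bool:
        return self.total_ion_charge + self.solute_charge == 0

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "valences": dict(self.valences),
            "solute_charge": self.solute_charge,
            "neutral": self.is_neutral,
        }


def neutralize(
    solute_charge: int,
    fixed_species: dict[str, tuple[int, int]],
    neutralizer: tuple[str, int] = ("Cl", -1),
) -> Composition:
    """Complete a composition so total charge (solute + ions) is exactly 0.

    ``fixed_species`` maps name -> (valence, count); these counts are kept
    as given.  The minimal count of the monovalent ``neutralizer`` (name,
    valence +-1) is added to cancel the remaining charge; if the system is
    already neutral nothing is added.  Raises if the residual charge has
    the same sign as the neutralizer (neutrality unreachable).
    """
    nz_name, nz_val = neutralizer
    if nz_val not in (-1, +1):
        raise ValueError("neutralizer must be monovalent (+1 or -1)")
    counts = {name: int(c) for name, (v, c) in fixed_species.items()}
    valences = {name: int(v) for name, (v, c) in fixed_species.items()}
    residual = int(solute_charge) + sum(
        valences[s] * counts[s] for s in counts
    )
    need = 0
    if residual != 0:
        if residual * nz_val > 0:
            raise ValueError(
                f"cannot neutralize residual charge {residual:+d} e with "
                f"{nz_name} (valence {nz_val:+d}); designate a neutralizer "
                "of the opposite sign"
            )
        need = -residual // nz_val
    if nz_name in counts:
        counts[nz_name] += need
        if valences[nz_name] != nz_val:
            raise ValueError(f"conflicting valence for {nz_name}")
    elif need > 0:
        counts[nz_name] = need
        valences[nz_name] = nz_val
    return Composition(counts=counts, valences=valences, solute_charge=int(solute_charge))


@dataclass
class IonSet:
    """Mobile ions of an initial configuration or trajectory frame.

    Parallel arrays over ions: ``labels`` (species name), ``positions``
    (n, 3) in A, ``charges`` in e, ``diffusion`` in A^2/ps.
    """

    labels: list[str]
    positions: np.ndarray
    charges: np.ndarray
    diffusion: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        self.diffusion = np.asarray(self.diffusion, dtype=float).reshape(n)
        self.labels = list(self.labels)
        if len(self.labels) != n:
            raise ValueError("one label per ion required")

    @property
    def n_ions(self) -> int:
        return self.positions.shape[0]


class PlacementError(RuntimeError):
    """Shell placement could not satisfy its constraints."""


def place_ions_on_shell(
    structure: Structure,
    composition: Composition,
    box_edges,
    shell: float = 8.00,
    seed: int = 0,
    species_table: dict[str, IonSpecies] | None = None,
    min_separation: float = 2.5,
    tolerance: float = 5e-3,
    max_attempts_per_ion: int = 400,
) -> IonSet:
    """Place every ion of ``composition`` at ``shell`` A from the solute's
    vdW surface, randomly distributed in direction.

    The solute is assumed centred in the box (``box_edges``, A).  For each
    ion a random direction from the solute centroid is drawn and the radial
    coordinate is bisected until the surface distance matches ``shell``
    within ``tolerance``; candidates closer than ``min_separation`` to an
    already placed ion (minimum image) or outside the box are rejected.
    Deterministic for a given seed.  Raises :class:`PlacementError`
    reporting the achieved count when the retry budget is exhausted.
    """
    if shell <= 0:
        raise ValueError("shell distance must be > 0")
    box = np.asarray(box_edges, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    table = species_table or DEFAULT_SPECIES
    center = structure.centroid()
    extent = float(
        np.linalg.norm(structure.coords - center, axis=1).max() + structure.radii.max()
    )
    t_hi0 = extent + shell + 2.0

    labels: list[str] = []
    charges: list[float] = []
    diffusion: list[float] = []
    placed: list[np.ndarray] = []
    order = sorted(composition.counts)
    total = sum(composition.counts.values())
    for name in order:
        if name in table:
            sp = table[name]
        else:
            sp = IonSpecies(name, composition.valences[name])
        for _ in range(composition.counts[name]):
            ok = False
            for _attempt in range(max_attempts_per_ion):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                # bisection on the radial coordinate from the centroid
                t_lo, t_hi = 0.0, t_hi0
                while ion_surface_distance(center + t_hi * u, structure) < shell:
                    t_hi *= 1.5
                for _ in range(60):
                    t_mid = 0.5 * (t_lo + t_hi)
                    d = ion_surface_distance(center + t_mid * u, structure)
                    if d < shell:
                        t_lo = t_mid
                    else:
                        t_hi = t_mid
                    if t_hi - t_lo < tolerance * 0.1:
                        break
                pos = center + 0.5 * (t_lo + t_hi) * u
                if abs(ion_surface_distance(pos, structure) - shell) > tolerance:
                    continue
                if np.any(pos < 0) or np.any(pos >= box):
                    continue
                if placed:
                    diff = pos[None, :] - np.array(placed)
                    diff -= box * np.round(diff / box)
                    if np.sqrt((diff * diff).sum(axis=1)).min() < min_separation:
                        continue
                ok = True
                break
            if not ok:
                raise PlacementError(
                    f"could only place {len(placed)} of {total} ions at "
                    f"{shell} A from the surface with min separation "
                    f"{min_separation} A in box {box.tolist()}"
                )
            placed.append(pos)
            labels.append(name)
            charges.append(float(composition.valences[name]))
            diffusion.append(sp.diffusion)
    return IonSet(
        labels=labels,
        positions=np.array(placed).reshape(-1, 3),
        charges=np.array(charges),
        diffusion=np.array(diffusion),
    )
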