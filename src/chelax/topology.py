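"""Molecular structures, van der Waals radii, and the dendrimer charge model.

A :class:`Structure` is the fixed macromolecule (the chelator) against whose
van der Waals surface ion distances are measured.  Structures can be parsed
from PDB files or a plain-text atom table, or generated procedurally as
coarse-grained templates: carboxylate-terminated PAMAM half-generation
dendrimers are modelled as ``-1 e`` terminal sites on a sphere, and EDTA as a
fixed four-site tetrahedral template.

The generation model for carboxyl-terminated (half-generation) PAMAM built
from an ethylenediamine core follows the standard doubling recursion: each
full generation doubles the terminal-group count, so a 4-branch core gives
``4 * 2**(floor(g) + 1)`` terminal COOH groups at generation ``g``.  Fully
deprotonated, each terminal carboxylate carries ``-1 e``, and the theoretical
chelation capacity for an ion of valence ``v`` is ``floor(|net charge| / v)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BONDI_RADII",
    "RadiiTable",
    "Structure",
    "GenerationSpec",
    "UnknownElementError",
    "load_structure",
    "write_structure",
    "surface_group_count",
    "net_charge_deprotonated",
    "theoretical_chelation_capacity",
    "coarse_dendrimer",
    "edta_template",
]

#: Bondi (1964) van der Waals radii in Angstrom, extended with the Mantina
#: et al. (2009) values for main-group metals that Bondi did not tabulate.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "Li": 1.81,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27,
    "Mg": 1.73,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "K": 2.75,
    "Ca": 2.31,
    "Br": 1.85,
    "I": 1.98,
    # Generic coarse-grained bead used by the procedural templates.
    "X": 2.00,
}


class UnknownElementError(KeyError):
    """Raised when a structure uses an element absent from the radii table."""


@dataclass(frozen=True)
class RadiiTable:
    """Element symbol -> van der Waals radius (A), with a provenance label.

    Radii must lie in (0.5, 3.5) A; anything outside that window is almost
    certainly a unit error.
    """

    radii: Mapping[str, float]
    provenance: str = "Bondi"

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not (0.5 < float(r) < 3.5):
                raise ValueError(
                    f"vdW radius for {el!r} is {r} A, outside the plausible "
                    "(0.5, 3.5) A window"
                )

    @classmethod
    def bondi(cls, overrides: Mapping[str, float] | None = None) -> "RadiiTable":
        """The default Bondi table, with optional per-element overrides."""
        table = dict(BONDI_RADII)
        label = "Bondi"
        if overrides:
            table.update({k: float(v) for k, v in overrides.items()})
            label = "Bondi+overrides"
        return cls(table, label)

    def lookup(self, element: str) -> float:
        try:
            return float(self.radii[element])
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} not present in radii table "
                f"({self.provenance}); add it via an override"
            ) from None


@dataclass
class Structure:
    """A fixed macromolecule: atoms with coordinates, vdW radii and charges.

    Parameters
    ----------
    elements : element symbol per atom.
    coords : (n, 3) coordinates in Angstrom.
    radii : per-atom vdW radius in Angstrom, all strictly positive.
    charges : per-atom (partial or site) charge in units of e.
    name : free-form label.
    terminal_group_count : number of terminal carboxylate groups (COOH/COO-);
        drives the deprotonated net charge of the chelator.
    """

    elements: list[str]
    coords: np.ndarray
    radii: np.ndarray
    charges: np.ndarray
    name: str = ""
    terminal_group_count: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        self.elements = list(self.elements)
        if len(self.elements) != n:
            raise ValueError("elements and coords length mismatch")
        if n == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("all vdW radii must be strictly positive")
        if self.terminal_group_count < 0:
            raise ValueError("terminal_group_count must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def centroid(self) -> np.ndarray:
        """Unweighted geometric centre of the atoms (A)."""
        return self.coords.mean(axis=0)

    def translated(self, shift: Sequence[float]) -> "Structure":
        return Structure(
            elements=list(self.elements),
            coords=self.coords + np.asarray(shift, dtype=float),
            radii=self.radii.copy(),
            charges=self.charges.copy(),
            name=self.name,
            terminal_group_count=self.terminal_group_count,
        )


@dataclass(frozen=True)
class GenerationSpec:
    """A carboxyl-terminated PAMAM half generation.

    ``generation`` must be a half-integer (-0.5, 0.5, 1.5, ...): full-integer
    generations are amine-terminated and carry no carboxylates, so they are
    outside this charge model.  ``core_multiplicity`` is the number of
    branches leaving the core (4 for the ethylenediamine core).
    """

    generation: float
    core_multiplicity: int = 4

    def __post_init__(self) -> None:
        if self.core_multiplicity < 2:
            raise ValueError("core_multiplicity must be >= 2")
        g2 = 2 * self.generation
        if not math.isclose(g2, round(g2)) or round(g2) % 2 == 0:
            raise ValueError(
                f"generation {self.generation} is not a half generation; "
                "carboxyl-terminated dendrimers have generation in "
                "{-0.5, 0.5, 1.5, ...}"
            )
        if self.generation < -0.5:
            raise ValueError("generation must be >= -0.5")


def surface_group_count(spec: GenerationSpec) -> int:
    """Number of terminal COOH groups of a half-generation dendrimer.

    Doubling recursion from the core: ``core * 2**(floor(g) + 1)``, e.g.
    generation 3.5 with a 4-branch core carries 64 terminal carboxylates.
    """
    return spec.core_multiplicity * 2 ** (math.floor(spec.generation) + 1)


def net_charge_deprotonated(structure_or_count: "Structure | int") -> int:
    """Net charge (e) after removing one proton from every terminal COOH.

    Each deprotonated carboxylate contributes ``-1 e``, so the net charge is
    minus the terminal-group count (EDTA: 4 groups -> -4; G3.5 PAMAM: 64
    groups -> -64).
    """
    if isinstance(structure_or_count, Structure):
        count = structure_or_count.terminal_group_count
    else:
        count = int(structure_or_count)
    if count < 0:
        raise ValueError("terminal group count must be >= 0")
    return -count


def theoretical_chelation_capacity(net_charge: int, ion_valence: int) -> int:
    """Maximum number of ions of the given valence the net charge can bind.

    Charge-stoichiometric capacity: ``floor(|net_charge| / valence)``.  A
    -64 e dendrimer can hold 32 divalent or 64 monovalent cations.
    """
    if ion_valence == 0:
        raise ValueError("ion valence must be non-zero")
    if ion_valence < 0:
        raise ValueError("ion valence must be positive for a chelated cation")
    return abs(int(net_charge)) // int(ion_valence)


# ---------------------------------------------------------------------------
# File I/O: PDB via biotite, plus a whitespace-delimited atom table.
# ---------------------------------------------------------------------------

def _load_pdb(path: Path, radii: RadiiTable) -> Structure:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, extra_fields=["charge"])
        charges = np.asarray(arr.charge, dtype=float)
    except Exception:
        arr = pdb.get_structure(model=1)
        charges = np.zeros(arr.array_length())
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no atoms found")
    elements = [el.capitalize() for el in arr.element]
    r = np.array([radii.lookup(el) for el in elements])
    return Structure(
        elements=elements,
        coords=np.asarray(arr.coord, dtype=float),
        radii=r,
        charges=charges,
        name=path.stem,
    )


def _load_atom_table(path: Path, radii: RadiiTable) -> Structure:
    elements: list[str] = []
    coords: list[list[float]] = []
    rads: list[float] = []
    charges: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'element x y z [radius] "
                    f"[charge]', got {raw.rstrip()!r}"
                )
            el = parts[0].capitalize()
            try:
                xyz = [float(v) for v in parts[1:4]]
                rad = float(parts[4]) if len(parts) > 4 else radii.lookup(el)
                q = float(parts[5]) if len(parts) > 5 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            elements.append(el)
            coords.append(xyz)
            rads.append(rad)
            charges.append(q)
    if not elements:
        raise ValueError(f"{path}: file contains no atoms")
    return Structure(
        elements=elements,
        coords=np.array(coords),
        radii=np.array(rads),
        charges=np.array(charges),
        name=path.stem,
    )


def load_structure(path: str | Path, radii: RadiiTable | None = None) -> Structure:
    """Read a structure from a PDB file or a plain-text atom table.

    Dispatch is by extension (``.pdb`` / ``.ent`` -> PDB, anything else ->
    atom table).  Atom order is preserved.  Radii come from ``radii``
    (Bondi defaults) unless the atom table provides an explicit column.
    """
    path = Path(path)
    radii = radii or RadiiTable.bondi()
    if path.suffix.lower() in {".pdb", ".ent"}:
        return _load_pdb(path, radii)
    return _load_atom_table(path, radii)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as PDB (by extension) or as an atom table.

    Coordinates survive a write/read round trip to 3 decimals (the PDB
    fixed-column format's native precision).
    """
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arr = struc.AtomArray(structure.n_atoms)
        arr.coord = structure.coords.astype(np.float32)
        arr.element = np.array([el.upper() for el in structure.elements])
        arr.atom_name = np.array([el.upper() for el in structure.elements])
        arr.res_name = np.array(["LIG"] * structure.n_atoms)
        arr.res_id = np.ones(structure.n_atoms, dtype=int)
        arr.hetero = np.ones(structure.n_atoms, dtype=bool)
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(str(path))
        return
    with open(path, "w") as fh:
        fh.write(f"# {structure.name or 'structure'}: element x y z radius charge\n")
        for el, xyz, r, q in zip(
            structure.elements, structure.coords, structure.radii, structure.charges
        ):
            fh.write(
                f"{el} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f} {r:.3f} {q:+.3f}\n"
            )


# ---------------------------------------------------------------------------
# Coarse-grained templates
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n approximately equidistant points on a sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    return radius * pts


def coarse_dendrimer(
    spec: GenerationSpec,
    sphere_radius: float = 15.0,
    site_radius: float = 2.0,
    site_charge: float = -1.0,
    element: str = "X",
    name: str | None = None,
) -> Structure:
    """Coarse-grained half-generation dendrimer: terminal sites on a sphere.

    The chelation analysis only needs positions, radii and charges of the
    deprotonated terminal carboxylates, so the dendrimer interior is dropped
    and the terminal sites are placed deterministically (Fibonacci lattice)
    on a sphere of ``sphere_radius``.  Each site carries ``site_charge``
    (default -1 e, the deprotonated carboxylate).
    """
    n = surface_group_count(spec)
    coords = _fibonacci_sphere(n, sphere_radius)
    return Structure(
        elements=[element] * n,
        coords=coords,
        radii=np.full(n, float(site_radius)),
        charges=np.full(n, float(site_charge)),
        name=name or f"coarse-G{spec.generation}",
        terminal_group_count=n,
    )


def edta_template(
    arm_length: float = 3.5,
    site_radius: float = 1.6,
    site_charge: float = -1.0,
) -> Structure:
    """Coarse EDTA: four carboxylate sites at tetrahedron vertices.

    EDTA is always this fixed 4-site template (or a user-supplied PDB); the
    dendrimer generation formula never applies to it.  Fully deprotonated the
    template carries -4 e.
    """
    verts = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) / math.sqrt(3.0)
    return Structure(
        elements=["X"] * 4,
        coords=arm_length * verts,
        radii=np.full(4, float(site_radius)),
        charges=np.full(4, float(site_charge)),
        name="coarse-EDTA",
        terminal_group_count=4,
    )
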