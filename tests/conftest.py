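"""Shared fixtures: toy structures and session-scoped simulation runs.

The expensive Brownian-dynamics runs (square-well recovery, the shipped
two-species demo, the uniform-gas reference) are computed once per session
and shared by the unit and acceptance tests that consume them.
"""

from __future__ import annotations

import numpy as np
import pytest

import chelax as cx
from chelax.builder import IonSet
from chelax.demo import demo_buffer_config
from chelax.pipeline import run_pipeline


@pytest.fixture
def one_atom_structure() -> cx.Structure:
    """Single atom of radius 1.5 A at the origin."""
    return cx.Structure(
        elements=["C"], coords=[[0.0, 0.0, 0.0]], radii=[1.5], charges=[0.0],
        name="one-atom",
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-atom (C, O, O) PDB file."""
    path = tmp_path / "toy.pdb"
    path.write_text(
        "HETATM    1  C   LIG A   1       0.000   0.000   0.000  1.00  0.00"
        "           C\n"
        "HETATM    2  O   LIG A   1       1.250   0.000   0.000  1.00  0.00"
        "           O\n"
        "HETATM    3  O   LIG A   1      -1.250   0.500   0.000  1.00  0.00"
        "           O\n"
        "END\n"
    )
    return path


SQUARE_WELL = dict(radius=5.0, depth=4.0, box_edge=40.0, atom_radius=2.0)


@pytest.fixture(scope="session")
def square_well_runs():
    """Three seeded BD runs of one ideal ion in a pure square well.

    The well (radius 5 A, depth 4 kT) is centred on a single uncharged atom
    of vdW radius 2 A in a 40 A cubic box, so "within 3.0 A of the surface"
    is exactly "inside the well".  Returns (structure, list of
    per-seed centre-distance arrays, params dict).
    """
    sw = SQUARE_WELL
    L = sw["box_edge"]
    center = np.full(3, L / 2.0)
    structure = cx.Structure(
        elements=["X"], coords=[center], radii=[sw["atom_radius"]],
        charges=[0.0], name="well-site",
    )
    well = cx.BindingWell(site_index=0, radius=sw["radius"], depth=sw["depth"])
    distances = []
    for seed in (11, 12, 13):
        ions = IonSet(
            labels=["Na"], positions=[[5.0, 5.0, 5.0]],
            charges=[0.0], diffusion=[2.0],
        )
        params = cx.BDParams(
            box_edges=[L] * 3, n_steps=500_000, timestep=0.02,
            save_interval=10, lj_epsilon=0.0, binding_well=well, seed=seed,
        )
        traj = cx.simulate(structure, ions, params)
        d = traj.frames[:, 0, :] - center
        d -= L * np.round(d / L)
        distances.append(np.sqrt((d * d).sum(axis=1)))
    return structure, distances, sw


@pytest.fixture(scope="session")
def uniform_gas():
    """Equilibrated BD run of 256 fully non-interacting ions.

    No charges and no excluded volume: the stationary distribution is
    exactly uniform, so g(r) around the (inert) central reference atom is
    1 everywhere.  Starting from a uniform draw the run is stationary from
    frame 0.
    """
    L = 40.0
    structure = cx.Structure(
        elements=["X"], coords=[[L / 2] * 3], radii=[1.0], charges=[0.0],
        name="reference",
    )
    rng = np.random.default_rng(7)
    ions = IonSet(
        labels=["Na"] * 256, positions=rng.uniform(0, L, (256, 3)),
        charges=np.zeros(256), diffusion=np.full(256, 1.0),
    )
    params = cx.BDParams(
        box_edges=[L] * 3, n_steps=80_000, timestep=0.02, save_interval=2,
        lj_epsilon=0.0, seed=3,
    )
    traj = cx.simulate(structure, ions, params)
    return structure, traj


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The shipped G3.5-buffer demo pipeline (32 Na+ + 16 Ca2+, 3 seeds)."""
    outdir = tmp_path_factory.mktemp("demo_buffer")
    config = demo_buffer_config(base_seed=1)
    report = run_pipeline(config, outdir)
    return config, report, outdir
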