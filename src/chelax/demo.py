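"""Shipped demo configurations mirroring the study's box compositions.

The compositions are the printed ones: the G3.5-dendrimer buffer box
(approximately 460,000 A^3) holds the -64 e coarse dendrimer with 32 Na+
and 16 Ca2+ (charge-neutral, so no Cl- is added), and the EDTA water box
(approximately 75,000 A^3) holds the -4 e EDTA template with 5 Ca2+ and
6 Cl-.  Counter ions start on the 8.00 A shell; three replicates per
system.  The Brownian-dynamics settings are the package defaults at desk
scale — they emulate, and do not claim to reproduce, all-atom solvated MD.
"""

from __future__ import annotations

from .pipeline import MDProtocol, RunConfig, SpeciesConfig

__all__ = ["demo_buffer_config", "demo_edta_water_config"]

#: Provenance of the emulated all-atom protocol (never used by the BD core).
EMULATED_PROTOCOL = MDProtocol(
    n_steps=15_000_000, timestep_fs=2.0, stated_duration_ns=30.0
)

_G35_BOX_EDGE = 460_000.0 ** (1.0 / 3.0)  # ~77.18 A
_EDTA_BOX_EDGE = 75_000.0 ** (1.0 / 3.0)  # ~42.17 A


def demo_buffer_config(
    base_seed: int = 1,
    replicates: int = 3,
    n_steps: int = 60_000,
    save_interval: int = 30,
) -> RunConfig:
    """Coarse G3.5 dendrimer with 32 Na+ and 16 Ca2+ in the buffer box."""
    return RunConfig(
        name="g35-buffer-demo",
        solute={"kind": "dendrimer", "generation": 3.5, "core_multiplicity": 4,
                "sphere_radius": 15.0, "site_radius": 2.0},
        box_edges=[_G35_BOX_EDGE] * 3,
        species=[
            SpeciesConfig(name="Na", valence=+1, count=32),
            SpeciesConfig(name="Ca", valence=+2, count=16),
        ],
        neutralizer="Cl",
        shell=8.00,
        threshold=3.0,
        replicates=replicates,
        seeds=[int(base_seed) + i for i in range(replicates)],
        bd={
            "n_steps": int(n_steps),
            "timestep": 0.01,
            "save_interval": int(save_interval),
            "screening_length": 8.0,
            "lj_epsilon": 1.0,
            "lj_sigma": 3.0,
        },
        rdf={"bin_width": 0.25, "r_max": 35.0, "reference": "com"},
        protocol=EMULATED_PROTOCOL,
    )


def demo_edta_water_config(
    base_seed: int = 1,
    replicates: int = 3,
    n_steps: int = 40_000,
    save_interval: int = 20,
) -> RunConfig:
    """Coarse EDTA with 5 Ca2+ (and the 6 Cl- that neutralize) in water."""
    return RunConfig(
        name="edta-water-demo",
        solute={"kind": "edta"},
        box_edges=[_EDTA_BOX_EDGE] * 3,
        species=[
            SpeciesConfig(name="Ca", valence=+2, count=5),
        ],
        neutralizer="Cl",
        shell=8.00,
        threshold=3.0,
        replicates=replicates,
        seeds=[int(base_seed) + i for i in range(replicates)],
        bd={
            "n_steps": int(n_steps),
            "timestep": 0.01,
            "save_interval": int(save_interval),
            "screening_length": 8.0,
            "lj_epsilon": 1.0,
            "lj_sigma": 3.0,
        },
        rdf={"bin_width": 0.25, "r_max": 20.0, "reference": "com"},
        protocol=EMULATED_PROTOCOL,
    )
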