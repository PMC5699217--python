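"""End-to-end pipeline: build -> simulate -> analyse -> RDF -> report.

A :class:`RunConfig` describes one study: the solute (coarse template or a
structure file), the box, the ion species with explicit counts or target
concentrations, the Brownian-dynamics parameters, and one seed per
replicate.  :func:`run_pipeline` executes every replicate, aggregates the
chelation statistics over runs (both pooled and per-run spreads), averages
the RDFs, and writes deterministic artifacts: trajectories, a stats JSON, a
g(r) CSV per species, and a markdown report whose body is byte-identical on
rerun with the same config and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__ as _version
from .analysis import ChelationStats, distance_series, summarize
from .bd import BDParams, Trajectory, simulate
from .builder import (
    DEFAULT_SPECIES,
    Composition,
    IonSpecies,
    ion_count_for_concentration,
    neutralize,
    place_ions_on_shell,
)
from .rdf import RDFResult, average_rdf, compute_rdf
from .topology import (
    GenerationSpec,
    RadiiTable,
    Structure,
    coarse_dendrimer,
    edta_template,
    load_structure,
)
from .trajio import render_report, write_trajectory

__all__ = ["MDProtocol", "SpeciesConfig", "RunConfig", "Report", "run_pipeline"]

log = logging.getLogger("chelax.pipeline")


@dataclass(frozen=True)
class MDProtocol:
    """Provenance record of an all-atom MD protocol a run emulates.

    Never used by the Brownian propagator; the validator only checks the
    internal arithmetic: ``n_steps * timestep_fs`` must equal the stated
    duration (1.5e7 steps of 2 fs -> 30 ns).
    """

    n_steps: int
    timestep_fs: float
    stated_duration_ns: float | None = None

    @property
    def duration_ns(self) -> float:
        return self.n_steps * self.timestep_fs * 1e-6

    def validate(self) -> None:
        if self.n_steps < 1 or self.timestep_fs <= 0:
            raise ValueError("protocol needs n_steps >= 1 and timestep_fs > 0")
        if self.stated_duration_ns is not None and not np.isclose(
            self.duration_ns, self.stated_duration_ns, rtol=1e-9, atol=1e-12
        ):
            raise ValueError(
                f"protocol arithmetic mismatch: {self.n_steps} steps x "
                f"{self.timestep_fs} fs = {self.duration_ns} ns, but the "
                f"stated duration is {self.stated_duration_ns} ns"
            )


@dataclass
class SpeciesConfig:
    """One mobile species of a run: count or target concentration."""

    name: str
    valence: int
    count: int | None = None
    concentration: float | None = None  # mol/L
    diffusion: float | None = None  # A^2/ps
    radius: float | None = None  # A

    def resolve_count(self, box_volume: float) -> int:
        if self.count is not None:
            return int(self.count)
        if self.concentration is not None:
            return ion_count_for_concentration(self.concentration, box_volume)
        raise ValueError(f"species {self.name}: give either count or concentration")

    def ion_species(self) -> IonSpecies:
        base = DEFAULT_SPECIES.get(self.name)
        return IonSpecies(
            name=self.name,
            valence=self.valence,
            diffusion=self.diffusion
            if self.diffusion is not None
            else (base.diffusion if base else 0.1),
            radius=self.radius
            if self.radius is not None
            else (base.radius if base else 2.0),
        )


@dataclass
class RunConfig:
    """Everything needed to reproduce a study: structure, box, ions, BD.

    ``solute`` is either ``{"kind": "dendrimer", "generation": 3.5, ...}``,
    ``{"kind": "edta"}`` or ``{"kind": "file", "path": ...}``.  Exactly one
    seed per replicate is required.
    """

    name: str
    solute: dict
    box_edges: list[float]
    species: list[SpeciesConfig]
    seeds: list[int]
    replicates: int = 3
    neutralizer: str = "Cl"
    shell: float = 8.00
    threshold: float = 3.0
    bd: dict = field(default_factory=dict)
    rdf: dict = field(default_factory=dict)
    radii_overrides: dict = field(default_factory=dict)
    protocol: MDProtocol | None = None

    def __post_init__(self) -> None:
        self.species = [
            s if isinstance(s, SpeciesConfig) else SpeciesConfig(**s)
            for s in self.species
        ]
        if self.protocol is not None and not isinstance(self.protocol, MDProtocol):
            self.protocol = MDProtocol(**self.protocol)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if len(self.seeds) != self.replicates:
            raise ValueError(
                f"exactly one seed per replicate required: {self.replicates} "
                f"replicates but {len(self.seeds)} seeds"
            )
        if self.threshold <= 0:
            raise ValueError("dwell threshold must be > 0")
        if self.shell <= 0:
            raise ValueError("shell distance must be > 0")
        if len(self.box_edges) != 3 or any(e <= 0 for e in self.box_edges):
            raise ValueError("box_edges must be three positive lengths")
        if self.protocol is not None:
            self.protocol.validate()

    @property
    def box_volume(self) -> float:
        e = self.box_edges
        return float(e[0] * e[1] * e[2])

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- construction helpers --------------------------------------------
    def build_structure(self) -> Structure:
        radii = RadiiTable.bondi(self.radii_overrides or None)
        kind = self.solute.get("kind", "file")
        if kind == "dendrimer":
            spec = GenerationSpec(
                generation=float(self.solute.get("generation", 3.5)),
                core_multiplicity=int(self.solute.get("core_multiplicity", 4)),
            )
            s = coarse_dendrimer(
                spec,
                sphere_radius=float(self.solute.get("sphere_radius", 15.0)),
                site_radius=float(self.solute.get("site_radius", 2.0)),
            )
        elif kind == "edta":
            s = edta_template()
        elif kind == "file":
            s = load_structure(self.solute["path"], radii)
        else:
            raise ValueError(f"unknown solute kind {kind!r}")
        # centre the solute in the box
        box = np.asarray(self.box_edges, dtype=float)
        return s.translated(box / 2.0 - s.centroid())

    def resolve_composition(self, solute_charge: int) -> Composition:
        fixed = {
            s.name: (s.valence, s.resolve_count(self.box_volume))
            for s in self.species
        }
        nz_valence = -1
        for s in self.species:
            if s.name == self.neutralizer:
                nz_valence = s.valence
        if self.neutralizer in DEFAULT_SPECIES:
            nz_valence = DEFAULT_SPECIES[self.neutralizer].valence
        return neutralize(solute_charge, fixed, (self.neutralizer, nz_valence))

    def species_table(self) -> dict[str, IonSpecies]:
        table = dict(DEFAULT_SPECIES)
        for s in self.species:
            table[s.name] = s.ion_species()
        return table

    def bd_params(self, seed: int) -> BDParams:
        kw = dict(self.bd)
        prov = kw.pop("provenance", {})
        if self.protocol is not None:
            prov = {**prov, "emulated_protocol": asdict(self.protocol)}
        return BDParams(
            box_edges=self.box_edges,
            seed=seed,
            provenance=prov,
            **kw,
        )


@dataclass
class Report:
    """Pipeline output: stats (both aggregation modes), RDFs, provenance."""

    stats_pooled: ChelationStats
    stats_per_run: ChelationStats
    rdf_by_species: dict[str, RDFResult]
    provenance: dict

    def body(self) -> str:
        """Deterministic markdown body (no timestamps)."""
        lines = [
            f"# Chelation report: {self.provenance['name']}",
            "",
            f"Config hash: {self.provenance['config_hash']}",
            f"Seeds: {self.provenance['seeds']}",
            f"Replicates: {self.provenance['replicates']}",
            f"chelax version: {self.provenance['version']}",
            "",
            "## Species summary (pooled over all ions of all runs)",
            "",
            render_report(self.stats_pooled, "markdown"),
            "## Species summary (spread over replicate-run means)",
            "",
            render_report(self.stats_per_run, "markdown"),
        ]
        return "\n".join(lines)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2f s", name, dt)
            else:
                log.error("stage %s: FAILED after %.2f s (%s)", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Report:
    """Run build -> simulate -> analyse -> RDF -> report for every replicate.

    Artifacts written to ``outdir``: ``traj_rep<k>.xyz``, ``stats.json``,
    ``rdf_<species>.csv``, ``report.md``, ``composition.json``.  Everything
    except log output is a pure function of the config (and its seeds).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    with _stage("build"):
        structure = config.build_structure()
        solute_charge = int(round(structure.total_charge))
        composition = config.resolve_composition(solute_charge)
        (outdir / "composition.json").write_text(
            json.dumps(
                {"config_hash": cfg_hash, **composition.as_dict()},
                indent=2,
                sort_keys=True,
            )
        )

    runs = []
    trajectories: list[Trajectory] = []
    for k, seed in enumerate(config.seeds):
        with _stage(f"replicate{k}:place"):
            ions = place_ions_on_shell(
                structure,
                composition,
                box_edges=config.box_edges,
                shell=config.shell,
                seed=seed,
                species_table=config.species_table(),
            )
        with _stage(f"replicate{k}:simulate"):
            traj = simulate(structure, ions, config.bd_params(seed))
            traj.provenance["run_id"] = f"rep{k}"
            traj.provenance["config_hash"] = cfg_hash
            write_trajectory(traj, outdir / f"traj_rep{k}.xyz")
            trajectories.append(traj)
        with _stage(f"replicate{k}:analyse"):
            runs.append(distance_series(traj, structure))

    with _stage("summarize"):
        stats_pooled = summarize(runs, threshold=config.threshold, mode="pooled")
        stats_per_run = summarize(runs, threshold=config.threshold, mode="per_run")

    with _stage("rdf"):
        rdf_kw = dict(config.rdf)
        species_names = sorted({lbl for t in trajectories for lbl in t.species})
        rdf_by_species: dict[str, RDFResult] = {}
        for name in species_names:
            per_run = [
                compute_rdf(t, structure, species=name, **rdf_kw)
                for t in trajectories
            ]
            avg = average_rdf(per_run)
            rdf_by_species[name] = avg
            with open(outdir / f"rdf_{name}.csv", "w") as fh:
                fh.write(f"# config_hash={cfg_hash} reference={avg.reference}\n")
                fh.write("r_center,g_r,count\n")
                for r, g, c in zip(avg.bin_centers, avg.g, avg.counts):
                    fh.write(f"{r:.4f},{g:.6f},{int(c)}\n")

    with _stage("report"):
        provenance = {
            "name": config.name,
            "config_hash": cfg_hash,
            "seeds": list(config.seeds),
            "replicates": config.replicates,
            "version": _version,
            "composition": composition.as_dict(),
            "protocol": asdict(config.protocol) if config.protocol else None,
        }
        report = Report(
            stats_pooled=stats_pooled,
            stats_per_run=stats_per_run,
            rdf_by_species=rdf_by_species,
            provenance=provenance,
        )
        (outdir / "stats.json").write_text(
            json.dumps(
                {
                    "config_hash": cfg_hash,
                    "pooled": stats_pooled.as_dict(),
                    "per_run": stats_per_run.as_dict(),
                    "provenance": provenance,
                },
                indent=2,
                sort_keys=True,
            )
        )
        (outdir / "report.md").write_text(report.body())
    return report
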