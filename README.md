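# chelax

Counter-ion chelation analysis around polyanions — dwell-time statistics,
ion-to-surface distance series, and radial distribution functions — with the
box-composition arithmetic behind such studies and a coarse-grained
Brownian-dynamics generator so the whole pipeline runs at desk scale.

## The problem

Carboxylate-terminated macromolecules such as EDTA (4 COO⁻, net charge
−4 e) and half-generation PAMAM dendrimers (G3.5: 64 COO⁻, net charge
−64 e) chelate divalent cations. Whether, and how strongly, Ca²⁺ binds to
such a polyanion — and whether it out-competes monovalent Na⁺ — is typically
read off molecular-dynamics trajectories through three per-ion observables:

* **surface distance** `d_i(t) = min_a (‖x_i(t) − x_a‖_MIC − r_a)` — the
  minimum-image distance from ion *i* to the van der Waals surface (the
  envelope of atom-centred spheres of vdW radius `r_a`);
* **dwell fraction** — the fraction of frames with `d_i(t) ≤ 3.0 Å`;
* **g(r)** — the radial distribution function of each ion species around the
  solute, averaged over replicate runs.

`chelax` implements these analyses as a reusable library plus CLI, together
with the supporting arithmetic: molarity ↔ ion count for a given box volume
(`n = round(c · N_A · V)`), charge-neutral composition building, the
dendrimer generation model (terminal groups `= 4·2^(⌊g⌋+1)`, capacity
`⌊|q|/v⌋`), and initial placement of all counter ions at 8.00 Å from the
solute surface. Because all-atom solvated MD is far beyond desk scale, the
package ships an implicit-solvent Brownian-dynamics propagator (screened
Coulomb + WCA repulsion, optional square binding well) whose equilibrium
behaviour has closed-form ground truth, so every statistic can be validated
end to end.

## Worked example

The shipped demo is the two-species buffer system: a coarse −64 e G3.5
dendrimer (64 −1 e sites on a 15 Å sphere) with 32 Na⁺ and 16 Ca²⁺ in a
~460,000 Å³ periodic box, three seeded replicates, ions started on the
8.00 Å shell:

```bash
chelax run --config examples/demo_buffer.yaml --out scratch/demo
```

or in Python:

```python
from chelax.demo import demo_buffer_config
from chelax.pipeline import run_pipeline

report = run_pipeline(demo_buffer_config(base_seed=1), "scratch/demo")
print(report.body())
```

which prints (among other things):

```
| Counter ion | Average distance (A) | Average minimum distance (A) | Average dwell fraction |
|---|---|---|---|
| Ca | 5.11 (4.64) | 1.89 (2.27) | 0.58 (0.35) |
| Na | 8.85 (6.65) | 2.91 (2.81) | 0.33 (0.32) |
```

Read: over three replicates, a Ca²⁺ ion averages 5.11 Å from the dendrimer
surface and spends 58 % of the trajectory within the 3.0 Å chelation cutoff,
versus 8.85 Å and 33 % for Na⁺ — the divalent ion binds preferentially, and
the mean minimum distance shows every ion visits the surface at least
transiently. Parenthesised values are population standard deviations over
all ions of all runs ("pooled"); the report also prints the spread over
replicate-run means. Artifacts written alongside: per-replicate extended-XYZ
trajectories, `stats.json`, one run-averaged `rdf_<species>.csv` per
species, `composition.json`, and `report.md`, all byte-reproducible from the
config and seeds.

Individual steps are available as `chelax build / simulate / analyze / rdf /
report` and as plain library functions (`ion_surface_distance`,
`dwell_fraction`, `summarize`, `compute_rdf`, `square_well_occupancy`, …).

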