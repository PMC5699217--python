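# Methods

## Observables

All analyses are defined on trajectories of mobile ions around a single
frozen macromolecule in an orthorhombic periodic box.

**Surface distance.** For ion position `x` and solute atoms `a` with
coordinates `x_a` and van der Waals radii `r_a`,

    d(x) = min_a ( ‖x − x_a‖_MIC − r_a ),

with every pair distance taken under the minimum-image convention (MIC) when
a box is given. `d` is the distance to the vdW surface (the envelope of
atom-centred spheres) and is slightly negative when the ion overlaps it.
The kernel is vectorised over atoms and ions and is verified against an
exhaustive double-loop oracle to 1e−9 Å, with and without periodicity.

**Dwell fraction.** The fraction of frames with `d ≤ τ`, boundary
inclusive, default `τ = 3.0 Å`. Storing fractions in [0, 1] (never
percentages) avoids unit ambiguity; reports render two decimals.

**Ensemble summaries.** Per ion we compute mean distance, minimum distance,
and dwell fraction; species-level summaries aggregate these per-ion values
over replicate runs in two labelled modes:

* `pooled` (default): mean and population SD over all ions of all runs —
  the spread between individual ions;
* `per_run`: mean over runs of the per-run means, population SD over the
  run means — the spread between independent replicates.

Both are always computed by the pipeline and printed side by side, since the
two conventions answer different questions and are easy to conflate. For
equal-length series, averaging per-ion means equals pooling all frames, so
no further convention is needed there.

**Radial distribution function.** With one reference point per frame
(solute geometric centre, mode `com`; or the nearest solute atom, mode
`nearest-atom` — the mode is recorded in every result so curves are never
compared silently across conventions),

    g(r) = counts(r-bin) / Σ_frames [ N_sel · 4π r_c² Δr / V_frame ],

where `r_c` is the bin centre and `V_frame` the instantaneous box volume
(constant for the built-in generator; the per-frame form is ready for NPT
input). `r_max` may not exceed half the smallest box edge, where
minimum-image distances stop being complete. Replicates are combined by
per-bin averaging of `g` with counts and frame counts summed.
Normalisation is validated two ways: a non-interacting uniform gas gives
`g = 1` bin-wise, and integrating `g · ρ · 4πr²dr` recovers the directly
counted mean ion number within `r_max`.

**Windowed convergence.** RDFs over nested, growing windows (default:
first third, two thirds, full) are compared to the full-window RDF by the
maximum absolute per-bin difference; the run is flagged converged when the
penultimate window agrees within a tolerance (default 0.1). Bin width
matters here: the innermost spherical shells hold few counts, so the
convergence check should use bins coarse enough that per-bin noise sits
well below the tolerance (the shipped tests use 2 Å bins at 256 ions).

## Composition arithmetic

Ion counts follow `n = round(c · N_A · V · 10⁻²⁷)` with `V` in Å³ and ties
rounded away from zero; this reproduces every documented box (0.115 M in
460,000 Å³ → 32; 0.115 M in 75,000 Å³ → 5; 0.0575 M in 460,000 Å³ → 16).
Charge neutrality is restored by topping up with one designated monovalent
species (Cl⁻ by default): explicit counts always win and the neutralizer
fills exactly the residual (−4 e solute + 5 Ca²⁺ → 6 Cl⁻; the −64 e
dendrimer with 32 Na⁺ + 16 Ca²⁺ is already neutral and gets none).

The generation model for carboxyl-terminated (half-generation) PAMAM from a
4-branch ethylenediamine core is the doubling recursion
`groups(g) = 4 · 2^(⌊g⌋+1)` (G3.5 → 64), net deprotonated charge
`−groups`, and charge-stoichiometric capacity `⌊|q|/v⌋` (−64 e, v = 2 →
32). Integer generations are amine-terminated and rejected. EDTA is never
run through this formula; it is a fixed 4-site template.

**Initial placement.** "At 8.00 Å from the molecule" is interpreted as
8.00 Å from the vdW *surface* — the same distance definition the analysis
uses, so placement is verifiable by the analysis module (±0.01 Å). Each
ion takes a random direction from the solute centroid and the radial
coordinate is bisected until the surface distance matches the shell; a
minimum ion–ion separation of 2.5 Å is enforced with a bounded retry
budget, and failure reports the achieved count.

## The Brownian-dynamics generator

The generator exists to exercise and validate the analysis layer with
controllable ground truth; it does not attempt to reproduce all-atom
solvated MD, whose protocol parameters are carried as inert provenance
metadata only (including the consistency check that 1.5×10⁷ steps × 2 fs
= 30 ns).

**Propagator.** Overdamped (inertia-free) Euler–Maruyama:
`x ← x + D F dt + √(2 D dt) ξ` with energies in kT (so `D F` has F in
kT/Å), per-coordinate standard normal `ξ`, and per-species diffusion
coefficients (defaults: Ca²⁺ 0.079, Na⁺ 0.133, Cl⁻ 0.203 Å²/ps — standard
dilute-solution values at 300 K). A step displacing any ion by more than a
quarter box edge aborts with advice to reduce the timestep (default
0.01 ps). Runs are bitwise reproducible from the seed.

**Interactions.** Screened Coulomb (Yukawa) between all charged pairs,
`u = l_B · s · q_i q_j · e^(−r/λ)/r`, with Bjerrum length `l_B(T)` (7.10 Å
in water at 300 K), dielectric scaling `s` (default 1) and Debye length `λ`
(default 8 Å ≈ 0.12 M ionic strength), plus a purely repulsive
shifted-truncated Lennard-Jones (WCA) core (default ε = 1 kT, σ = 3 Å)
preventing overlap. All pairs use the minimum-image convention; the solute
is frozen. These parameters are package conventions, not derived from any
force field. Note that ε and σ apply to ion–ion as well as ion–site pairs;
an ideal (non-interacting) gas therefore requires ε = 0 and zero charges.

**Square binding well.** A discontinuous square well admits no force, so it
is handled by a Metropolis accept/reject step on the proposed displacement
(the Gaussian proposal is symmetric). With no other interactions this
samples the well's Boltzmann distribution *exactly*, so the time-average
bound fraction converges to the closed form

    p = V_b e^ε / (V_b e^ε + (V − V_b)),   V_b = (4/3)π r_w³,

which is the package's core parameter-recovery check. When continuous
forces and a well are combined the splitting is approximate (documented
limitation). Because bound/unbound residence times are long, the empirical
standard error of the bound fraction is estimated from block averages, not
the naive binomial formula, which serial correlation renders far too small.

**Coarse solute.** The analysis needs only positions, radii and charges,
so the dendrimer is modelled as its deprotonated terminal sites (−1 e
each) on a deterministic Fibonacci sphere (default radius 15 Å, site
radius 2 Å); EDTA as four −1 e sites at tetrahedron vertices (arm 3.5 Å).
Atomistic structures can be supplied as PDB (parsed via biotite) or a
plain atom table, with Bondi vdW radii (Mantina extension for Ca etc.) and
per-element overrides — the exact radius set shifts all surface distances
by a small constant, so it is configurable rather than guessed.

## What the synthetic data does and does not show

The demo (−64 e coarse dendrimer, 32 Na⁺ + 16 Ca²⁺, 8.00 Å start, three
replicates of 600 ps at desk scale — sizes chosen so the full suite runs in
minutes) reproduces the *qualitative* signature of preferential divalent
chelation: Ca²⁺ shows a higher dwell fraction and smaller mean surface
distance than Na⁺ in every replicate. It does not — and is not meant to —
reproduce quantitative results of all-atom solvated MD: there is no
explicit water, no solute flexibility, no Ewald electrostatics, no
barostat, and the interaction parameters are conventions. Passing tests
demonstrate that the *analysis* is correct and that the generator's
equilibria match their closed forms; they say nothing about force-field
accuracy on real systems.

## Numerical choices and edge cases

* Dwell boundary `d ≤ τ` inclusive; thresholds and the shell distance are
  configurable, defaults 3.0 Å and 8.00 Å.
* Ion-count rounding: nearest integer, ties away from zero.
* Spreads are population (ddof = 0) standard deviations, matching the
  degenerate expectation that identical ions give spread 0.
* Minimum-image via `r − L·round(r/L)`; box edges must exceed twice the
  interaction cutoff, and the Yukawa/WCA cutoff is capped at half the
  smallest edge.
* Empty structures, empty series, absent species (error names the species
  that are present), mismatched frame counts, malformed trajectory frames
  (error names the line), non-half generations, unreachable neutrality and
  oversized `r_max` all raise explicit errors.
* Trajectories are written as extended XYZ with 4-decimal coordinates:
  write → read is lossless to 3 decimals and read → write is
  byte-identical, which is what makes pipeline reruns reproducible at the
  byte level (timestamps are confined to logs).

## Known limitations

* The solute is rigid; conformational coupling to binding is absent.
* Yukawa screening approximates electrostatics at ~0.1 M; no Ewald sums.
* Combining a square well with strong continuous forces mixes an exact
  Metropolis step with a first-order integrator; the stationary
  distribution is then only approximately Boltzmann.
* `nearest-atom` RDF mode shares the spherical-shell normalisation of
  `com` mode, so its absolute scale is only comparable within the mode.
* The placement bisection assumes the solute is star-shaped about its
  centroid (true for the shipped templates and typical compact solutes).
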