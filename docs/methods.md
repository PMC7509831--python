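# Methods

This note documents the models implemented in `npamyloid`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Coarse-grained aggregation model

### Representation

Peptides are freely jointed chains of 8 hard beads (diameter σ = bond
length σ) in a cubic box with periodic boundaries in all three dimensions;
all pair interactions use minimum-image distances. One reduced length σ
maps to 1 nm, so a bead stands for roughly five Aβ42 residues and a chain
spans the peptide's ~7–8 nm contour at this resolution. The mapping was
chosen so that the full 2–15 nm nanoparticle diameter range fits a single
32 σ box while respecting the safety margin box > 2·d_max; a finer mapping
(σ = 0.5 nm) would force a ≥60 σ box and thousands of chains for the same
sweep, out of reach of a desk-scale run.

Energies are in units of kT (the simulation is athermal apart from the
Metropolis criterion; temperature never appears separately).

### Interactions

* **Excluded volume.** No two bead centers may come closer than σ, except
  bonded neighbors, which sit at exactly σ. No bead center may enter a
  nanoparticle hard sphere.
* **Hydrogen bonds.** An unordered inter-chain bead pair within 1.2 σ may
  carry a bond of depth ε_hb (default 4 kT, attractive). Each bead holds at
  most 2 bonds — a β-strand-like valence that favors extended, fibril-like
  aggregates over compact droplets. Before each attempted move the bonds of
  the affected beads are re-judged: stretched bonds (beyond 1.2 σ) break,
  new eligible pairs form nearest-distance-first (ties broken by lowest
  bead index), and the energy change enters ΔE. With ε_hb = 0 bond
  formation is disabled outright, which makes the non-interacting limit
  exact.
* **Nanoparticle adsorption.** Each fixed nanoparticle of radius R carries
  a square-well shell of thickness 0.5 σ and flat-surface depth ε_ads
  (default 8 kT) attenuated by curvature,

      ε(R) = ε_ads · R / (R + l_c),      l_c = 1 σ,

  expressing that a bead on a strongly curved surface shares less contact
  with it. An optional second attenuation of the shell thickness itself
  (`shell_curvature_length`) exists but is off by default.
* **Bond-face occlusion.** A bead inside an adsorption shell has bonding
  faces occluded by the surface: both faces on particles with R ≥ 1.25 σ
  (no new bonds while adsorbed), one face on smaller particles (one new
  bond still possible). Existing bonds are never severed by adsorption.
  This is the model's expression of the curvature effect: a flat-ish
  surface engages an adsorbed peptide's bonding interface completely,
  while a particle smaller than the bead scale cannot.

The occlusion rule, the curvature attenuation and their two length
parameters are the only parts of the interaction model that were calibrated
rather than set a priori. They were tuned once, on the size-sweep study
itself, to the qualitative behavior the model exists to express — strong
inhibition with an interior optimum near 3–4 nm — and then frozen; the
robustness of that behavior was subsequently confirmed on independent
seeds. Without the occlusion asymmetry the sweep is monotone toward the
smallest diameter (many small particles win purely on encounter kinetics at
matched total area); with a uniformly weak well (2 kT) no inhibition is
measurable at desk scale at all.

### Moves and schedule

A step is one attempted move of one uniformly chosen chain; move types are
drawn with equal probability 0.25:

* **pivot** — rigid rotation of a random tail about a random bead, uniform
  axis, angle uniform in (−π, π]. A pivot at a chain end moves nothing and
  counts as an accepted null move.
* **crankshaft** — rotation of one interior bead about the axis through its
  two neighbors by a uniform angle.
* **kink-jump** — repositioning of one interior bead uniformly on the
  circle of points preserving both adjacent bond lengths.
* **translation** — whole-chain displacement, each component uniform in
  [−σ, σ].

Acceptance follows min(1, e^(−ΔE)); hard-core or nanoparticle overlap
rejects outright. The total energy is maintained incrementally; in debug
runs it is compared against a from-scratch recomputation every 10³ steps
and agrees to < 10⁻⁸ kT over full runs.

All randomness flows through an explicit xoshiro256++ stream seeded from
the run seed, making trajectories bit-reproducible; replicate r of a
configuration uses seed + r for both initial coordinates and the move
stream.

### Initialization

Nanoparticles are placed uniformly at random without mutual overlap
(bounded retries; failure raises a packing error reporting the achieved
density). Chains grow as self-avoiding random walks avoiding all previously
placed material. The bond registry is initialized by a global
nearest-distance-first scan of all inter-chain pairs within the cutoff,
respecting valence and occlusion.

### Observable and presets

Aggregates are connected components of the chains-share-an-H-bond relation
(a config switch can additionally merge chains adsorbed on the same
particle; it is off by default, so a particle covered in mutually unbonded
peptides does not count as one aggregate). The reported quantity is the
mean number of chains per aggregate, n_chains / n_components, averaged over
snapshots taken every 10³ steps across the final analysis window.

Three presets:

| preset | box (σ) | chains | relax | production | analysis | replicates |
|---|---|---|---|---|---|---|
| desk | 20 | 100 | 10⁴ | 10⁵ | last 10⁴ | 5 |
| sweep | 32 | 150 | 10⁴ | 3×10⁵ | last 3×10⁴ | 10 |
| paper2020 | 38.7 | 1330 | 10⁴ | 10⁶ | last 10⁵ | 10 |

The sweep preset's chain count (4.6×10⁻³ σ⁻³) was chosen to keep the
zero-NP control in the moderate-aggregation regime (mean ≈ 5 chains per
aggregate, ≈9% replicate scatter); its replicate count follows the
full-scale protocol's ten samples per system. At desk densities above ~10⁻² σ⁻³ the
system races into gelation, where the observable is dominated by one
system-spanning cluster and its replicate variance swamps the nanoparticle
effect. The full-scale preset mirrors the 38.7 nm / 1330-chain / 10⁶-step
schedule of the study the model emulates and costs hours per replicate; it
is provided but not exercised by the tests.

The size sweep compares diameters {2, 3, 4, 6, 9, 15} nm at equal total
surface area, n(d) = round(A/πd²), with A defaulting to twice the area of
the largest particle so that even the 15 nm condition has two particles and
no condition rests on a single placement. A zero-NP control is always
included. With the defaults, every nanoparticle condition lowers the mean
chains-per-aggregate below control (inhibition ≈30–55%) and the minimum of
the curve falls at 3 or 4 nm: 2 nm particles are numerous but leaky
(weakened well, one bonding face left free), large particles are strong
adsorbers but few and far between, and 3–4 nm particles balance coverage
against disarming power.

## ThT fibrillation kinetics

The Boltzmann sigmoid F(t) = F₀ + A/(1 + e^(−k(t−t½))) is fitted by
Levenberg–Marquardt least squares with data-driven starting values (F₀ from
the minimum, A from the range, t½ from the half-range crossing, k from the
steepest slope via k ≈ 4·slope/A). The lag time uses the
tangent-at-midpoint convention, lag = t½ − 2/k, stated prominently because
other conventions exist; the identity lag + 2/k = t½ holds exactly for
every returned fit. Flat curves raise a "no transition" error;
non-convergence returns a flagged fit rather than failing silently.
Replicates are fitted independently and summarized as mean ± sd — fitting
averaged curves would understate replicate variance. Percent
maximum-intensity decrease is computed from fitted amplitudes (raw plateau
maxima are available from the curves themselves but amplitude is the
default, as it is baseline-corrected).

## ITC one-site binding

The one-site model treats each nanoparticle as n₀ identical independent
sites; with total titrant X_t and cell species M_t the bound concentration
follows the mass-action quadratic in closed form (verified in tests against
a root-finding equilibrium solver to 10⁻⁶). Injection bookkeeping uses the
perfusion convention: per injection of dV into V₀, effective concentrations
dilute by (1 − dV/2V₀)/(1 + dV/2V₀), and the measured heat is the change in
cell heat content corrected for displaced material. In the saturating limit
the cumulative heat approaches n₀·M₀·V₀·ΔH (conservation check, ~0.5%
residual at 50 µL into 200 µL). Because the titration injects peptide into
a nanoparticle cell, n₀ counts peptides per particle and the fitter leaves
it unconstrained (multilayer adsorption makes large n₀ physical). Heats of
dilution enter as an optional constant per-injection offset (on by
default). Starting values come from total-heat and inflection heuristics
plus a coarse log-spaced scan over K; a Wiseman c-value n₀KM outside
[1, 10⁴] triggers a reliability warning. ΔG = −RT ln K (R = 1.987×10⁻³
kcal mol⁻¹ K⁻¹) and ΔS = (ΔH − ΔG)/T hold to machine precision by
construction.

The synthetic default (n₀ = 8, K = 4.2×10⁶ M⁻¹, ΔH = −12 kcal/mol) puts the
standard geometry — 20 × 2 µL of 138 µM peptide into 200 µL of 1.5 µM
particles — at c ≈ 50, the comfortably fittable regime. The enantiomer-like
presets instead encode the published free energies (−6.7 and −7.3
kcal/mol); at this geometry they sit near c ≈ 1, where K is genuinely
poorly constrained — the acceptance script therefore averages triplicate
fits, mirroring the triplicate assay design.

## Pharmacokinetics

First-order elimination is fitted as ordinary least squares of
log₁₀(concentration) on time, with the slope reported positive for decay
and half-life = log₁₀(2)/b. The log₁₀ convention is forced by the
half-life arithmetic: a slope of 0.0211 log₁₀-units/h gives
log₁₀(2)/0.0211 = 14.27 ≈ 14.3 h, and 0.0203 gives 14.83 ≈ 14.8 h; a
natural-log reading would not reproduce those half-lives. Group fits use
per-time means (destructive sampling: separate animals per time point);
per-subject fitting is available when longitudinal series exist.
Biodistribution summaries report the time of maximum group mean and its
fold-change against a control group on a shared grid, ties breaking to the
earliest time.

## Synthetic data

Every generator is a pure function of (parameters, seed), and its
noise-free output satisfies the corresponding stage model identically, so
noise-free round trips isolate the fitters. Noise models: additive Gaussian
(sd 2 a.u.) for plate-reader fluorescence; proportional Gaussian (2% of the
largest heat) per ITC injection; multiplicative lognormal (sd 0.1) for
concentrations, which keeps them positive. Effect sizes of the treated ThT
groups (60/63/11% amplitude decreases) mirror the study the pipeline
emulates so end-to-end demos are recognizable — they are emulation presets,
not data. What passing tests show is that the estimators recover known
truth under these idealized noise models; real assays add baseline drift,
ThT quenching, inner-filter effects and inter-plate variation that the
generators deliberately omit.

## Numerical choices and limitations

* Cell lists (cell edge ≥ 1.2 σ) accelerate neighbor search; a static
  cell-to-nanoparticle map accelerates shell lookups. Boxes smaller than
  three cells fall back to all-pairs scanning.
* Degenerate proposals (pivot at a chain end, crankshaft with coincident
  neighbors) are accepted null moves, keeping the step count well-defined.
* The greedy nearest-first bond assignment is deterministic but makes the
  bond registry history-dependent; the energy is always consistent with
  the registry (checked to 10⁻⁸ kT), but the move set does not satisfy
  detailed balance exactly with respect to a bond-free Hamiltonian. The
  simulation is used as a kinetic aggregation model, not an equilibrium
  sampler, matching its purpose.
* Monte Carlo steps carry no calibrated physical time; all kinetic
  statements are per-step, and cross-condition comparisons use identical
  schedules.
* Trajectory output is limited to cluster snapshots and final states;
  no chunked binary trajectory container is written.
* The model is not residue-resolved and carries no chirality: enantiomer
  differences enter only through the fitting stages' inputs, never the
  simulator.
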