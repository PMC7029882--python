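# Methods

## The problem

Strong positive selection leaves a characteristic footprint in a population
sample: linked neutral variation is removed around the selected site, the
local site frequency spectrum (SFS) is shifted toward rare and
high-frequency derived variants, and the signal decays on the coalescent
timescale of 4N generations.  When the beneficial allele arrives by gene
flow from a diverged population instead of by new mutation — an
*introgressed sweep* — the donor haplotype wipes variation only in a narrow
core, while recombination during and after the sweep splices diverged donor
fragments into the flanks, *elevating* diversity and intermediate-frequency
variation there.  The result is a "volcano": a narrow central trough flanked
by ridges, as opposed to the broad crater of a classic hard sweep.

This package provides, in one place, the machinery needed to generate,
detect and interpret both signatures:

1. a forward-in-time two-population Wright-Fisher simulator (``simcore``),
2. window summary statistics π, Tajima's D, Kelly's ZnS (``sumstats``),
3. a SweepFinder-style composite-likelihood-ratio (CLR) scan (``clr_scan``),
4. the downstream conversions — CLR significance thresholds, Ne, selection
   coefficients, detection horizons (``selection_inference``),
5. replicated time-course experiments (``timecourse``), and
6. synthetic generators for download-free testing (``synthetic_data``).

## Simulation model

Discrete non-overlapping generations; each individual is a single diploid
recombining chromosome of L sites.  Per generation and population:
migration (each individual independently replaced by a migrant from the
other population with probability m), fitness-proportional parent sampling
(fitnesses 1, 1+hs, 1+s by genotype at the beneficial site; h = 0.5 by
default), gamete formation with Poisson(r·(L−1)) crossovers at uniform
breakpoints, and Poisson(2N·μ·L) new mutations at uniform positions under a
quasi-infinite-sites model (collisions with segregating or fixed positions
re-drawn).  Sites fixed in the pooled metapopulation are compacted but
remain queryable and re-enter samples as substitution columns.

The canonical experiment is: 10N generations of neutral burn-in; a single
beneficial copy introduced at the chromosome centre of p1 and *conditioned
on fixation* (on loss, the stored post-burn-in state is restored and the
allele reintroduced with a per-attempt reseeded RNG); 5N migration-free
generations; then 10N generations of symmetric migration at rate m during
which the allele can introgress into p2, where it is equally beneficial.
Time since fixation is reported in scaled units τ = Δg/(4N).

Full-scale parameter values: N = 1000 diploids per population, L = 750 kb,
μ = 6×10⁻⁷/bp/gen (so 4Nμ = 0.0024 per site), r = 4×10⁻⁷/bp/gen (40 cM/Mb),
s ∈ {0.5, 0.25, 0.1}, m = 10⁻⁴ (M = 2Nm = 0.2), sampling every 100
generations before and 50 after the sweep's introduction.

Design points that were genuinely open and how they were settled:

* **Dominance** is additive (h = 0.5), the convention of forward simulators;
  exposed as a parameter.
* **Origin of p2**: p2 is instantiated as an exact copy of the post-burn-in
  p1 state and evolves neutrally in parallel through the sweep and
  pre-migration phases.  The two populations therefore share standing
  variation at the moment of the split and diverge for ≳6N generations
  before migration begins.
* **The introgressed allele is beneficial in p2** with the same s and h;
  p2 carries no other selected sites.
* **τ = 0** is anchored at the fixation generation in the focal population
  (p1 for classic, p2 for introgressed sweeps).  If a requested snapshot
  falls beyond the 10N migration phase, the run is extended with migration
  kept on; a replicate whose allele never fixes in p2 within the cap is
  reported as failed and re-run with a fresh seed (counts recorded).
* **Sample size**: "sampled individuals" is read as sampled *sequences*
  (haplotypes); the full-scale default is 500 sequences.

## Reduced ("desk") scale

Replicated experiments run at N = 200, L = 50 kb with compound parameters
preserved: μ rescaled so 4Nμ = 0.0024, and r rescaled so the *total map
length* r·L matches the full-scale scenario (0.3 Morgans for the classic
scenario, 0.03 Morgans for the 4 cM/Mb migration-sweep scenario).  Matching
r·L keeps the hitchhiking footprint 1/α = s/(r·ln 2N) at the same fraction
of the chromosome, so the spatial sweep/volcano geometry survives the
rescaling; keeping the literal per-bp rate instead would stretch the
footprint past the whole 50-kb chromosome.  Snapshots sample 50 sequences
(CLR cost grows quadratically in sample size) and the CLR α grid uses 24
log-spaced points in [10⁻⁷, 10] per bp (the full default is 40).  Batches
use 30 replicates for the headline classic scenario and 10–12 for the
others, with scaled_down flagged in the spec.  These problem sizes are the
package's default test profile; full-scale parameters are accepted
throughout but are long-running.

## CLR scan

The scan follows the composite-likelihood construction used by
SweepFinder-class methods.  The background SFS Φ (over derived counts 0..n,
class n fed by substitutions, class 0 never observed) is estimated from
background data.  Under a sweep at distance d with intensity α, each of the
n sampled lineages escapes the sweep independently with probability
p_e = 1 − exp(−α·d); the n−k non-escapees coalesce into one pre-sweep
lineage; the pre-sweep sample of size k+1 draws its derived count from Φ
projected (hypergeometrically) to that size; the swept lineage is a uniform
member of the pre-sweep sample and its allele is copied to all non-escapees.
The per-site probability of the observed count is the exact binomial
mixture over k — precomputed as a kernel matrix V[k, c] per background, so
one scan costs O(sites × n) per (grid point, α).

Both null and sweep distributions are renormalized over classes 1..n
(invariant-ancestral sites are never scored).  Folded sites are scored as
the sum of both orientations under both models.  CLR = 2(max_α log CL_sweep
− log CL_background), clipped at zero; ties in α go to the smallest value
(strongest selection).  Because the α·d → ∞ limit of the sweep model is
exactly the background, CLR ≥ 0 by construction.  This is a faithful
re-derivation of the published model, validated against enumeration oracles
and by its qualitative behaviour — not by output-file identity with any
particular released binary.

Scans of simulated time-course snapshots score polymorphic sites only.  The
simulator knows the true ancestral state, so sample-fixed sites could be
scored as substitutions — but such ancestral-truth substitutions have no
empirical analogue (real data uses an outgroup) and would plant a permanent,
never-decaying signal at the sweep centre.  With polymorphic-only input the
simulated CLR decays to background within ~1 scaled generation, matching
the modelled system.  Substitution records remain fully supported for
empirical-style inputs (`records_from_matrix(include_substitutions=True)`,
polarized freq files).

Polarization mirrors the -OM workflow: biallelic sites called in ≥75% of
focal sequences; one outgroup allele drawn uniformly at random (explicit
seed) from sites with at least `min_outgroup_called` outgroup calls is
declared ancestral; sites failing the threshold are folded with the minor
count; fixed-derived sites become substitutions; fixed-ancestral sites are
dropped.  Mixed per-site sample sizes are reconciled by hypergeometric
expectation (`project_sfs`), which returns fractional class weights per
site; these feed the background-SFS estimator directly.

## Downstream inference

* CLR significance threshold: 99.9th percentile (type-7 linear
  interpolation, numpy's default) of the CLR distribution over background
  regions.
* Effective population size: Ne = π/(4μ); Watterson's-θ variant exposed.
* Selection coefficient: s = r·ln(2Ne)/α̂ with per-chromosome r supplied by
  the user (linkage-map estimates are external data).
* Detection horizon: τ_max · 4Ne · generation time, with τ_max = 0.4 (the
  oldest localizable sweep age) and 0.25-yr generations by default; at
  Ne = 2×10⁶ this is 0.8 Myr, at 0.5×10⁶ 0.2 Myr, at 3.5×10⁶ 1.4 Myr.
* Welch's unequal-variance t test (two-sided) compares sweep-site CLR
  across replicates against the neutral-background CLR distribution; the
  background distribution is the CLR at the *central* grid point of each
  neutral replicate (like-for-like with the sweep site), not all grid
  points pooled.

## Time-course experiments

`timecourse.run_experiment` runs a replicate batch (burn-in → conditioned
sweep → optional introgression → snapshots at the scaled timepoints →
window statistics and CLR scans) and aggregates replicate means/sds per
10-kb window and at fixed offsets from the centre (0, L/37.5, L/18.75 —
proportional to the 0/20 kb/40 kb offsets on a 750-kb chromosome).

Backgrounds are matched in two senses.  (1) Model: classic sweeps are
compared against migration-free neutral runs, introgressed sweeps against
neutral runs with the same migration schedule (p2 cloned at burn-in end,
migration switched on at the batch-mean sweep time).  (2) Depth: neutral
replicates are advanced to the same mean generation as the sweep snapshots
before sampling, so the background SFS carries a comparable load of recent
mutations per timepoint.

`migration_sensitivity` reports, per M, the central π-dip depth and the
flanking Tajima's D elevation.  The dip is measured against the
*no-migration* neutral background: migration inflates diversity everywhere
in the recipient population, so the migration-matched background would mask
the progressive softening of the sweep.  The flank elevation is measured
against the migration-matched background, since it is an excess over what
migration alone produces.

## Synthetic generators

`sample_neutral_matrix` draws independent sites with derived counts from
the neutral equilibrium spectrum q_i ∝ 1/i (or a custom spectrum) at
uniform positions — a stand-in for post-burn-in samples that has a known
ground truth but no linkage disequilibrium, no recombination structure and
no demography.  `make_sweep_fixture` applies the same escape model the CLR
scan assumes (per-lineage escape with probability 1 − exp(−a·d), the rest
copying a uniformly chosen swept lineage), so end-to-end recovery tests
check localization and calibration of the scan, not robustness to model
mismatch; the forward simulations provide the mismatched (linked,
drift-perturbed) test surface.  `make_outgroup_table` emits outgroup
genotypes with controlled divergence and missingness plus a truth table for
polarization accuracy.  Passing these tests therefore demonstrates internal
consistency and correct arithmetic; claims about real resequencing data
(mapping artefacts, genotype error, population structure) are out of reach
of the generators by design.

## Numerical choices and degenerate inputs

* Tajima's D is undefined (None) for S = 0 or n < 4; with missing data the
  pairwise term uses per-site sample sizes and the constants use the mean
  called count (rounded) — exact textbook behaviour on complete matrices.
* ZnS is None with fewer than two segregating sites; pairs with zero
  variance after missing-data removal are skipped.
* π can be divided by window span (simulation mode) or by the number of
  genotyped sites (empirical mode); the per-window QC (≥100 sites genotyped
  in ≥75% of individuals) applies only in empirical mode.
* Windows are 0-based half-open [start, start+size), tiled from 0.
* Site probabilities are floored at 1e-300 before logs; sites with zero
  probability under every model are skipped with a warning.
* Background spectra used for scoring take a pseudo-count (0.5 per class,
  `estimate_background_sfs(smoothing=...)`): with many classes and few
  background sites an interior class can otherwise be empty, and a single
  observed site in that class would dominate the whole composite
  likelihood.  The raw (unsmoothed) estimator remains the default of the
  function itself.
* The beneficial allele is placed at L/2, shifted to the nearest free
  position if occupied; conditioning re-seeds each attempt from
  (seed, replicate, attempt) and raises after a configurable restart cap.
* All stochastic operations are pure functions of (inputs, seed); replicate
  seeds derive from a master seed via numpy SeedSequence and stay below
  2³¹.

## Known limitations

* The simulator is not meant for large N or long chromosomes (dense
  genotype matrices); the rescaled desk profile is the intended regime.
* The CLR model omits recombination-map-aware distances and any
  two-species divergence model; distances are physical bp.
* Empirical-mode Tajima's D with heavy missingness uses an averaged-n
  approximation (documented above) rather than per-site exact constants.
* The neutral synthetic generator has no linkage; LD-based statistics on
  its output are only sanity-checked, not calibrated.
* With very high migration (M ≫ 2) the two populations behave as one; the
  introgressed-sweep signature largely disappears, which is the expected
  biology but limits what the migration sweep can assert there.
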