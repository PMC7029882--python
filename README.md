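# sweepvolcano

Forward Wright–Fisher simulation of classic and introgressed selective
sweeps, SFS-based composite-likelihood sweep scanning, and the downstream
selection inference used to interpret sweep scans — in one tested Python
package.

## Who this is for

Population geneticists studying recent positive selection, and in
particular **adaptive introgression**: alleles that sweep through a
population after arriving by gene flow from a diverged relative (the
textbook case being mimicry colour-pattern alleles exchanged between
hybridising *Heliconius* butterflies).  A classic hard sweep from a new
mutation carves a broad trough of diversity with an excess of rare
variants.  An introgressed sweep instead leaves a "volcano": a narrow
central trough where the donor haplotype fixed, flanked by ridges of
*elevated* diversity and intermediate-frequency variants where
recombination spliced diverged donor fragments into the local background.
This package simulates both processes, measures their signatures, and asks
how long each remains detectable.

## The model and the statistic

**Simulation.**  A discrete-generation Wright–Fisher model of two
populations of N diploids, each individual one recombining chromosome of L
sites: mutation at μ/bp/gen (quasi-infinite sites), crossovers Poisson with
rate r/bp/gen, symmetric migration at per-capita rate m (population-scaled
M = 2Nm), and one beneficial mutation at the chromosome centre with
genotype fitnesses 1, 1+hs, 1+s.  The canonical experiment: 10N generations
of burn-in; a sweep in p1 conditioned on fixation (reset-and-retry on
loss); 5N generations of isolation; 10N generations of migration during
which the allele introgresses into, and sweeps through, p2.  Time since
fixation is reported in scaled units τ = Δgenerations/4N.

**Scan.**  A SweepFinder-style composite likelihood ratio.  Given a
background spectrum Φ over derived counts, a sweep at distance d with
intensity α lets each sampled lineage escape with probability
p\_e = 1 − e^{−αd}; non-escapees coalesce into one lineage whose allele is
drawn through Φ projected to the reduced sample size.  At each grid
position, CLR = 2(max\_α log CL\_sweep − log CL\_background) ≥ 0, and the
fitted α̂ converts to a selection coefficient via

    s = r · ln(2Ne) / α̂ ,      Ne = π / 4μ .

The oldest localizable sweep is τ ≈ 0.4, i.e. 0.4·4Ne·(generation time) in
years — 0.8 Myr at Ne = 2×10⁶ and 3-month generations.

## Worked example

Simulate one classic hard sweep at the reduced scale (N = 200, L = 50 kb,
4Nμ = 0.0024, s = 0.5), sample 50 sequences just after fixation
(τ = 0.01), and scan it against a neutral background:

```python
from sweepvolcano.simcore import (SimParams, run_burn_in, run_conditioned_sweep,
                                  sample_at_timepoints, take_sample)
from sweepvolcano.sumstats import window_scan
from sweepvolcano.clr_scan import (records_from_matrix, estimate_background_sfs,
                                   scan_region, default_alpha_grid)
from sweepvolcano.selection_inference import estimate_ne, selection_coefficient

params = SimParams.desk_scale(sel_coeff=0.5, seed=42)
state = run_burn_in(params)
state, traj = run_conditioned_sweep(state, params)
snap = sample_at_timepoints(state, params, [0.01], traj.fixation_gen_p1,
                            "p1", n_sequences=50)[0]

pool = []           # background SFS pooled over neutral replicates
for s in range(43, 49):
    st = run_burn_in(SimParams.desk_scale(seed=s))
    pool += records_from_matrix(take_sample(st, "p1", 50, seed=s),
                                include_substitutions=False)
background = estimate_background_sfs(pool, smoothing=0.5)

windows = window_scan(snap.matrix, 10_000, chrom_len=params.chrom_len)
grid = [w.window_start + 5_000 for w in windows]
results = scan_region(records_from_matrix(snap.matrix, include_substitutions=False),
                      grid, background, alpha_grid=default_alpha_grid(size=24))

print(f"sweep fixed at generation {traj.fixation_gen_p1} "
      f"after {traj.n_restarts} restarts")
print("window      pi      TajD     CLR   alpha")
for w, r in zip(windows, results):
    d = "  --" if w.tajimas_d is None else f"{w.tajimas_d:+.2f}"
    print(f"{w.window_start:>6}  {w.pi_per_site:.4f}  {d}  {r.clr:6.1f}  {r.alpha_hat:.2e}")

peak = max(results, key=lambda r: r.clr)
ne = estimate_ne(0.0024, params.mu)
s_hat = selection_coefficient(peak.alpha_hat, params.rec, ne)
print(f"Ne = {ne:.0f}, s_hat at peak = {s_hat:.2f} (true s = 0.5)")
```

Output (exactly what the snippet prints):

```
sweep fixed at generation 2063 after 5 restarts
window      pi      TajD     CLR   alpha
     0  0.0021  -0.23     1.8  3.32e-03
 10000  0.0016  -0.72     0.1  7.41e-03
 20000  0.0004  -1.63     2.6  1.35e-04
 30000  0.0017  -0.58     3.3  3.32e-03
 40000  0.0023  +0.01     1.4  1.65e-02
Ne = 200, s_hat at peak = 0.01 (true s = 0.5)
```

The sweep sits at 25 kb.  The window statistics show it unambiguously: the
centre window has lost five sixths of its diversity (π 0.0004 against the
neutral 0.0024) and Tajima's D there is −1.6.  The CLR of a *single*
50-sequence replicate at this reduced scale is modest and noisy — here it
concentrates in the two central windows, and the smallest fitted α̂
(strongest implied selection) lands on the centre.  The replicate-averaged
experiments in `tests/test_acceptance.py` are the calibrated version of
this picture: across 30 replicates the mean CLR profile peaks at the
centre window roughly an order of magnitude above the flanks, decays
five-to-ten-fold between τ = 0.01 and τ = 0.1, and the median α̂ separates
s = 0.5 from s = 0.1 batches cleanly.  The ŝ printed here likewise
underestimates the true s, as expected from one weak-peak replicate —
`selection_coefficient` is calibrated on the replicate-median α̂, not on
single scans.

The same pipeline is scriptable from the shell:

```
sweepvolcano simulate --config sim.yaml --out run/
sweepvolcano stats --haps run/snapshot_tau0.01_p1 --window-size 10000 --out windows.tsv
sweepvolcano scan --freq sites.freq --self-sfs --grid-every 50 --out scan.tsv
sweepvolcano threshold --scan background_scan.tsv --percentile 99.9
sweepvolcano infer --scan scan.tsv --threshold 12.3 --pi 0.016 --mu 2.9e-9 --rec 1e-8 --out region.tsv
```

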