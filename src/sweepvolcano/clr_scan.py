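"""SweepFinder-style composite-likelihood-ratio sweep scan.

The scan compares, at each grid position, a hitchhiking model of the local
site frequency spectrum against an empirical background spectrum.  Under the
hitchhiking model each of the n sampled lineages escapes the sweep
independently with probability p_e = 1 − exp(−α·d) (α the sweep intensity,
d the distance in bp from the tested position); the non-escaping lineages
coalesce into a single pre-sweep lineage, the pre-sweep sample draws its
derived count from the background spectrum projected to its size, and the
swept lineage's allele is copied to every non-escapee.  Small α therefore
means a wide footprint and strong selection (s = r·ln(2Ne)/α).

The composite likelihood multiplies the per-site probabilities of the
observed derived counts (polymorphic sites and substitutions; invariant
ancestral sites are never scored, so both models are renormalized over
derived counts 1..n).  CLR = 2(max_α log CL_sweep − log CL_background),
clipped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .sumstats import HaplotypeMatrix, SiteFrequencySpectrum, project_probs

__all__ = [
    "FreqRecord",
    "ProjectedSites",
    "CLRResult",
    "SweepSpectrumModel",
    "default_alpha_grid",
    "records_from_matrix",
    "polarize_sites",
    "project_sfs",
    "estimate_background_sfs",
    "sweep_transformed_spectrum",
    "clr_at_point",
    "scan_region",
]

MISSING = -1


@dataclass(frozen=True)
class FreqRecord:
    """One scan site: 1-based position, derived (or minor) count x out of n
    called alleles; ``folded`` marks orientation-free sites.  Substitutions
    are encoded as x = n with folded = 0."""

    position: int
    x: int
    n: int
    folded: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.x <= self.n:
            raise ValueError(f"need 1 <= x <= n, got x={self.x}, n={self.n}")
        if self.folded and self.x > self.n - self.x:
            raise ValueError("folded records must carry the minor count")


@dataclass
class ProjectedSites:
    """Sites projected to a common sample size: per-site fractional class
    weights over derived counts 0..n (hypergeometric expectations)."""

    positions: np.ndarray
    weights: np.ndarray  # (n_sites, n_target + 1)
    n: int
    folded: np.ndarray | None = None


@dataclass(frozen=True)
class CLRResult:
    grid_position: int
    clr: float
    alpha_hat: float


def default_alpha_grid(low: float = 1e-7, high: float = 10.0, size: int = 40) -> np.ndarray:
    """Log-spaced grid of sweep intensities α (per bp)."""
    return np.geomspace(low, high, size)


def records_from_matrix(matrix: HaplotypeMatrix, include_substitutions: bool = True) -> list[FreqRecord]:
    """Freq records from a simulated (fully polarized) haplotype matrix.

    Positions are emitted 1-based; sample-fixed derived sites become
    substitutions (x = n) or are dropped when ``include_substitutions`` is
    False (the polymorphic-sites-only data set)."""
    counts = matrix.derived_counts()
    called = matrix.called_counts()
    recs = []
    for pos, x, n, pol in zip(matrix.positions, counts, called, matrix.polarized):
        if x == 0 or n < 2:
            continue
        if x == n and not include_substitutions:
            continue
        if pol:
            recs.append(FreqRecord(position=int(pos) + 1, x=int(x), n=int(n), folded=False))
        else:
            xm = int(min(x, n - x))
            if xm > 0:
                recs.append(FreqRecord(position=int(pos) + 1, x=xm, n=int(n), folded=True))
    return recs


def polarize_sites(
    focal_genotypes: np.ndarray,
    outgroup_genotypes: np.ndarray,
    positions: Sequence[int],
    min_outgroup_called: int = 1,
    seed: int = 0,
    min_focal_fraction: float = 0.75,
) -> list[FreqRecord]:
    """Orient focal allele counts with a randomly drawn outgroup allele.

    ``focal_genotypes`` and ``outgroup_genotypes`` are (sequences x sites)
    allele matrices (0 = REF, 1 = ALT, -1 = missing; other codes are treated
    as alleles absent from the focal sample).  Sites called in fewer than
    ``min_focal_fraction`` of focal sequences are dropped.  For each site
    with at least ``min_outgroup_called`` called outgroup alleles one
    outgroup allele is drawn uniformly (seeded) and declared ancestral;
    remaining sites are emitted folded with the minor count.  Sites fixed
    derived become substitutions; sites fixed ancestral are dropped.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 929])))
    focal = np.asarray(focal_genotypes)
    out = np.asarray(outgroup_genotypes)
    if focal.shape[1] != len(positions) or out.shape[1] != len(positions):
        raise ValueError("genotype matrices and positions disagree on site count")
    records: list[FreqRecord] = []
    n_demoted = 0
    for j, pos in enumerate(positions):
        col = focal[:, j]
        called = col != MISSING
        n = int(called.sum())
        if n < 2 or n < min_focal_fraction * focal.shape[0]:
            continue
        k = int(np.sum(col[called] == 1))  # ALT count
        ocol = out[:, j]
        ocalled = ocol[ocol != MISSING]
        folded = True
        x = None
        if ocalled.size >= min_outgroup_called:
            anc = int(ocalled[rng.integers(0, ocalled.size)])
            if anc == 0:
                x, folded = k, False
            elif anc == 1:
                x, folded = n - k, False
            else:
                n_demoted += 1  # outgroup allele absent from the focal pair
        if folded:
            x = min(k, n - k)
            if x == 0:
                continue  # invariant and unpolarizable
            records.append(FreqRecord(position=int(pos), x=x, n=n, folded=True))
            continue
        if x == 0:
            continue  # fixed ancestral
        records.append(FreqRecord(position=int(pos), x=x, n=n, folded=False))
    if n_demoted:
        warnings.warn(f"{n_demoted} sites demoted to folded (outgroup allele not in focal pair)")
    return records


def project_sfs(records: Iterable[FreqRecord], n_target: int) -> ProjectedSites:
    """Project mixed-n sites to a common sample size by hypergeometric
    expectation; sites with n < n_target are dropped (with a warning).

    Folded records are split half-weight over both orientations before
    projection, so the weight matrix stays on the unfolded axis."""
    from scipy.stats import hypergeom

    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    recs = list(records)
    kept = [r for r in recs if r.n >= n_target]
    if len(kept) < len(recs):
        warnings.warn(f"dropped {len(recs) - len(kept)} sites with n < {n_target}")
    positions = np.array([r.position for r in kept], dtype=np.int64)
    weights = np.zeros((len(kept), n_target + 1))
    folded = np.array([r.folded for r in kept], dtype=bool)
    j = np.arange(n_target + 1)
    for i, r in enumerate(kept):
        if r.folded and r.x != r.n - r.x:
            w = 0.5 * hypergeom.pmf(j, r.n, r.x, n_target)
            w = w + 0.5 * hypergeom.pmf(j, r.n, r.n - r.x, n_target)
        else:
            w = hypergeom.pmf(j, r.n, r.x, n_target)
        weights[i] = w
    return ProjectedSites(positions=positions, weights=weights, n=n_target, folded=folded)


def estimate_background_sfs(
    records: Iterable[FreqRecord] | ProjectedSites,
    include_invariant_classes: bool = True,
    folded: bool = False,
    smoothing: float = 0.0,
) -> SiteFrequencySpectrum:
    """Empirical background spectrum from scan records.

    Folded records contribute half-weight to each orientation; substitutions
    populate the count-n class when invariant classes are included.  Class 0
    (invariant ancestral) is never observed and stays empty.  ``smoothing``
    adds a pseudo-count to every scoreable class so that sparse backgrounds
    (few sites, many classes) never assign zero probability to an observable
    count; set it to 0 for the raw empirical spectrum.
    """
    if isinstance(records, ProjectedSites):
        if records.weights.shape[0] == 0:
            raise ValueError("no sites to estimate a spectrum from")
        weight = records.weights.sum(axis=0)
        n = records.n
    else:
        recs = list(records)
        if not recs:
            raise ValueError("no sites to estimate a spectrum from")
        ns = {r.n for r in recs}
        if len(ns) != 1:
            raise ValueError("mixed sample sizes; use project_sfs first")
        n = ns.pop()
        weight = np.zeros(n + 1)
        for r in recs:
            if r.folded and r.x != n - r.x:
                weight[r.x] += 0.5
                weight[n - r.x] += 0.5
            else:
                weight[r.x] += 1.0
    weight = np.asarray(weight, dtype=float)
    if smoothing > 0:
        weight[1:] += smoothing
    weight[0] = 0.0
    if not include_invariant_classes:
        weight[n] = 0.0
    tot = weight.sum()
    if tot <= 0:
        raise ValueError("no usable sites after class filtering")
    sfs = SiteFrequencySpectrum(n=n, probs=weight / tot, folded=False)
    return sfs.fold() if folded else sfs


class SweepSpectrumModel:
    """Precomputed hitchhiking kernel for one background spectrum.

    ``V[k, c]`` is the probability of final derived count c given exactly k
    escaping lineages; mixing over k ~ Binomial(n, p_e) yields the
    sweep-transformed spectrum for any (α, d).
    """

    def __init__(self, background: SiteFrequencySpectrum) -> None:
        if background.folded:
            raise ValueError("background must be unfolded with invariant classes")
        self.background = background
        n = background.n
        self.n = n
        V = np.zeros((n + 1, n + 1))
        for k in range(n + 1):
            if k == n:
                V[k] = background.probs
                continue
            m = k + 1
            phi = project_probs(background.probs, n, m)
            for j in range(m + 1):
                pj = phi[j]
                if pj == 0:
                    continue
                # swept lineage is a uniform member of the pre-sweep sample
                V[k, j] += pj * (m - j) / m            # ancestral allele sweeps
                V[k, (j - 1) + (n - k)] += pj * j / m  # derived allele sweeps
        self.V = V
        self._logC = gammaln(n + 1) - gammaln(np.arange(n + 1) + 1) - gammaln(n - np.arange(n + 1) + 1)

    def escape_prob(self, alpha: float, d: np.ndarray | float) -> np.ndarray:
        return -np.expm1(-alpha * np.asarray(d, dtype=float))

    def _binom_weights(self, p_e: np.ndarray) -> np.ndarray:
        """Binomial(n, p_e) pmf over k for each site; shape (sites, n+1)."""
        n = self.n
        k = np.arange(n + 1)
        p = np.clip(p_e, 0.0, 1.0)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            logpmf = self._logC[None, :] + k[None, :] * np.log(p) + (n - k)[None, :] * np.log1p(-p)
        B = np.exp(logpmf)
        B[p[:, 0] == 0.0] = 0.0
        B[p[:, 0] == 0.0, 0] = 1.0
        B[p[:, 0] == 1.0] = 0.0
        B[p[:, 0] == 1.0, n] = 1.0
        return B

    def spectrum(self, alpha: float, d: float) -> SiteFrequencySpectrum:
        if alpha <= 0 or d < 0:
            raise ValueError("need alpha > 0 and d >= 0")
        p_e = self.escape_prob(alpha, np.array([float(d)]))
        probs = (self._binom_weights(p_e) @ self.V)[0]
        probs = np.clip(probs, 0.0, None)
        return SiteFrequencySpectrum(n=self.n, probs=probs / probs.sum(), folded=False)

    def site_probs(self, alpha: float, dists: np.ndarray, x: np.ndarray, folded: np.ndarray) -> np.ndarray:
        """P(observed count | sweep at distance d), renormalized over 1..n,
        folded sites scored as the sum of both orientations."""
        B = self._binom_weights(self.escape_prob(alpha, dists))  # (S, n+1)
        P0 = B @ self.V[:, 0]
        Px = np.einsum("sk,ks->s", B, self.V[:, x])
        both = folded & (x != self.n - x)
        if np.any(both):
            Pnx = np.einsum("sk,ks->s", B[both], self.V[:, self.n - x[both]])
            Px[both] = Px[both] + Pnx
        with np.errstate(divide="ignore", invalid="ignore"):
            out = Px / np.clip(1.0 - P0, 1e-300, None)
        return np.clip(out, 0.0, None)


def sweep_transformed_spectrum(
    background: SiteFrequencySpectrum, alpha: float, d: float
) -> SiteFrequencySpectrum:
    """Exact mixture distribution of derived counts after a sweep at
    distance ``d`` with intensity ``alpha`` (full 0..n, sums to 1)."""
    if alpha <= 0 or d < 0:
        raise ValueError("need alpha > 0 and d >= 0")
    model = SweepSpectrumModel(background)
    p_e = model.escape_prob(alpha, np.array([float(d)]))
    probs = (model._binom_weights(p_e) @ model.V)[0]
    probs = np.clip(probs, 0.0, None)
    return SiteFrequencySpectrum(n=background.n, probs=probs / probs.sum(), folded=False)


def _null_logprobs(
    background: SiteFrequencySpectrum, x: np.ndarray, folded: np.ndarray
) -> np.ndarray:
    n = background.n
    probs = background.probs.copy()
    probs[0] = 0.0
    tot = probs.sum()
    probs = probs / tot
    p = probs[x]
    both = folded & (x != n - x)
    p[both] = p[both] + probs[n - x[both]]
    return p


def clr_at_point(
    records: Sequence[FreqRecord],
    grid_position: int,
    background: SiteFrequencySpectrum,
    alpha_grid: np.ndarray | None = None,
    model: SweepSpectrumModel | None = None,
) -> CLRResult:
    """Composite likelihood ratio for a sweep at ``grid_position``.

    Maximizes over the α grid; CLR = 2(max_α logCL_sweep − logCL_background)
    clipped at zero, ties broken toward the smallest α.  Sites with zero
    probability under both models are skipped with a warning.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0 or np.any(alpha_grid <= 0):
        raise ValueError("alpha_grid must be non-empty and positive")
    recs = sorted(records, key=lambda r: r.position)
    ns = sorted({r.n for r in recs})
    if not recs:
        raise ValueError("no records to scan")
    if len(ns) != 1:
        raise ValueError("mixed sample sizes; project records first")
    if ns[0] != background.n:
        raise ValueError("record sample size does not match the background spectrum")
    x = np.array([r.x for r in recs], dtype=np.int64)
    folded = np.array([r.folded for r in recs], dtype=bool)
    dists = np.abs(np.array([r.position for r in recs], dtype=float) - float(grid_position))
    if model is None:
        model = SweepSpectrumModel(background)
    p_null = _null_logprobs(background, x, folded)
    p_sweep = np.stack(
        [model.site_probs(float(a), dists, x, folded) for a in alpha_grid]
    )  # (A, S)
    # skip only sites unscorable under every model
    dead = (p_null <= 0) & np.all(p_sweep <= 0, axis=0)
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} sites have zero probability under both models; skipped")
    use = ~dead
    with np.errstate(divide="ignore"):
        ll_sweep = np.sum(np.log(np.clip(p_sweep[:, use], 1e-300, None)), axis=1)
        ll_null = float(np.sum(np.log(np.clip(p_null[use], 1e-300, None))))
    best = int(np.argmax(ll_sweep))  # first max = smallest alpha on ties
    clr = max(0.0, 2.0 * (float(ll_sweep[best]) - ll_null))
    return CLRResult(grid_position=int(grid_position), clr=clr, alpha_hat=float(alpha_grid[best]))


def scan_region(
    records: Sequence[FreqRecord],
    grid_spec: int | Sequence[int],
    background: SiteFrequencySpectrum,
    alpha_grid: np.ndarray | None = None,
) -> list[CLRResult]:
    """CLR at every grid point: either every k-th site (``grid_spec=k``) or
    an explicit list of positions; output ordered by position."""
    recs = sorted(records, key=lambda r: r.position)
    if not recs:
        raise ValueError("no records to scan")
    if isinstance(grid_spec, (int, np.integer)):
        k = int(grid_spec)
        if k < 1:
            raise ValueError("grid step must be >= 1")
        if len(recs) < k:
            grid = [recs[len(recs) // 2].position]
        else:
            grid = [r.position for r in recs[k - 1 :: k]]
    else:
        grid = sorted(int(g) for g in grid_spec)
    model = SweepSpectrumModel(background)
    return [
        clr_at_point(recs, g, background, alpha_grid=alpha_grid, model=model) for g in grid
    ]
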