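"""Window-based population-genetic summary statistics.

Operates on binary haplotype matrices (rows = sequences, columns = sites with
physical positions).  Provides the site frequency spectrum, nucleotide
diversity (π), Tajima's D and Kelly's ZnS, plus a non-overlapping window scan
with the coverage QC used for empirical genotype tables (≥ ``min_sites`` sites
genotyped in ≥ ``min_call_fraction`` of individuals).

Two window modes are supported:

* ``simulation`` — every base pair is callable; π is divided by the window
  length and no QC is applied (10-kb windows by convention).
* ``empirical`` — per-site sample sizes come from a callable mask; π is
  divided by the number of genotyped sites and windows failing QC are dropped
  (1-kb windows by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "HaplotypeMatrix",
    "SiteFrequencySpectrum",
    "WindowStat",
    "compute_sfs",
    "nucleotide_diversity",
    "tajimas_d",
    "kellys_zns",
    "window_scan",
]

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Sampled binary derived/ancestral matrix with physical positions.

    ``states`` holds 0 (ancestral), 1 (derived) and -1 (missing, empirical
    mode only).  ``substitution`` flags sites fixed derived within the sample;
    ``polarized`` flags sites with known ancestral orientation.  Positions are
    0-based base-pair coordinates, strictly increasing.
    """

    positions: np.ndarray
    states: np.ndarray
    polarized: np.ndarray | None = None
    substitution: np.ndarray | None = None
    chrom_len: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D (sequences x sites) array")
        if self.states.shape[1] != self.positions.shape[0]:
            raise ValueError("positions and states disagree on site count")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.polarized is None:
            self.polarized = np.ones(self.n_sites, dtype=bool)
        else:
            self.polarized = np.asarray(self.polarized, dtype=bool)
        counts = self.derived_counts()
        called = self.called_counts()
        if self.substitution is None:
            self.substitution = (counts == called) & (called > 0)
        else:
            self.substitution = np.asarray(self.substitution, dtype=bool)
        if np.any(counts[self.substitution] != called[self.substitution]):
            raise ValueError("substitution sites must be fixed derived among called sequences")

    @property
    def n_sequences(self) -> int:
        return int(self.states.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.states.shape[1])

    @property
    def has_missing(self) -> bool:
        return bool(np.any(self.states == MISSING))

    def called_counts(self) -> np.ndarray:
        """Number of non-missing calls per site."""
        return np.sum(self.states != MISSING, axis=0).astype(np.int64)

    def derived_counts(self) -> np.ndarray:
        return np.sum(self.states == 1, axis=0).astype(np.int64)

    def site_slice(self, start: int, end: int) -> np.ndarray:
        """Indices of sites with start <= position < end."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="left")
        return np.arange(lo, hi)

    def subset_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            positions=self.positions[idx],
            states=self.states[:, idx],
            polarized=self.polarized[idx],
            substitution=self.substitution[idx],
            chrom_len=self.chrom_len,
            metadata=dict(self.metadata),
        )


@dataclass
class SiteFrequencySpectrum:
    """Normalized distribution of derived-allele counts 0..n in a sample.

    ``probs[j]`` is the probability that a site carries j derived copies.
    Classes 0 and n model invariant-ancestral sites and substitutions; most
    estimators leave class 0 empty.  ``folded`` spectra put all mass on
    j <= floor(n/2).
    """

    n: int
    probs: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.n + 1,):
            raise ValueError("probs must have length n + 1")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative SFS probability")
        tot = self.probs.sum()
        if not math.isclose(tot, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"SFS probabilities sum to {tot}, expected 1")
        if self.folded and np.any(self.probs[self.n // 2 + 1 :] > 1e-12):
            raise ValueError("folded spectrum has mass above n/2")

    def project(self, m: int) -> "SiteFrequencySpectrum":
        """Hypergeometric projection to a subsample of size ``m``."""
        if self.folded:
            raise ValueError("cannot project a folded spectrum")
        if not 1 <= m <= self.n:
            raise ValueError("projection size out of range")
        probs = project_probs(self.probs, self.n, m)
        return SiteFrequencySpectrum(n=m, probs=probs, folded=False)

    def expected_pi(self) -> float:
        """Mean pairwise difference per site implied by the spectrum."""
        n = self.n
        j = np.arange(n + 1)
        return float(np.sum(self.probs * 2.0 * j * (n - j) / (n * (n - 1))))

    def fold(self) -> "SiteFrequencySpectrum":
        if self.folded:
            return self
        n = self.n
        probs = np.zeros(n + 1)
        for j in range(n + 1):
            k = min(j, n - j)
            probs[k] += self.probs[j]
        return SiteFrequencySpectrum(n=n, probs=probs, folded=True)


def project_probs(probs: np.ndarray, n: int, m: int) -> np.ndarray:
    """Project a count distribution on 0..n down to 0..m (hypergeometric)."""
    J = np.arange(n + 1)
    out = np.zeros(m + 1)
    for j in range(m + 1):
        out[j] = float(np.sum(probs * hypergeom.pmf(j, n, J, m)))
    s = out.sum()
    return out / s


@dataclass
class WindowStat:
    """Per-window summary statistics over a half-open interval [start, end)."""

    window_start: int
    window_end: int
    n_sites_genotyped: int
    S: int
    pi_per_site: float
    tajimas_d: float | None
    kellys_zns: float | None


def _check_uniform_n(matrix: HaplotypeMatrix) -> int:
    called = matrix.called_counts()
    if matrix.n_sites and not np.all(called == called[0]):
        raise ValueError("sites have unequal sample sizes; project first")
    return int(called[0]) if matrix.n_sites else matrix.n_sequences


def compute_sfs(
    matrix: HaplotypeMatrix,
    include_invariant_classes: bool = False,
    folded: bool = False,
) -> SiteFrequencySpectrum:
    """Site frequency spectrum of a haplotype matrix.

    Unfolded spectra use polarized sites only; a folded spectrum uses every
    site with its minor-allele count.  Substitutions (derived count = n) are
    kept only when ``include_invariant_classes`` is set.
    """
    if matrix.n_sites == 0:
        raise ValueError("cannot compute an SFS from an empty matrix")
    n = _check_uniform_n(matrix)
    counts = matrix.derived_counts()
    weight = np.zeros(n + 1)
    if folded:
        folded_counts = np.minimum(counts, n - counts)
        for c in folded_counts:
            weight[c] += 1.0
        if not include_invariant_classes:
            weight[0] = 0.0
    else:
        use = matrix.polarized
        if not np.any(use):
            raise ValueError("no polarized sites; request a folded spectrum")
        for c in counts[use]:
            weight[c] += 1.0
        if not include_invariant_classes:
            weight[0] = 0.0
            weight[n] = 0.0
    tot = weight.sum()
    if tot == 0:
        raise ValueError("no sites left after filtering invariant classes")
    return SiteFrequencySpectrum(n=n, probs=weight / tot, folded=folded)


def _window_site_stats(matrix: HaplotypeMatrix, idx: np.ndarray):
    x = matrix.derived_counts()[idx]
    n = matrix.called_counts()[idx]
    seg = (x > 0) & (x < n) & (n >= 2)
    return x, n, seg


def nucleotide_diversity(
    matrix: HaplotypeMatrix,
    window: tuple[int, int],
    denominator: str = "span",
) -> float:
    """Per-site nucleotide diversity π in a half-open window.

    π = Σ_sites 2x(n−x)/(n(n−1)) divided by the window length
    (``denominator='span'``, simulation mode) or by the number of genotyped
    sites (``denominator='genotyped'``, empirical mode).
    """
    start, end = window
    idx = matrix.site_slice(start, end)
    x, n, _ = _window_site_stats(matrix, idx)
    if idx.size and np.any(n < 2):
        raise ValueError("fewer than two called sequences at a site")
    if matrix.n_sequences < 2:
        raise ValueError("need at least two sequences")
    num = float(np.sum(2.0 * x * (n - x) / (n * (n - 1.0)))) if idx.size else 0.0
    if denominator == "span":
        denom = end - start
    elif denominator == "genotyped":
        denom = idx.size
        if denom == 0:
            return float("nan")
    else:
        raise ValueError("denominator must be 'span' or 'genotyped'")
    return num / denom


def _tajima_constants(n: int) -> dict:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(matrix: HaplotypeMatrix, window: tuple[int, int] | None = None) -> float | None:
    """Tajima's (1989) D over a window; None when S = 0 or n < 4.

    With missing data the per-site sample size enters the pairwise sum and
    the normalizing constants use the mean called count (rounded); on
    complete matrices this is the textbook statistic.
    """
    if window is None:
        window = (int(matrix.positions[0]) if matrix.n_sites else 0,
                  int(matrix.positions[-1]) + 1 if matrix.n_sites else 1)
    idx = matrix.site_slice(*window)
    x, n, seg = _window_site_stats(matrix, idx)
    S = int(np.sum(seg))
    if S == 0:
        return None
    n_eff = int(round(float(np.mean(n[seg]))))
    if n_eff < 4:
        return None
    pi_sum = float(np.sum(2.0 * x[seg] * (n[seg] - x[seg]) / (n[seg] * (n[seg] - 1.0))))
    k = _tajima_constants(n_eff)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return (pi_sum - theta_w) / math.sqrt(var)


def _pairwise_r2(col_a: np.ndarray, col_b: np.ndarray) -> float | None:
    ok = (col_a != MISSING) & (col_b != MISSING)
    a = col_a[ok].astype(float)
    b = col_b[ok].astype(float)
    if a.size < 2:
        return None
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va <= 0 or vb <= 0:
        return None
    D = float(np.mean(a * b)) - pa * pb
    return D * D / (va * vb)


def kellys_zns(matrix: HaplotypeMatrix, window: tuple[int, int] | None = None) -> float | None:
    """Kelly's ZnS: mean pairwise r² among segregating sites in a window."""
    if window is None:
        window = (0, int(matrix.positions[-1]) + 1 if matrix.n_sites else 1)
    idx = matrix.site_slice(*window)
    _, _, seg = _window_site_stats(matrix, idx)
    seg_idx = idx[seg]
    if seg_idx.size < 2:
        return None
    cols = matrix.states[:, seg_idx]
    if not matrix.has_missing:
        X = cols.astype(float)
        p = X.mean(axis=0)
        v = p * (1 - p)
        Dm = (X.T @ X) / X.shape[0] - np.outer(p, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = Dm * Dm / np.outer(v, v)
        iu = np.triu_indices(seg_idx.size, k=1)
        vals = r2[iu]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else None
    vals = []
    for i in range(seg_idx.size):
        for j in range(i + 1, seg_idx.size):
            r2 = _pairwise_r2(cols[:, i], cols[:, j])
            if r2 is not None:
                vals.append(r2)
    return float(np.mean(vals)) if vals else None


def window_scan(
    matrix: HaplotypeMatrix,
    window_size: int,
    min_sites: int = 0,
    min_call_fraction: float = 0.0,
    mode: str = "simulation",
    chrom_len: int | None = None,
) -> list[WindowStat]:
    """Tile non-overlapping half-open windows from coordinate 0 and summarise.

    Empirical mode first drops sites called in fewer than
    ``min_call_fraction`` of sequences, then drops whole windows with fewer
    than ``min_sites`` qualifying sites.  Simulation mode applies no QC and
    divides π by the window span.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if mode not in ("simulation", "empirical"):
        raise ValueError("mode must be 'simulation' or 'empirical'")
    total = chrom_len or matrix.chrom_len
    if total is None:
        total = int(matrix.positions[-1]) + 1 if matrix.n_sites else window_size
    work = matrix
    if mode == "empirical" and min_call_fraction > 0 and matrix.n_sites:
        frac = matrix.called_counts() / matrix.n_sequences
        work = matrix.subset_sites(np.flatnonzero(frac >= min_call_fraction))
    out: list[WindowStat] = []
    for start in range(0, total, window_size):
        end = min(start + window_size, total)
        idx = work.site_slice(start, end)
        n_geno = (end - start) if mode == "simulation" else int(idx.size)
        if mode == "empirical" and idx.size < min_sites:
            continue
        x, n, seg = _window_site_stats(work, idx)
        denom = "span" if mode == "simulation" else "genotyped"
        pi = nucleotide_diversity(work, (start, end), denominator=denom)
        out.append(
            WindowStat(
                window_start=start,
                window_end=end,
                n_sites_genotyped=n_geno,
                S=int(np.sum(seg)),
                pi_per_site=pi if not math.isnan(pi) else 0.0,
                tajimas_d=tajimas_d(work, (start, end)),
                kellys_zns=kellys_zns(work, (start, end)),
            )
        )
    return out
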