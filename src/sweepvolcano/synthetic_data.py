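"""Generators for download-free test inputs.

Everything the scan half of the toolkit consumes can be emulated here:
neutral matrices drawn from a known frequency spectrum (the equilibrium
1/i form by default), hitchhiking fixtures with a planted sweep centre
following the same escape model the CLR scan assumes, outgroup genotype
tables with controlled divergence and missingness for polarization tests,
and tiny hand-checkable matrices with oracle-verified statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats import HaplotypeMatrix

__all__ = [
    "GeneratorSpec",
    "OutgroupTable",
    "sample_neutral_matrix",
    "make_sweep_fixture",
    "make_outgroup_table",
    "toy_fixtures",
]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic matrix generators.

    Either ``n_sites`` is given directly or it is drawn Poisson with mean
    theta·length·a_{n-1} (Watterson's expectation).  ``spectrum`` is
    'neutral_1_over_i' or an explicit probability vector over derived counts
    1..n-1.  ``sweep_alpha_d_scale`` is the per-bp escape-rate parameter a in
    p_e = 1 − exp(−a·d) used by the sweep fixture.
    """

    n_sequences: int = 20
    length: int = 100_000
    n_sites: int | None = None
    theta: float | None = None
    spectrum: str | np.ndarray = "neutral_1_over_i"
    sweep_centre: int | None = None
    sweep_alpha_d_scale: float | None = None
    n_outgroup: int = 4
    outgroup_missing_rate: float = 0.0
    outgroup_divergence_rate: float = 0.0
    seed: int = 0

    def spectrum_probs(self) -> np.ndarray:
        """Probability of derived count i = 1..n-1 for a segregating site."""
        n = self.n_sequences
        if isinstance(self.spectrum, str):
            if self.spectrum != "neutral_1_over_i":
                raise ValueError(f"unknown spectrum {self.spectrum!r}")
            q = 1.0 / np.arange(1, n)
        else:
            q = np.asarray(self.spectrum, dtype=float)
            if q.shape != (n - 1,):
                raise ValueError("custom spectrum must have length n_sequences - 1")
        return q / q.sum()

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(np.random.SeedSequence([self.seed, 4242])))


@dataclass
class OutgroupTable:
    """Outgroup genotypes plus the polarization truth table."""

    positions: np.ndarray
    genotypes: np.ndarray  # (2 * n_outgroup, n_sites); 0/1/-1
    true_derived_is_one: np.ndarray  # always True in matrix coding
    flipped: np.ndarray  # sites where the outgroup carries the derived allele
    missing: np.ndarray  # sites with no called outgroup allele


def _site_count(spec: GeneratorSpec, rng: np.random.Generator) -> int:
    if spec.n_sites is not None:
        return int(spec.n_sites)
    if spec.theta is None:
        raise ValueError("need n_sites or theta")
    a_n = float(np.sum(1.0 / np.arange(1, spec.n_sequences)))
    return int(rng.poisson(spec.theta * spec.length * a_n))


def sample_neutral_matrix(spec: GeneratorSpec) -> HaplotypeMatrix:
    """Matrix of independent sites with counts drawn from the spectrum.

    Positions are uniform on [0, length); within a count class the carrying
    haplotypes are uniform.  The expected per-site π implied by the spectrum
    is reported in ``metadata['expected_pi_per_segregating_site']``.
    """
    rng = spec.rng()
    n = spec.n_sequences
    S = _site_count(spec, rng)
    probs = spec.spectrum_probs()
    positions = np.sort(rng.choice(spec.length, size=S, replace=False)) if S else np.empty(0, dtype=np.int64)
    counts = rng.choice(np.arange(1, n), size=S, p=probs)
    states = np.zeros((n, S), dtype=np.uint8)
    for j, c in enumerate(counts):
        carriers = rng.choice(n, size=int(c), replace=False)
        states[carriers, j] = 1
    i = np.arange(1, n)
    exp_pi = float(np.sum(probs * 2.0 * i * (n - i) / (n * (n - 1))))
    return HaplotypeMatrix(
        positions=positions,
        states=states,
        chrom_len=spec.length,
        metadata={"expected_pi_per_segregating_site": exp_pi, "seed": spec.seed},
    )


def make_sweep_fixture(spec: GeneratorSpec) -> HaplotypeMatrix:
    """Neutral matrix distorted by a planted sweep at ``sweep_centre``.

    Per site at distance d, each lineage escapes with probability
    1 − exp(−a·d); non-escapees copy the allele of a uniformly chosen swept
    lineage.  Sites rendered monomorphic ancestral are dropped; sites fixed
    derived stay as substitutions.  The true centre is stored in metadata.
    """
    if spec.sweep_centre is None or spec.sweep_alpha_d_scale is None:
        raise ValueError("sweep_centre and sweep_alpha_d_scale are required")
    if not 0 <= spec.sweep_centre < spec.length:
        raise ValueError("sweep_centre outside the chromosome")
    neutral = sample_neutral_matrix(spec)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, 777])))
    n = spec.n_sequences
    a = spec.sweep_alpha_d_scale
    states = neutral.states.copy()
    d = np.abs(neutral.positions - spec.sweep_centre)
    p_e = -np.expm1(-a * d)
    for j in range(states.shape[1]):
        escaped = rng.random(n) < p_e[j]
        swept = int(rng.integers(0, n))
        allele = states[swept, j]
        states[~escaped, j] = allele
        states[swept, j] = allele
    counts = states.sum(axis=0)
    keep = counts > 0
    meta = dict(neutral.metadata)
    meta.update({"sweep_centre": spec.sweep_centre, "sweep_alpha_d_scale": a})
    return HaplotypeMatrix(
        positions=neutral.positions[keep],
        states=states[:, keep],
        chrom_len=spec.length,
        metadata=meta,
    )


def make_outgroup_table(
    matrix: HaplotypeMatrix,
    divergence_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    n_outgroup: int = 4,
) -> OutgroupTable:
    """Outgroup genotypes for each site of ``matrix``.

    The outgroup carries the true ancestral allele (0) except at a fraction
    ``divergence_rate`` of sites where it is fixed for the derived allele;
    individual outgroup calls are missing at ``missing_rate``.  The truth
    table (flipped / missing flags) supports polarization accuracy tests.
    """
    if not 0 <= divergence_rate <= 1 or not 0 <= missing_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 555])))
    S = matrix.n_sites
    n_alleles = 2 * n_outgroup
    flipped = rng.random(S) < divergence_rate
    geno = np.zeros((n_alleles, S), dtype=np.int8)
    geno[:, flipped] = 1
    miss = rng.random((n_alleles, S)) < missing_rate
    geno[miss] = -1
    all_missing = np.all(geno == -1, axis=0)
    return OutgroupTable(
        positions=matrix.positions.copy(),
        genotypes=geno,
        true_derived_is_one=np.ones(S, dtype=bool),
        flipped=flipped,
        missing=all_missing,
    )


def toy_fixtures() -> dict[str, HaplotypeMatrix]:
    """Hand-checkable matrices with their expected statistics in metadata.

    Expected values were fixed after verification against from-scratch
    oracles (the same oracles the test suite re-runs).
    """
    fixtures: dict[str, HaplotypeMatrix] = {}

    # two sequences differing at exactly one site in a 100-bp window: pi = 0.01
    fixtures["pi_pair"] = HaplotypeMatrix(
        positions=np.array([50]),
        states=np.array([[0], [1]], dtype=np.uint8),
        chrom_len=100,
        metadata={"expected_pi_span_100": 0.01},
    )

    # n=4, derived counts {1,2,3}: Tajima's D ~ 0.1677 (textbook constants)
    fixtures["tajima_n4"] = HaplotypeMatrix(
        positions=np.array([10, 20, 30]),
        states=np.array(
            [
                [1, 1, 1],
                [0, 1, 1],
                [0, 0, 1],
                [0, 0, 0],
            ],
            dtype=np.uint8,
        ),
        chrom_len=100,
        metadata={"expected_tajimas_d": 0.1676557950339481},
    )

    # two sites with identical patterns: ZnS = 1
    fixtures["zns_perfect"] = HaplotypeMatrix(
        positions=np.array([5, 15]),
        states=np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.uint8),
        chrom_len=100,
        metadata={"expected_zns": 1.0},
    )

    # site A (1,1,0,0), site B (1,0,1,0): D = 0.25 - 0.25 = 0, ZnS = 0
    fixtures["zns_zero"] = HaplotypeMatrix(
        positions=np.array([5, 15]),
        states=np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8),
        chrom_len=100,
        metadata={"expected_zns": 0.0},
    )

    fixtures["empty"] = HaplotypeMatrix(
        positions=np.empty(0, dtype=np.int64),
        states=np.zeros((4, 0), dtype=np.uint8),
        chrom_len=100,
        metadata={},
    )
    return fixtures
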