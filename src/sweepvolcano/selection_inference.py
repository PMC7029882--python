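"""Downstream inference on CLR scan output.

Empirical significance thresholding (99.9th percentile of background CLR),
effective population size from diversity (Ne = π/4μ), conversion of the
fitted sweep intensity to a selection coefficient (s = r·ln(2Ne)/α), the
detection-horizon arithmetic (τ_max·4Ne·generation time), per-region
summaries and the Welch t test used to compare sweep-site and background
CLR distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .clr_scan import CLRResult

__all__ = [
    "InferenceParams",
    "RegionSummary",
    "clr_threshold",
    "estimate_ne",
    "watterson_theta_ne",
    "selection_coefficient",
    "detection_horizon",
    "region_summary",
    "welch_t_test",
    "cross_species_correlation",
]


@dataclass(frozen=True)
class InferenceParams:
    """Constants entering the downstream conversions.

    ``rec_per_bp`` is the per-chromosome crossover rate per bp per
    generation (from linkage maps), ``mu_real`` the real mutation rate per
    bp per generation, ``gen_time_years`` the generation time (butterflies:
    0.25 yr), ``tau_max`` the oldest localizable sweep age in units of 4Ne
    generations, and ``threshold_percentile`` the empirical CLR cut-off.
    """

    rec_per_bp: float = 1e-8
    mu_real: float = 2.9e-9
    gen_time_years: float = 0.25
    tau_max: float = 0.4
    threshold_percentile: float = 99.9

    def __post_init__(self) -> None:
        if min(self.rec_per_bp, self.mu_real, self.gen_time_years, self.tau_max) <= 0:
            raise ValueError("all rates and times must be positive")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold_percentile must be in (0, 100)")


@dataclass
class RegionSummary:
    region_id: str
    pct_above_threshold: float
    max_inv_alpha: float
    peak: CLRResult


def clr_threshold(background_clrs: Sequence[float], percentile: float = 99.9) -> float:
    """Linear-interpolation (type-7) percentile of the background CLR values."""
    vals = np.asarray(list(background_clrs), dtype=float)
    if vals.size == 0:
        raise ValueError("empty background CLR list")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(vals, percentile, method="linear"))


def estimate_ne(pi_per_site: float, mu_real: float) -> float:
    """Effective population size from diversity: Ne = π/(4μ)."""
    if mu_real <= 0:
        raise ValueError("mutation rate must be positive")
    if pi_per_site <= 0:
        raise ValueError("diversity must be positive")
    return pi_per_site / (4.0 * mu_real)


def watterson_theta_ne(S: int, n: int, length: int, mu_real: float) -> float:
    """Alternative Ne from Watterson's θ: S/(a_{n-1}·L·4μ)."""
    if mu_real <= 0 or length <= 0 or n < 2:
        raise ValueError("invalid inputs")
    a = float(np.sum(1.0 / np.arange(1, n)))
    return S / (a * length * 4.0 * mu_real)


def selection_coefficient(alpha_hat: float, rec_per_bp: float, ne: float) -> float:
    """Selection coefficient implied by a fitted sweep intensity:
    s = r·ln(2Ne)/α."""
    if alpha_hat <= 0:
        raise ValueError("alpha must be positive")
    if rec_per_bp <= 0 or ne <= 0:
        raise ValueError("recombination rate and Ne must be positive")
    return rec_per_bp * math.log(2.0 * ne) / alpha_hat


def detection_horizon(ne: float, gen_time_years: float = 0.25, tau_max: float = 0.4) -> float:
    """Oldest detectable sweep age in years: τ_max · 4Ne · generation time."""
    if ne <= 0 or gen_time_years <= 0 or tau_max <= 0:
        raise ValueError("all arguments must be positive")
    return tau_max * 4.0 * ne * gen_time_years


def region_summary(results: Sequence[CLRResult], threshold: float, region_id: str = "") -> RegionSummary:
    """Fraction of grid points above threshold, the strongest implied
    selection (max 1/α̂) and the peak CLR (smallest position on ties)."""
    if not results:
        raise ValueError("empty result list")
    clrs = np.array([r.clr for r in results])
    pct = 100.0 * float(np.sum(clrs > threshold)) / len(results)
    max_inv_alpha = float(max(1.0 / r.alpha_hat for r in results))
    ordered = sorted(results, key=lambda r: (-r.clr, r.grid_position))
    return RegionSummary(
        region_id=region_id,
        pct_above_threshold=pct,
        max_inv_alpha=max_inv_alpha,
        peak=ordered[0],
    )


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Unequal-variance t statistic, Welch–Satterthwaite df, two-sided p."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cross_species_correlation(
    summary_a: Sequence[RegionSummary],
    summary_b: Sequence[RegionSummary],
    attribute: str = "pct_above_threshold",
) -> float | None:
    """Pearson correlation of a summary attribute across paired regions
    (e.g. co-mimic populations); None when undefined (a constant vector)."""
    if len(summary_a) != len(summary_b):
        raise ValueError("summaries must be paired")
    if len(summary_a) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([getattr(s, attribute) for s in summary_a], dtype=float)
    y = np.array([getattr(s, attribute) for s in summary_b], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
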