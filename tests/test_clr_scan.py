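"""Composite-likelihood sweep scan: polarization, projection, CLR."""

import warnings
from itertools import product

import numpy as np
import pytest
from scipy.stats import hypergeom

from sweepvolcano.clr_scan import (
    CLRResult,
    FreqRecord,
    SweepSpectrumModel,
    clr_at_point,
    default_alpha_grid,
    estimate_background_sfs,
    polarize_sites,
    project_sfs,
    records_from_matrix,
    scan_region,
    sweep_transformed_spectrum,
)
from sweepvolcano.sumstats import SiteFrequencySpectrum, project_probs
from sweepvolcano.synthetic_data import GeneratorSpec, sample_neutral_matrix


def random_background(n, seed):
    rng = np.random.default_rng(seed)
    probs = rng.random(n + 1)
    probs[0] = 0.0
    return SiteFrequencySpectrum(n=n, probs=probs / probs.sum())


def brute_force_sweep_spectrum(bg: SiteFrequencySpectrum, alpha: float, d: float) -> np.ndarray:
    """Exhaustive enumeration over all escape configurations and pre-sweep
    draws (independent oracle for small n)."""
    n = bg.n
    p_e = -np.expm1(-alpha * d)
    out = np.zeros(n + 1)
    for esc in product([0, 1], repeat=n):
        k = sum(esc)
        w = p_e**k * (1 - p_e) ** (n - k)
        if k == n:
            out += w * bg.probs
            continue
        m = k + 1
        phi = project_probs(bg.probs, n, m)
        for j in range(m + 1):
            out[j] += w * phi[j] * (m - j) / m
            out[(j - 1) + (n - k)] += w * phi[j] * j / m
    return out


class TestPolarize:
    def test_outgroup_monomorphic_ancestral(self):
        focal = np.zeros((10, 1), dtype=np.int8)
        focal[:3, 0] = 1
        outgroup = np.zeros((8, 1), dtype=np.int8)
        recs = polarize_sites(focal, outgroup, [101], min_outgroup_called=1, seed=0)
        assert recs == [FreqRecord(position=101, x=3, n=10, folded=False)]

    def test_missing_outgroup_falls_back_to_folded(self):
        focal = np.zeros((10, 1), dtype=np.int8)
        focal[:7, 0] = 1
        outgroup = np.full((8, 1), -1, dtype=np.int8)
        recs = polarize_sites(focal, outgroup, [5], min_outgroup_called=1, seed=0)
        assert recs == [FreqRecord(position=5, x=3, n=10, folded=True)]

    def test_heterozygous_outgroup_orientation_is_fair(self):
        focal = np.zeros((10, 1), dtype=np.int8)
        focal[:3, 0] = 1
        outgroup = np.array([[0], [1], [0], [1]], dtype=np.int8)
        xs = []
        for seed in range(200):
            (rec,) = polarize_sites(focal, outgroup, [7], min_outgroup_called=1, seed=seed)
            xs.append(rec.x)
        frac3 = np.mean(np.array(xs) == 3)
        assert set(xs) == {3, 7}
        assert abs(frac3 - 0.5) < 3.5 * np.sqrt(0.25 / 200)

    def test_fixed_derived_becomes_substitution(self):
        focal = np.ones((10, 1), dtype=np.int8)
        outgroup = np.zeros((4, 1), dtype=np.int8)
        recs = polarize_sites(focal, outgroup, [3], min_outgroup_called=1, seed=0)
        assert recs == [FreqRecord(position=3, x=10, n=10, folded=False)]

    def test_third_allele_in_outgroup_demotes_to_folded(self):
        focal = np.zeros((10, 1), dtype=np.int8)
        focal[:4, 0] = 1
        outgroup = np.full((4, 1), 2, dtype=np.int8)
        with pytest.warns(UserWarning, match="demoted"):
            recs = polarize_sites(focal, outgroup, [9], min_outgroup_called=1, seed=0)
        assert recs == [FreqRecord(position=9, x=4, n=10, folded=True)]

    def test_low_call_focal_sites_dropped(self):
        focal = np.full((10, 1), -1, dtype=np.int8)
        focal[:4, 0] = 1
        focal[4:6, 0] = 0  # 6/10 called < 75%
        outgroup = np.zeros((4, 1), dtype=np.int8)
        assert polarize_sites(focal, outgroup, [9], seed=0) == []


class TestProjection:
    def test_hypergeometric_example(self):
        proj = project_sfs([FreqRecord(position=1, x=2, n=4)], 2)
        assert proj.weights[0] == pytest.approx([1 / 6, 4 / 6, 1 / 6])

    def test_identity_projection(self):
        rec = FreqRecord(position=1, x=3, n=6)
        proj = project_sfs([rec], 6)
        expected = np.zeros(7)
        expected[3] = 1.0
        assert proj.weights[0] == pytest.approx(expected)

    def test_all_sites_too_small_warns_and_empties(self):
        with pytest.warns(UserWarning, match="dropped"):
            proj = project_sfs([FreqRecord(position=1, x=1, n=3)], 5)
        assert proj.weights.shape[0] == 0

    def test_rejects_tiny_target(self):
        with pytest.raises(ValueError):
            project_sfs([FreqRecord(position=1, x=1, n=4)], 1)

    def test_projection_matches_direct_hypergeometric(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            x = int(rng.integers(1, n + 1))
            m = int(rng.integers(2, n + 1))
            proj = project_sfs([FreqRecord(position=1, x=x, n=n)], m)
            want = hypergeom.pmf(np.arange(m + 1), n, x, m)
            assert proj.weights[0] == pytest.approx(want, abs=1e-10)


class TestBackgroundSFS:
    def test_single_record(self):
        sfs = estimate_background_sfs([FreqRecord(position=1, x=1, n=4)])
        assert sfs.probs[1] == pytest.approx(1.0)

    def test_folded_records_split_half_weight(self):
        sfs = estimate_background_sfs([FreqRecord(position=1, x=1, n=4, folded=True)])
        assert sfs.probs[1] == pytest.approx(0.5)
        assert sfs.probs[3] == pytest.approx(0.5)

    def test_substitutions_only_shift_class_n(self):
        poly = [FreqRecord(position=i, x=1 + i % 3, n=6) for i in range(30)]
        subs = [FreqRecord(position=100 + i, x=6, n=6) for i in range(10)]
        a = estimate_background_sfs(poly, include_invariant_classes=True)
        b = estimate_background_sfs(poly + subs, include_invariant_classes=True)
        ra = a.probs[1:6] / a.probs[1:6].sum()
        rb = b.probs[1:6] / b.probs[1:6].sum()
        assert ra == pytest.approx(rb)
        assert b.probs[6] > a.probs[6]

    def test_neutral_generator_spectrum(self):
        m = sample_neutral_matrix(GeneratorSpec(n_sequences=8, length=50_000, n_sites=4000, seed=2))
        sfs = estimate_background_sfs(records_from_matrix(m))
        q = (1 / np.arange(1, 8)) / np.sum(1 / np.arange(1, 8))
        se = np.sqrt(q * (1 - q) / 4000)
        assert np.all(np.abs(sfs.probs[1:8] - q) < 5 * se)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            estimate_background_sfs([])


class TestSweepSpectrum:
    @pytest.mark.parametrize("n", [3, 4])
    @pytest.mark.parametrize("alpha,d", [(0.7, 1.0), (0.05, 3.0), (2.0, 0.5)])
    def test_matches_enumeration_oracle(self, n, alpha, d):
        bg = random_background(n, seed=n)
        got = sweep_transformed_spectrum(bg, alpha, d).probs
        want = brute_force_sweep_spectrum(bg, alpha, d)
        assert got == pytest.approx(want, abs=1e-12)

    def test_infinite_distance_recovers_background(self):
        bg = random_background(6, seed=1)
        got = sweep_transformed_spectrum(bg, 10.0, 1e9).probs
        assert np.max(np.abs(got - bg.probs)) < 1e-9

    def test_zero_distance_puts_all_mass_on_boundaries(self):
        bg = random_background(6, seed=2)
        got = sweep_transformed_spectrum(bg, 1.0, 0.0).probs
        assert got[0] + got[6] == pytest.approx(1.0)

    def test_sums_to_one_for_random_parameters(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 20))
            bg = random_background(n, seed=int(rng.integers(1 << 30)))
            alpha = float(10 ** rng.uniform(-6, 1))
            d = float(rng.uniform(0, 1e5))
            probs = sweep_transformed_spectrum(bg, alpha, d).probs
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_parameters(self):
        bg = random_background(4, seed=3)
        with pytest.raises(ValueError):
            sweep_transformed_spectrum(bg, 0.0, 1.0)
        with pytest.raises(ValueError):
            sweep_transformed_spectrum(bg, 1.0, -1.0)


class TestCLR:
    def _records_from_spectrum(self, bg, positions, seed):
        rng = np.random.default_rng(seed)
        probs = bg.probs.copy()
        probs[0] = 0
        probs /= probs.sum()
        xs = rng.choice(np.arange(bg.n + 1), size=len(positions), p=probs)
        return [
            FreqRecord(position=int(p), x=int(x), n=bg.n)
            for p, x in zip(positions, xs)
        ]

    def test_single_alpha_matches_direct_arithmetic(self):
        bg = random_background(6, seed=4)
        positions = np.arange(100, 2100, 100)
        recs = self._records_from_spectrum(bg, positions, seed=0)
        alpha = 1e-3
        res = clr_at_point(recs, 1000, bg, alpha_grid=[alpha])
        # independent arithmetic: renormalized spectra at each distance
        ll_sweep = ll_null = 0.0
        null_probs = bg.probs.copy()
        null_probs[0] = 0
        null_probs /= null_probs.sum()
        for r in recs:
            d = abs(r.position - 1000)
            probs = sweep_transformed_spectrum(bg, alpha, d).probs
            probs = probs / probs[1:].sum()
            ll_sweep += np.log(probs[r.x])
            ll_null += np.log(null_probs[r.x])
        want = max(0.0, 2 * (ll_sweep - ll_null))
        assert res.clr == pytest.approx(want, rel=1e-9, abs=1e-9)
        assert res.alpha_hat == alpha

    def test_null_records_give_small_nonnegative_clr(self):
        bg = random_background(8, seed=6)
        clrs = []
        for seed in range(60):
            recs = self._records_from_spectrum(bg, np.arange(50, 5050, 50), seed=seed)
            res = clr_at_point(recs, 2500, bg, alpha_grid=default_alpha_grid(size=16))
            clrs.append(res.clr)
        clrs = np.array(clrs)
        assert np.all(clrs >= 0)
        assert np.median(clrs) <= np.percentile(clrs, 99)
        assert np.median(clrs) < 5.0

    def test_clr_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            bg = random_background(n, seed=int(rng.integers(1 << 30)))
            recs = self._records_from_spectrum(
                bg, np.sort(rng.choice(10_000, 50, replace=False)) + 1, seed=int(rng.integers(1 << 30))
            )
            res = clr_at_point(recs, 5000, bg, alpha_grid=default_alpha_grid(size=10))
            assert res.clr >= 0

    def test_folded_records_are_scored(self):
        bg = random_background(6, seed=8)
        recs = [FreqRecord(position=100 * i + 1, x=2, n=6, folded=True) for i in range(20)]
        res = clr_at_point(recs, 1000, bg, alpha_grid=[1e-4, 1e-3])
        assert res.clr >= 0

    def test_mixed_sample_sizes_rejected(self):
        bg = random_background(6, seed=8)
        recs = [FreqRecord(position=1, x=2, n=6), FreqRecord(position=2, x=2, n=5)]
        with pytest.raises(ValueError, match="mixed"):
            clr_at_point(recs, 1, bg)


class TestScanRegion:
    def test_every_50th_site_gives_10_grid_points(self):
        bg = random_background(4, seed=1)
        recs = [FreqRecord(position=i + 1, x=1 + i % 3, n=4) for i in range(500)]
        res = scan_region(recs, 50, bg, alpha_grid=[1e-3])
        assert len(res) == 10
        assert [r.grid_position for r in res] == [r.position for r in recs[49::50]]

    def test_explicit_grid_positions(self):
        bg = random_background(4, seed=1)
        recs = [FreqRecord(position=i + 1, x=1 + i % 3, n=4) for i in range(100)]
        grid = [10, 50, 90]
        res = scan_region(recs, grid, bg, alpha_grid=[1e-3])
        assert [r.grid_position for r in res] == grid

    def test_sparse_grid_is_subsample_of_dense_grid(self):
        bg = random_background(5, seed=2)
        recs = [FreqRecord(position=3 * i + 1, x=1 + i % 4, n=5) for i in range(80)]
        dense = {r.grid_position: r for r in scan_region(recs, 1, bg, alpha_grid=[1e-4, 1e-2])}
        sparse = scan_region(recs, 20, bg, alpha_grid=[1e-4, 1e-2])
        for r in sparse:
            assert r.clr == pytest.approx(dense[r.grid_position].clr, abs=1e-10)
            assert r.alpha_hat == dense[r.grid_position].alpha_hat

    def test_fewer_sites_than_grid_step_gives_central_point(self):
        bg = random_background(4, seed=3)
        recs = [FreqRecord(position=p, x=1, n=4) for p in (10, 20, 30)]
        res = scan_region(recs, 50, bg, alpha_grid=[1e-3])
        assert len(res) == 1
        assert res[0].grid_position == 20
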