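"""Replicate sweep experiments and their time-course summaries.

Orchestrates batches of classic and introgressed sweep simulations, takes
post-fixation snapshots at scaled timepoints, computes 10-kb window π and
Tajima's D profiles and CLR scans against a matched neutral background, and
derives the fixed-offset time series, sweep-versus-background significance
tests and the migration-rate sensitivity table.

Backgrounds are like-for-like: neutral replicates are run to the same
generation depth as the mean sweep replicate (so the substitution load of
the background spectrum matches the swept snapshots) and, for introgressed
scenarios, with the same migration schedule but no beneficial allele.  The
background CLR distribution is the CLR at the central grid point of each
neutral replicate, matching the sweep-site location.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import clr_scan, simcore, sumstats
from .clr_scan import estimate_background_sfs, records_from_matrix, scan_region
from .selection_inference import welch_t_test
from .simcore import SimParams

__all__ = [
    "ExperimentSpec",
    "ProfileSeries",
    "ExperimentResult",
    "run_experiment",
    "decay_ratio",
    "sweep_vs_background_test",
    "migration_sensitivity",
]

DEFAULT_TIMEPOINTS = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0, 2.0)


@dataclass(frozen=True)
class ExperimentSpec:
    """One replicate batch: scenario, simulator parameters, timepoints.

    ``offsets_bp`` are the fixed distances from the sweep centre at which
    the CLR / Tajima's D time series are tracked (0, L/37.5 and L/18.75 by
    default — the spacing used at full scale, kept proportional on shorter
    chromosomes).  ``scaled_down`` marks reduced profiles in the output
    metadata.
    """

    scenario: str = "classic"
    params: SimParams = field(default_factory=SimParams)
    timepoints_scaled: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 100
    migration_values: tuple[float, ...] = (200.0, 2.0, 0.2, 0.02)
    offsets_bp: tuple[int, ...] | None = None
    window_size: int = 10_000
    sample_size: int | None = None
    alpha_grid: tuple[float, ...] | None = None
    n_background: int | None = None  # neutral replicates (default: n_replicates)
    master_seed: int = 0
    scaled_down: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in ("classic", "introgressed", "neutral"):
            raise ValueError("scenario must be classic|introgressed|neutral")
        tps = tuple(self.timepoints_scaled)
        if any(t <= 0 for t in tps) or list(tps) != sorted(tps):
            raise ValueError("timepoints must be positive and ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def offsets(self) -> tuple[int, ...]:
        if self.offsets_bp is not None:
            return tuple(self.offsets_bp)
        L = self.params.chrom_len
        return (0, round(L / 37.5), round(L / 18.75))

    @property
    def effective_sample_size(self) -> int:
        if self.sample_size is not None:
            return self.sample_size
        return min(500, 2 * self.params.n_diploids)

    def alpha_values(self) -> np.ndarray:
        if self.alpha_grid is not None:
            return np.asarray(self.alpha_grid, dtype=float)
        return clr_scan.default_alpha_grid()

    @classmethod
    def desk_scale(
        cls,
        scenario: str = "classic",
        sel_coeff: float = 0.5,
        effective_migration_rate: float = 0.2,
        map_length: float = 0.3,
        timepoints_scaled: tuple[float, ...] = (0.01, 0.1, 1.0),
        n_replicates: int = 30,
        sample_size: int = 50,
        master_seed: int = 0,
        **param_kwargs,
    ) -> "ExperimentSpec":
        """Reduced profile: N=200, L=50 kb, 4Nmu=0.0024, r·L matched to the
        full-scale map length, 24-point α grid."""
        params = SimParams.desk_scale(
            sel_coeff=sel_coeff,
            effective_migration_rate=effective_migration_rate,
            map_length=map_length,
            seed=master_seed,
            **param_kwargs,
        )
        return cls(
            scenario=scenario,
            params=params,
            timepoints_scaled=timepoints_scaled,
            n_replicates=n_replicates,
            sample_size=sample_size,
            alpha_grid=tuple(clr_scan.default_alpha_grid(size=24)),
            master_seed=master_seed,
            scaled_down=True,
        )


@dataclass
class ProfileSeries:
    """Replicate-mean window profiles and offset series at one timepoint."""

    scenario: str
    tau: float
    window_starts: np.ndarray
    stat_means: dict[str, np.ndarray]
    stat_sds: dict[str, np.ndarray]
    offset_series: dict[str, dict[int, tuple[float, float]]]
    n_reps: int


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    profiles: dict[float, ProfileSeries]
    sweep_site_values: dict[str, dict[float, np.ndarray]]  # stat -> tau -> per-rep
    background: "ExperimentResult | None"
    background_clr: dict[float, np.ndarray]  # tau -> per-neutral-rep central CLR
    n_failed: int = 0
    n_restarts_total: int = 0

    @property
    def window_table(self) -> pd.DataFrame:
        rows = []
        M = self.spec.params.effective_migration_rate if self.spec.scenario != "classic" else 0.0
        for tau, prof in self.profiles.items():
            for stat in prof.stat_means:
                for w, m, s in zip(prof.window_starts, prof.stat_means[stat], prof.stat_sds[stat]):
                    rows.append(
                        {
                            "scenario": self.spec.scenario,
                            "M": M,
                            "tau": tau,
                            "window_start": int(w),
                            "stat": stat,
                            "mean": m,
                            "sd": s,
                            "n_reps": prof.n_reps,
                        }
                    )
        return pd.DataFrame(rows)

    @property
    def offset_table(self) -> pd.DataFrame:
        rows = []
        for tau, prof in self.profiles.items():
            for stat, series in prof.offset_series.items():
                for off, (m, s) in series.items():
                    rows.append(
                        {
                            "scenario": self.spec.scenario,
                            "tau": tau,
                            "offset_bp": off,
                            "stat": stat,
                            "mean": m,
                            "sd": s,
                            "n_reps": prof.n_reps,
                        }
                    )
        return pd.DataFrame(rows)

    def sweep_site_mean(self, stat: str, tau: float) -> float:
        return float(np.mean(self.sweep_site_values[stat][tau]))

    def background_window_mean(self, stat: str, tau: float | None = None) -> float:
        src = self.background if self.background is not None else self
        vals = []
        profs = src.profiles
        taus = [tau] if tau is not None and tau in profs else list(profs)
        for t in taus:
            vals.append(profs[t].stat_means[stat])
        arr = np.concatenate(vals)
        return float(np.nanmean(arr))


def _rep_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def _window_values(matrix, spec: ExperimentSpec) -> dict[str, np.ndarray]:
    ws = sumstats.window_scan(matrix, spec.window_size, chrom_len=spec.params.chrom_len)
    return {
        "pi": np.array([w.pi_per_site for w in ws], dtype=float),
        "tajd": np.array(
            [np.nan if w.tajimas_d is None else w.tajimas_d for w in ws], dtype=float
        ),
        "starts": np.array([w.window_start for w in ws], dtype=float),
    }


def _grid_positions(spec: ExperimentSpec) -> list[int]:
    L = spec.params.chrom_len
    centre = L // 2
    wins = [w + spec.window_size // 2 for w in range(0, L, spec.window_size)]
    grid = set(wins) | {centre + off for off in spec.offsets} | {centre}
    return sorted(g + 1 for g in grid)  # records are 1-based


def _snapshot_records(matrix) -> list[clr_scan.FreqRecord]:
    # polymorphic sites only: the simulation has no outgroup, and fixed
    # differences from the true ancestor would plant a permanent (never
    # decaying) signal at the sweep centre that the modelled scans lack
    return records_from_matrix(matrix, include_substitutions=False)


def _collect_sweep_snapshots(spec: ExperimentSpec):
    """Run sweep replicates; returns per-replicate {tau: matrix}, fixation
    offsets, restart and failure counts."""
    seeds = _rep_seeds(spec.master_seed, 4 * spec.n_replicates)
    out = []
    p1_offsets, p2_offsets = [], []
    n_failed = 0
    n_restarts = 0
    seed_iter = iter(seeds)
    while len(out) < spec.n_replicates:
        try:
            seed = next(seed_iter)
        except StopIteration:
            raise RuntimeError("too many failed replicates")
        params = replace(spec.params, seed=seed)
        state = simcore.run_burn_in(params)
        burn_end = state.generation
        if spec.scenario == "introgressed":
            state.add_population_copy("p2")
        try:
            state, traj = simcore.run_conditioned_sweep(state, params)
        except simcore.ConditioningError:
            n_failed += 1
            continue
        n_restarts += traj.n_restarts
        if spec.scenario == "classic":
            snaps = simcore.sample_at_timepoints(
                state,
                params,
                spec.timepoints_scaled,
                reference_gen=traj.fixation_gen_p1,
                population_label="p1",
                n_sequences=spec.effective_sample_size,
                selection_on=True,
                migration_on=False,
            )
            p1_offsets.append(traj.fixation_gen_p1 - burn_end)
        else:
            snaps, traj2 = simcore.run_introgression_phase(
                state, params, spec.timepoints_scaled, n_sequences=spec.effective_sample_size
            )
            if traj2.fixation_gen_p2 is None:
                n_failed += 1
                continue
            p1_offsets.append(traj.fixation_gen_p1 - burn_end)
            p2_offsets.append(traj2.fixation_gen_p2 - burn_end)
        out.append({tau: s.matrix for tau, s in zip(spec.timepoints_scaled, snaps)})
    return out, p1_offsets, p2_offsets, n_failed, n_restarts


def _collect_background_snapshots(
    spec: ExperimentSpec, anchor_p1: int, anchor_ref: int
) -> list[dict[float, object]]:
    """Neutral replicates matched to the sweep batch's generation depth.

    ``anchor_ref`` is the generation offset (past burn-in) playing the role
    of the fixation generation; migration (if any) switches on at
    ``anchor_p1`` + 5N, mirroring the introgression schedule.
    """
    with_migration = spec.scenario == "introgressed"
    n_bg = spec.n_background if spec.n_background is not None else spec.n_replicates
    seeds = _rep_seeds(spec.master_seed + 1, n_bg)
    label = "p2" if with_migration else "p1"
    out = []
    for seed in seeds:
        params = replace(spec.params, seed=seed)
        state = simcore.run_burn_in(params)
        burn_end = state.generation
        if with_migration:
            state.add_population_copy("p2")
            mig_start = burn_end + anchor_p1 + params.pre_migration
            while state.generation < mig_start:
                simcore._step_inplace(state, params, selection_on=False, migration_on=False)
            snaps = simcore.sample_at_timepoints(
                state,
                params,
                spec.timepoints_scaled,
                reference_gen=burn_end + anchor_ref,
                population_label=label,
                n_sequences=spec.effective_sample_size,
                selection_on=False,
                migration_on=True,
            )
        else:
            snaps = simcore.sample_at_timepoints(
                state,
                params,
                spec.timepoints_scaled,
                reference_gen=burn_end + anchor_ref,
                population_label=label,
                n_sequences=spec.effective_sample_size,
                selection_on=False,
                migration_on=False,
            )
        out.append({tau: s.matrix for tau, s in zip(spec.timepoints_scaled, snaps)})
    return out


def _aggregate(
    spec: ExperimentSpec,
    snapshots: list[dict[float, object]],
    backgrounds: list[dict[float, object]] | None,
) -> tuple[dict[float, ProfileSeries], dict[str, dict[float, np.ndarray]], dict[float, np.ndarray]]:
    """Window/offset aggregation plus CLR scans against per-τ background SFS."""
    centre = spec.params.chrom_len // 2
    grid = _grid_positions(spec)
    centre_grid = centre + 1
    profiles: dict[float, ProfileSeries] = {}
    sweep_vals: dict[str, dict[float, np.ndarray]] = {"clr": {}, "tajd": {}, "pi": {}, "alpha": {}}
    bg_clr: dict[float, np.ndarray] = {}
    for tau in spec.timepoints_scaled:
        mats = [rep[tau] for rep in snapshots if tau in rep]
        if not mats:
            continue
        # background SFS at matched depth
        if backgrounds is not None:
            bg_mats = [rep[tau] for rep in backgrounds if tau in rep]
            bg_records = [r for m in bg_mats for r in _snapshot_records(m)]
        else:
            bg_mats = []
            bg_records = [r for m in mats for r in _snapshot_records(m)]
        background_sfs = estimate_background_sfs(
            bg_records, include_invariant_classes=True, smoothing=0.5
        )
        model = clr_scan.SweepSpectrumModel(background_sfs)
        alpha_grid = spec.alpha_values()

        win_vals: dict[str, list[np.ndarray]] = {"pi": [], "tajd": [], "clr": []}
        offset_vals: dict[str, dict[int, list[float]]] = {
            "clr": {o: [] for o in spec.offsets},
            "tajd": {o: [] for o in spec.offsets},
        }
        site_clr, site_tajd, site_pi, site_alpha = [], [], [], []
        starts = None
        for m in mats:
            wv = _window_values(m, spec)
            starts = wv["starts"]
            win_vals["pi"].append(wv["pi"])
            win_vals["tajd"].append(wv["tajd"])
            recs = _snapshot_records(m)
            results = {
                r.grid_position: r
                for r in scan_region(recs, grid, background_sfs, alpha_grid=alpha_grid)
            }
            win_centres = [int(s + spec.window_size // 2) + 1 for s in starts]
            win_vals["clr"].append(np.array([results[c].clr for c in win_centres]))
            for off in spec.offsets:
                res = results[centre_grid + off]
                offset_vals["clr"][off].append(res.clr)
                w_idx = int((centre + off) // spec.window_size)
                w_idx = min(w_idx, len(starts) - 1)
                offset_vals["tajd"][off].append(wv["tajd"][w_idx])
            site = results[centre_grid]
            site_clr.append(site.clr)
            site_alpha.append(site.alpha_hat)
            c_idx = int(centre // spec.window_size)
            site_tajd.append(wv["tajd"][c_idx])
            site_pi.append(wv["pi"][c_idx])
        # CLR of the neutral replicates at the sweep-site grid point
        if bg_mats:
            vals = []
            for m in bg_mats:
                recs = _snapshot_records(m)
                res = clr_scan.clr_at_point(
                    recs, centre_grid, background_sfs, alpha_grid=alpha_grid, model=model
                )
                vals.append(res.clr)
            bg_clr[tau] = np.array(vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat_means = {k: np.nanmean(np.stack(v), axis=0) for k, v in win_vals.items()}
            stat_sds = {k: np.nanstd(np.stack(v), axis=0, ddof=1) for k, v in win_vals.items()}
            offset_series = {
                stat: {
                    off: (float(np.nanmean(v)), float(np.nanstd(v, ddof=1)))
                    for off, v in per_off.items()
                }
                for stat, per_off in offset_vals.items()
            }
        profiles[tau] = ProfileSeries(
            scenario=spec.scenario,
            tau=tau,
            window_starts=starts,
            stat_means=stat_means,
            stat_sds=stat_sds,
            offset_series=offset_series,
            n_reps=len(mats),
        )
        sweep_vals["clr"][tau] = np.array(site_clr)
        sweep_vals["tajd"][tau] = np.array(site_tajd)
        sweep_vals["pi"][tau] = np.array(site_pi)
        sweep_vals["alpha"][tau] = np.array(site_alpha)
    return profiles, sweep_vals, bg_clr


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Run the full replicate batch of one scenario.

    Per replicate: burn-in → conditioned sweep (→ introgression phase) →
    snapshots at the scaled timepoints → window statistics and CLR scans.
    Matched neutral backgrounds are generated for classic and introgressed
    scenarios; ``neutral`` runs are background-style batches themselves.
    Failed replicates (conditioning cap, no introgression) are re-run with
    fresh seeds and counted in ``n_failed``.
    """
    N = spec.params.n_diploids
    if spec.scenario == "neutral":
        backs = _collect_background_snapshots(spec, anchor_p1=0, anchor_ref=N)
        profiles, sweep_vals, _ = _aggregate(spec, backs, None)
        return ExperimentResult(
            spec=spec,
            profiles=profiles,
            sweep_site_values=sweep_vals,
            background=None,
            background_clr={},
        )
    snaps, p1_off, p2_off, n_failed, n_restarts = _collect_sweep_snapshots(spec)
    anchor_p1 = int(np.mean(p1_off)) if p1_off else N
    anchor_ref = int(np.mean(p2_off)) if spec.scenario == "introgressed" else anchor_p1
    backs = _collect_background_snapshots(spec, anchor_p1=anchor_p1, anchor_ref=anchor_ref)
    profiles, sweep_vals, bg_clr = _aggregate(spec, snaps, backs)
    bg_profiles, bg_vals, _ = _aggregate(replace(spec, scenario="neutral"), backs, None)
    bg_result = ExperimentResult(
        spec=replace(spec, scenario="neutral"),
        profiles=bg_profiles,
        sweep_site_values=bg_vals,
        background=None,
        background_clr={},
    )
    return ExperimentResult(
        spec=spec,
        profiles=profiles,
        sweep_site_values=sweep_vals,
        background=bg_result,
        background_clr=bg_clr,
        n_failed=n_failed,
        n_restarts_total=n_restarts,
    )


def decay_ratio(result: ExperimentResult, stat: str, tau_a: float, tau_b: float) -> float | None:
    """Ratio of the replicate-mean sweep-site statistic at tau_a to tau_b."""
    num = result.sweep_site_mean(stat, tau_a)
    den = result.sweep_site_mean(stat, tau_b)
    if den == 0:
        return None
    return num / den


def sweep_vs_background_test(result: ExperimentResult, tau: float) -> tuple[float, float, float]:
    """Welch t test of per-replicate sweep-site CLR at ``tau`` against the
    neutral-background CLR distribution at the matching timepoint."""
    a = result.sweep_site_values["clr"][tau]
    if tau in result.background_clr:
        b = result.background_clr[tau]
    else:
        b = np.concatenate(list(result.background_clr.values()))
    return welch_t_test(a, b)


def migration_sensitivity(spec: ExperimentSpec) -> pd.DataFrame:
    """Introgressed-sweep signatures across effective migration rates.

    For each M (at the spec's timepoints): depth of the central π dip and
    the flanking Tajima's D elevation.  The dip is measured against the
    no-migration neutral background (the locus's equilibrium diversity):
    migration itself inflates diversity everywhere in the recipient
    population, so the migration-matched background would hide the softening
    of the sweep.  Flank elevation is measured against the migration-matched
    background (the flank signal is an excess over what migration alone
    produces).  Ordered by M ascending.
    """
    if spec.scenario != "introgressed":
        raise ValueError("migration_sensitivity requires an introgressed spec")
    neutral_spec = replace(
        spec,
        scenario="neutral",
        params=replace(spec.params, mig_rate=0.0),
        n_replicates=spec.n_background or spec.n_replicates,
    )
    neutral = run_experiment(neutral_spec)
    ref_pi = neutral.background_window_mean("pi")
    rows = []
    for M in sorted(spec.migration_values):
        m_rate = M / (2.0 * spec.params.n_diploids)
        sub = replace(spec, params=replace(spec.params, mig_rate=m_rate))
        res = run_experiment(sub)
        for tau in spec.timepoints_scaled:
            prof = res.profiles[tau]
            n_w = prof.window_starts.size
            c_idx = n_w // 2
            flanks = [i for i in (c_idx - 1, c_idx + 1) if 0 <= i < n_w]
            bg_pi = res.background_window_mean("pi", tau)
            bg_tajd = res.background_window_mean("tajd", tau)
            rows.append(
                {
                    "M": M,
                    "tau": tau,
                    "pi_dip_depth": ref_pi - float(prof.stat_means["pi"][c_idx]),
                    "centre_pi": float(prof.stat_means["pi"][c_idx]),
                    "neutral_pi": ref_pi,
                    "background_pi": bg_pi,
                    "flank_tajd_elevation": float(
                        np.nanmean(prof.stat_means["tajd"][flanks]) - bg_tajd
                    ),
                    "background_tajd": bg_tajd,
                    "centre_sd_pi": float(prof.stat_sds["pi"][c_idx]),
                    "n_reps": prof.n_reps,
                }
            )
    return pd.DataFrame(rows).sort_values(["M", "tau"]).reset_index(drop=True)
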