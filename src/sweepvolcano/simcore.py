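"""Forward-in-time two-population Wright-Fisher simulator.

Discrete non-overlapping generations on a single diploid recombining
chromosome of finite length.  Neutral mutations arise at rate ``mu`` per bp
per generation under a quasi-infinite-sites model (uniform positions,
collisions re-drawn); crossovers are Poisson with uniform breakpoints; one
beneficial allele at the chromosome centre can be introduced and conditioned
on fixation.  Two populations, p1 and p2, may exchange migrants symmetrically
(each individual replaced by a migrant from the other population with
per-capita probability ``mig_rate``).

The intended experiment mirrors sweep/introgression studies: a 10N-generation
neutral burn-in, a selective sweep in p1 conditioned on fixation (reset to
the stored post-burn-in state on loss), a 5N migration-free phase, then 10N
generations of migration during which the beneficial allele can introgress
into and sweep through p2.  Time since fixation is reported in scaled units
of 4N generations.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .sumstats import HaplotypeMatrix

__all__ = [
    "SimParams",
    "PopulationState",
    "Trajectory",
    "SampleSnapshot",
    "ConditioningError",
    "run_burn_in",
    "advance_generation",
    "run_conditioned_sweep",
    "run_introgression_phase",
    "sample_at_timepoints",
    "take_sample",
    "scaled_time",
]


class ConditioningError(RuntimeError):
    """Raised when conditioning on fixation exhausts its restart cap."""


@dataclass(frozen=True)
class SimParams:
    """Parameterization of the two-population Wright-Fisher model.

    Defaults are the full-scale study conditions (N=1000 diploids, 750-kb
    chromosome, mu=6e-7 so that 4Nmu=0.0024 per site, r=4e-7 per bp = 40
    cM/Mb, s=0.5, additive dominance, per-capita migration 1e-4 so that the
    population-scaled migration rate M=2Nm=0.2).  ``desk_scale`` builds the
    reduced profile used for fast replicated runs.
    """

    n_diploids: int = 1000
    chrom_len: int = 750_000
    mu: float = 6e-7
    rec: float = 4e-7
    sel_coeff: float = 0.5
    dominance: float = 0.5
    mig_rate: float = 1e-4
    burn_in_gens: int | None = None
    pre_migration_gens: int | None = None
    migration_phase_gens: int | None = None
    sample_every_pre: int = 100
    sample_every_post: int = 50
    seed: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.n_diploids < 2:
            raise ValueError("n_diploids must be >= 2")
        if self.chrom_len < 2:
            raise ValueError("chrom_len must be >= 2")
        if self.mu < 0 or self.rec < 0 or self.sel_coeff < 0:
            raise ValueError("rates and sel_coeff must be non-negative")
        if not 0 <= self.dominance <= 1:
            raise ValueError("dominance must be in [0, 1]")
        if not 0 <= self.mig_rate <= 1:
            raise ValueError("mig_rate must be in [0, 1]")

    # phase lengths default to the 10N / 5N / 10N schedule
    @property
    def burn_in(self) -> int:
        return self.burn_in_gens if self.burn_in_gens is not None else 10 * self.n_diploids

    @property
    def pre_migration(self) -> int:
        return self.pre_migration_gens if self.pre_migration_gens is not None else 5 * self.n_diploids

    @property
    def migration_phase(self) -> int:
        return self.migration_phase_gens if self.migration_phase_gens is not None else 10 * self.n_diploids

    @property
    def theta_per_site(self) -> float:
        return 4.0 * self.n_diploids * self.mu

    @property
    def expected_mutations_per_generation(self) -> float:
        """Expected new mutations per population per generation, 2N·mu·L."""
        return 2.0 * self.n_diploids * self.mu * self.chrom_len

    @property
    def effective_migration_rate(self) -> float:
        """Population-scaled migration rate M = 2Nm."""
        return 2.0 * self.n_diploids * self.mig_rate

    @classmethod
    def desk_scale(
        cls,
        n_diploids: int = 200,
        chrom_len: int = 50_000,
        theta_per_site: float = 0.0024,
        map_length: float = 0.3,
        sel_coeff: float = 0.5,
        effective_migration_rate: float = 0.2,
        seed: int = 0,
        **kwargs,
    ) -> "SimParams":
        """Reduced-scale profile preserving the scaled compound parameters.

        mu is set so 4N·mu equals ``theta_per_site`` and rec so the total
        map length r·L (Morgans) equals ``map_length`` — keeping both the
        per-site diversity and the fraction of the chromosome covered by the
        hitchhiking footprint comparable to the full-scale runs.
        """
        mu = theta_per_site / (4.0 * n_diploids)
        rec = map_length / chrom_len
        mig = effective_migration_rate / (2.0 * n_diploids)
        return cls(
            n_diploids=n_diploids,
            chrom_len=chrom_len,
            mu=mu,
            rec=rec,
            sel_coeff=sel_coeff,
            mig_rate=mig,
            seed=seed,
            **kwargs,
        )


@dataclass
class Trajectory:
    """Per-generation frequency track of the beneficial allele."""

    generations: list[int] = field(default_factory=list)
    freq_p1: list[float] = field(default_factory=list)
    freq_p2: list[float] = field(default_factory=list)
    fixation_gen_p1: int | None = None
    fixation_gen_p2: int | None = None
    n_restarts: int = 0

    def record(self, gen: int, f1: float, f2: float) -> None:
        self.generations.append(gen)
        self.freq_p1.append(f1)
        self.freq_p2.append(f2)


@dataclass
class SampleSnapshot:
    """A sampled haplotype matrix taken at a known (scaled) time."""

    time_gens: int
    time_scaled: float
    population_label: str
    matrix: HaplotypeMatrix


class PopulationState:
    """Evolving haplotype pools of one or two populations.

    Segregating sites are shared columns across populations: ``positions``
    lists every site segregating in the pooled metapopulation, and each
    population holds a (2N x S) binary matrix over those columns.  Sites
    fixed derived in every pooled sequence are compacted into
    ``fixed_positions`` but remain queryable (and re-appear as substitution
    columns in samples).
    """

    def __init__(
        self,
        n_diploids: int,
        chrom_len: int,
        rng: np.random.Generator,
        generation: int = 0,
    ) -> None:
        self.n_diploids = n_diploids
        self.chrom_len = chrom_len
        self.generation = generation
        self.rng = rng
        self.positions = np.empty(0, dtype=np.int64)
        self.genos: dict[str, np.ndarray] = {
            "p1": np.zeros((2 * n_diploids, 0), dtype=np.uint8)
        }
        self.fixed_positions = np.empty(0, dtype=np.int64)
        self.beneficial_pos: int | None = None
        self.beneficial_fixed_pooled = False

    # -- bookkeeping -------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return list(self.genos)

    @property
    def n_segregating(self) -> int:
        return int(self.positions.size)

    def copy(self) -> "PopulationState":
        new = PopulationState.__new__(PopulationState)
        new.n_diploids = self.n_diploids
        new.chrom_len = self.chrom_len
        new.generation = self.generation
        new.rng = _copy.deepcopy(self.rng)
        new.positions = self.positions.copy()
        new.genos = {k: v.copy() for k, v in self.genos.items()}
        new.fixed_positions = self.fixed_positions.copy()
        new.beneficial_pos = self.beneficial_pos
        new.beneficial_fixed_pooled = self.beneficial_fixed_pooled
        return new

    def add_population_copy(self, label: str = "p2", source: str = "p1") -> None:
        """Instantiate a second population as an exact copy of ``source``."""
        if label in self.genos:
            raise ValueError(f"population {label!r} already exists")
        self.genos[label] = self.genos[source].copy()

    def _beneficial_index(self) -> int | None:
        if self.beneficial_pos is None:
            return None
        i = np.searchsorted(self.positions, self.beneficial_pos)
        if i < self.positions.size and self.positions[i] == self.beneficial_pos:
            return int(i)
        return None

    def beneficial_freq(self, label: str) -> float:
        if self.beneficial_pos is None:
            return 0.0
        idx = self._beneficial_index()
        if idx is not None:
            return float(self.genos[label][:, idx].mean())
        return 1.0 if self.beneficial_fixed_pooled else 0.0

    def introduce_beneficial(self, label: str = "p1") -> None:
        """Add a single copy of the beneficial allele at the chromosome centre.

        If the centre coordinate is occupied by a segregating or fixed neutral
        site the nearest free position is used.
        """
        pos = self.chrom_len // 2
        occupied = set(self.positions.tolist()) | set(self.fixed_positions.tolist())
        while pos in occupied:
            pos += 1
            if pos >= self.chrom_len:
                raise RuntimeError("no free position for the beneficial allele")
        self.beneficial_pos = int(pos)
        self.beneficial_fixed_pooled = False
        insert_at = int(np.searchsorted(self.positions, pos))
        self.positions = np.insert(self.positions, insert_at, pos)
        for lab in self.genos:
            col = np.zeros((self.genos[lab].shape[0], 1), dtype=np.uint8)
            self.genos[lab] = np.concatenate(
                [self.genos[lab][:, :insert_at], col, self.genos[lab][:, insert_at:]], axis=1
            )
        carrier = int(self.rng.integers(0, self.genos[label].shape[0]))
        self.genos[label][carrier, insert_at] = 1


def _make_rng(seed_parts: Sequence[int]) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(list(seed_parts))))


def _recombine_rows(
    G: np.ndarray,
    parent: np.ndarray,
    start: np.ndarray,
    ncross: np.ndarray,
    positions: np.ndarray,
    chrom_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form gametes: row i comes from diploid parent[i], strand start[i],
    with ncross[i] crossovers at uniform breakpoints."""
    child = G[2 * parent + start].copy()
    one = np.flatnonzero(ncross == 1)
    if one.size:
        # single crossover: switch strands at one uniform breakpoint
        bps = rng.integers(1, chrom_len, size=one.size)
        other = G[2 * parent[one] + 1 - start[one]]
        mask = positions[None, :] >= bps[:, None]
        child[one] = np.where(mask, other, child[one])
    for i in np.flatnonzero(ncross >= 2):
        bps = np.sort(rng.integers(1, chrom_len, size=int(ncross[i])))
        parity = np.searchsorted(bps, positions, side="right") % 2
        h0 = G[2 * parent[i] + start[i]]
        h1 = G[2 * parent[i] + 1 - start[i]]
        child[i] = np.where(parity == 0, h0, h1)
    return child


def _step_inplace(
    state: PopulationState,
    params: SimParams,
    selection_on: bool,
    migration_on: bool,
) -> None:
    rng = state.rng
    L = state.chrom_len
    labels = state.labels
    cur = dict(state.genos)

    # 1. migration: symmetric, based on the pre-step pools
    if migration_on and len(labels) == 2 and params.mig_rate > 0:
        pre = {lab: cur[lab] for lab in labels}
        for src in labels:
            other = labels[0] if src == labels[1] else labels[1]
            G = pre[src]
            H = pre[other]
            N = G.shape[0] // 2
            mig = rng.random(N) < params.mig_rate
            if np.any(mig):
                G = G.copy()
                donors = rng.integers(0, H.shape[0] // 2, size=int(mig.sum()))
                idx = np.flatnonzero(mig)
                G[2 * idx] = H[2 * donors]
                G[2 * idx + 1] = H[2 * donors + 1]
            cur[src] = G

    b_idx = state._beneficial_index()
    lam_rec = params.rec * (L - 1)

    children: dict[str, np.ndarray] = {}
    for lab in labels:
        G = cur[lab]
        n_seq = G.shape[0]
        N = n_seq // 2
        if selection_on and b_idx is not None and params.sel_coeff > 0:
            b = G[:, b_idx].astype(np.int64)
            g = b[0::2] + b[1::2]
            w = np.ones(N)
            w[g == 1] += params.dominance * params.sel_coeff
            w[g == 2] += params.sel_coeff
            if np.all(w == w[0]):
                parents = rng.integers(0, N, size=2 * N)
            else:
                parents = rng.choice(N, size=2 * N, p=w / w.sum())
        else:
            parents = rng.integers(0, N, size=2 * N)
        start = rng.integers(0, 2, size=n_seq).astype(np.int64)
        ncross = rng.poisson(lam_rec, size=n_seq) if lam_rec > 0 else np.zeros(n_seq, dtype=np.int64)
        children[lab] = _recombine_rows(G, parents, start, ncross, state.positions, L, rng)

    # 2. new mutations (quasi-infinite sites: collisions re-drawn)
    occupied = set(state.positions.tolist())
    occupied.update(state.fixed_positions.tolist())
    new_pos: list[int] = []
    new_by_pop: dict[str, list[tuple[int, int]]] = {lab: [] for lab in labels}
    for lab in labels:
        n_seq = children[lab].shape[0]
        n_mut = int(rng.poisson(params.mu * L * n_seq))
        accepted: list[int] = []
        need = n_mut
        while need > 0:
            for p in rng.integers(0, L, size=need).tolist():
                if p not in occupied:
                    occupied.add(p)
                    accepted.append(p)
            need = n_mut - len(accepted)
        carriers = rng.integers(0, n_seq, size=n_mut)
        new_pos.extend(accepted)
        new_by_pop[lab] = list(zip(accepted, carriers.tolist()))

    if new_pos:
        all_pos = np.concatenate([state.positions, np.array(new_pos, dtype=np.int64)])
        order = np.argsort(all_pos, kind="stable")
        pos_sorted = all_pos[order]
        col_of = {int(p): i for i, p in enumerate(pos_sorted)}
        for lab in labels:
            n_seq = children[lab].shape[0]
            ext = np.zeros((n_seq, len(new_pos)), dtype=np.uint8)
            M = np.concatenate([children[lab], ext], axis=1)[:, order]
            for p, carrier in new_by_pop[lab]:
                M[carrier, col_of[p]] = 1
            children[lab] = M
        state.positions = pos_sorted
    # 3. compaction across the pooled metapopulation
    if state.positions.size:
        counts = {lab: children[lab].sum(axis=0) for lab in labels}
        lost = np.ones(state.positions.size, dtype=bool)
        fixed = np.ones(state.positions.size, dtype=bool)
        for lab in labels:
            lost &= counts[lab] == 0
            fixed &= counts[lab] == children[lab].shape[0]
        if np.any(fixed):
            newly_fixed = state.positions[fixed]
            state.fixed_positions = np.sort(
                np.concatenate([state.fixed_positions, newly_fixed])
            )
            if state.beneficial_pos is not None and state.beneficial_pos in set(
                newly_fixed.tolist()
            ):
                state.beneficial_fixed_pooled = True
        keep = ~(lost | fixed)
        if not np.all(keep):
            state.positions = state.positions[keep]
            for lab in labels:
                children[lab] = np.ascontiguousarray(children[lab][:, keep])
    state.genos = children
    state.generation += 1


def advance_generation(
    state: PopulationState,
    params: SimParams,
    selection_on: bool = False,
    migration_on: bool = False,
) -> PopulationState:
    """One Wright-Fisher generation (migration, selection, recombination,
    mutation, drift); returns a new state, leaving the input untouched."""
    new = state.copy()
    _step_inplace(new, params, selection_on, migration_on)
    return new


def run_burn_in(params: SimParams, progress: bool = False) -> PopulationState:
    """Neutral-only equilibration for ``burn_in_gens`` (default 10N)."""
    if params.burn_in <= 0:
        raise ValueError("burn_in_gens must be positive")
    rng = _make_rng([params.seed, params.replicate_id, 0])
    state = PopulationState(params.n_diploids, params.chrom_len, rng)
    for _ in range(params.burn_in):
        _step_inplace(state, params, selection_on=False, migration_on=False)
    return state


def run_conditioned_sweep(
    state_post_burnin: PopulationState,
    params: SimParams,
    max_restarts: int = 10_000,
    max_gens: int | None = None,
) -> tuple[PopulationState, Trajectory]:
    """Introduce the beneficial allele in p1 and condition on its fixation.

    On loss the stored post-burn-in state is restored and the allele
    reintroduced with a per-attempt reseeded RNG; the first realization whose
    p1 frequency reaches 1 is returned, together with the per-generation
    frequency trajectory and the restart count.
    """
    if max_gens is None:
        max_gens = 100 * params.n_diploids
    saved = state_post_burnin
    for attempt in range(max_restarts + 1):
        work = saved.copy()
        work.rng = _make_rng([params.seed, params.replicate_id, 1, attempt])
        work.introduce_beneficial("p1")
        traj = Trajectory(n_restarts=attempt)
        has_p2 = "p2" in work.genos
        f1 = work.beneficial_freq("p1")
        traj.record(work.generation, f1, work.beneficial_freq("p2") if has_p2 else 0.0)
        lost = False
        for _ in range(max_gens):
            _step_inplace(work, params, selection_on=True, migration_on=False)
            f1 = work.beneficial_freq("p1")
            traj.record(work.generation, f1, work.beneficial_freq("p2") if has_p2 else 0.0)
            if f1 == 0.0:
                lost = True
                break
            if f1 >= 1.0:
                traj.fixation_gen_p1 = work.generation
                return work, traj
        if not lost:
            raise ConditioningError("beneficial allele neither fixed nor lost within max_gens")
    raise ConditioningError(f"conditioning failed after {max_restarts} restarts")


def sample_at_timepoints(
    state: PopulationState,
    params: SimParams,
    timepoints_scaled: Iterable[float],
    reference_gen: int,
    population_label: str,
    n_sequences: int | None = None,
    selection_on: bool = True,
    migration_on: bool = False,
) -> list[SampleSnapshot]:
    """Advance the state and sample ``population_label`` at scaled times
    measured from ``reference_gen`` (in units of 4N generations).

    Mutates ``state`` in place; snapshots fall at the nearest whole
    generation at or after each requested scaled time.
    """
    N = state.n_diploids
    if n_sequences is None:
        n_sequences = min(500, 2 * N)
    targets = sorted(int(math.ceil(t * 4 * N)) + reference_gen for t in timepoints_scaled)
    snaps: list[SampleSnapshot] = []
    for target in targets:
        while state.generation < target:
            _step_inplace(state, params, selection_on=selection_on, migration_on=migration_on)
        seed = int(state.rng.integers(0, 2**31 - 1))
        matrix = take_sample(state, population_label, n_sequences, seed)
        snaps.append(
            SampleSnapshot(
                time_gens=state.generation,
                time_scaled=scaled_time(state.generation, N, reference_gen),
                population_label=population_label,
                matrix=matrix,
            )
        )
    return snaps


def run_introgression_phase(
    state_fixed_p1: PopulationState,
    params: SimParams,
    timepoints_scaled: Sequence[float],
    n_sequences: int | None = None,
    max_extra_gens: int | None = None,
) -> tuple[list[SampleSnapshot], Trajectory]:
    """Migration-free 5N phase, then migration at ``mig_rate`` while the
    beneficial allele (still under selection) introgresses into p2.

    Snapshots of p2 are taken at the requested scaled timepoints measured
    from the allele's fixation generation in p2.  If the allele never fixes
    in p2 within the migration phase (plus the post-fixation sampling
    overhang), the trajectory is returned with ``fixation_gen_p2`` unset and
    no snapshots; the caller decides whether to re-run.
    """
    state = state_fixed_p1
    if "p2" not in state.genos:
        raise ValueError("p2 must exist before the introgression phase")
    if state.beneficial_freq("p1") < 1.0:
        raise ValueError("p1 must carry the beneficial allele at frequency 1")
    N = state.n_diploids
    traj = Trajectory()
    for _ in range(params.pre_migration):
        _step_inplace(state, params, selection_on=True, migration_on=False)
        traj.record(state.generation, state.beneficial_freq("p1"), state.beneficial_freq("p2"))
    overhang = int(math.ceil(max(timepoints_scaled) * 4 * N)) if len(list(timepoints_scaled)) else 0
    if max_extra_gens is None:
        max_extra_gens = overhang + 5 * N
    limit = state.generation + params.migration_phase + max_extra_gens
    fixation: int | None = None
    migration_end = state.generation + params.migration_phase
    while state.generation < limit:
        _step_inplace(state, params, selection_on=True, migration_on=True)
        f2 = state.beneficial_freq("p2")
        traj.record(state.generation, state.beneficial_freq("p1"), f2)
        if f2 >= 1.0:
            fixation = state.generation
            break
        if fixation is None and state.generation >= migration_end + max_extra_gens:
            break
    if fixation is None:
        return [], traj
    traj.fixation_gen_p2 = fixation
    snaps = sample_at_timepoints(
        state,
        params,
        timepoints_scaled,
        reference_gen=fixation,
        population_label="p2",
        n_sequences=n_sequences,
        selection_on=True,
        migration_on=True,
    )
    return snaps, traj


def take_sample(
    state: PopulationState,
    population_label: str,
    n_sequences: int,
    seed: int | None = None,
) -> HaplotypeMatrix:
    """Uniform subsample without replacement of one population's sequences.

    Sites monomorphic ancestral within the sample are dropped; sites fixed
    derived within the sample — including pooled-fixed sites — are retained
    and flagged as substitutions.
    """
    G = state.genos[population_label]
    if n_sequences > G.shape[0]:
        raise ValueError("cannot sample more sequences than the population holds")
    rng = _make_rng([0 if seed is None else seed, 17]) if seed is not None else state.rng
    rows = rng.choice(G.shape[0], size=n_sequences, replace=False)
    sub = G[np.sort(rows)]
    counts = sub.sum(axis=0)
    keep = counts > 0
    positions = state.positions[keep]
    states = sub[:, keep]
    # pooled-fixed sites re-enter as all-derived substitution columns
    if state.fixed_positions.size:
        fixed_cols = np.ones((n_sequences, state.fixed_positions.size), dtype=np.uint8)
        all_pos = np.concatenate([positions, state.fixed_positions])
        order = np.argsort(all_pos, kind="stable")
        positions = all_pos[order]
        states = np.concatenate([states, fixed_cols], axis=1)[:, order]
    return HaplotypeMatrix(
        positions=positions,
        states=states,
        chrom_len=state.chrom_len,
        metadata={
            "population": population_label,
            "generation": state.generation,
            "n_diploids": state.n_diploids,
        },
    )


def scaled_time(gens: int, n_diploids: int, reference_gen: int = 0) -> float:
    """Time in units of 4N generations: (gens - reference_gen) / (4N)."""
    if n_diploids <= 0:
        raise ValueError("n_diploids must be positive")
    return (gens - reference_gen) / (4.0 * n_diploids)
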