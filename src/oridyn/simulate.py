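"""Fixed-time-step stochastic simulation of S-phase replication kinetics.

One simulated S-phase follows a well-mixed bimolecular scheme.  A pool of
``NDT`` firing factors is loaded with exponentially relaxed timing
(characteristic time ``tau_load``).  At every step of length ``dt``:

1. newly arrived factors join the free pool ``NFD(t)``;
2. each free factor, independently, fires with probability
   ``1 - (1 - kon*dt)**Np_ori(t)``; a successful factor activates a
   uniformly random unreplicated potential origin, creating two divergent
   forks that each carry one half of the factor;
3. every fork advances by ``v*dt``; DNA it sweeps becomes replicated and
   potential origins inside it are passivated; converging forks that meet
   annihilate and release one reassembled factor back to the free pool;
   forks reaching a chromosome end are discarded (their half factor is
   lost by default, or recycled in pairs with ``recycle_at_ends``).

The S-phase ends when no unreplicated DNA remains; that time is the
replication time of the run.

Internally all chromosomes are laid end-to-end on one global axis,
separated by 1-kb walls that forks cannot cross, so the whole genome is
advanced with a handful of vectorized array operations per step.
Replicated DNA is held as disjoint "bubbles" ``[left, right]`` whose
active edges are the forks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .genome import GenomeSpec

if TYPE_CHECKING:  # pragma: no cover
    from .observables import EnsembleKinetics

__all__ = [
    "SimParams",
    "FactorPool",
    "KineticsRecord",
    "SimState",
    "SimulationStalledError",
    "sample_factor_arrivals",
    "firing_probability",
    "attempt_firings",
    "advance_forks",
    "step",
    "run_simulation",
    "run_ensemble",
]

_CHROM_GAP_KB = 1.0  # inert spacer between chromosomes on the global axis


class SimulationStalledError(RuntimeError):
    """Raised when unreplicated DNA remains but no event can ever occur."""


@dataclass(frozen=True)
class SimParams:
    """Full parameter set of one simulation series.

    Parameters
    ----------
    genome : GenomeSpec
        Chromosomes and potential-origin map.
    v : float
        Replication fork speed, kb/min.
    kon : float
        Productive-interaction rate of a free factor with one p-ori, 1/min.
    ndt : int
        Total number of firing factors NDT (the Poisson mean when
        ``ndt_mode="poisson"``).
    tau_load : float
        Characteristic time of the exponentially relaxed factor loading,
        min; 0 loads every factor at t=0.
    dt : float
        Time step, min.  ``kon*dt`` must not exceed 1.
    ndt_mode : {"constant", "poisson"}
        Whether ensembles use a fixed NDT or draw it per cell from a
        Poisson distribution of mean ``ndt``.
    recycle_at_ends : bool
        If True, half factors from forks discarded at chromosome ends are
        re-paired into free factors; by default they are lost.
    loading_mode : {"stochastic", "deterministic"}
        Per-factor i.i.d. exponential arrival times (default), or the
        deterministic count ``round(NDT*(1-exp(-t/tau)))`` for
        variance-reduction checks.
    max_time : float
        Guard against non-terminating runs (e.g. NDT=0): the run raises
        `SimulationStalledError` past this time, min.
    """

    genome: GenomeSpec
    v: float
    kon: float
    ndt: int
    tau_load: float = 0.0
    dt: float = 0.01
    ndt_mode: str = "constant"
    recycle_at_ends: bool = False
    loading_mode: str = "stochastic"
    max_time: float = 1.0e4

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError(f"fork speed v must be > 0, got {self.v}")
        if self.kon < 0:
            raise ValueError(f"kon must be >= 0, got {self.kon}")
        if self.ndt < 0:
            raise ValueError(f"NDT must be >= 0, got {self.ndt}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.tau_load < 0:
            raise ValueError(f"tau_load must be >= 0, got {self.tau_load}")
        if self.kon * self.dt > 1:
            raise ValueError(
                f"kon*dt = {self.kon * self.dt} > 1: time step too coarse"
            )
        if self.ndt_mode not in ("constant", "poisson"):
            raise ValueError(f"unknown ndt_mode {self.ndt_mode!r}")
        if self.loading_mode not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown loading_mode {self.loading_mode!r}")
        pos = self.genome.positions_by_chromosome()
        gaps = [np.diff(p) for p in pos.values() if len(p) >= 2]
        if gaps:
            min_gap = min(float(g.min()) for g in gaps)
            if self.v * self.dt > 0.5 * min_gap:
                warnings.warn(
                    f"v*dt = {self.v * self.dt:.4g} kb exceeds half the minimum "
                    f"inter-origin spacing ({min_gap:.4g} kb); consider a smaller dt",
                    stacklevel=2,
                )


@dataclass
class FactorPool:
    """Bookkeeping of the limiting firing factors.

    One factor splits into two halves on firing (one per fork) and
    reforms when two forks merge.  The conservation law

        n_free + (n_bound_halves + n_lost_halves + n_recycle_halves) / 2
            == n_loaded

    holds after every step; ``n_recycle_halves`` is the odd half waiting
    for a partner when ``recycle_at_ends`` is on.
    """

    n_loaded: int = 0
    n_free: int = 0
    n_bound_halves: int = 0
    n_lost_halves: int = 0
    n_recycle_halves: int = 0

    def check(self) -> None:
        lhs = 2 * self.n_free + self.n_bound_halves + self.n_lost_halves \
            + self.n_recycle_halves
        if lhs != 2 * self.n_loaded or self.n_free < 0:
            raise AssertionError(f"factor pool inconsistent: {self}")


def sample_factor_arrivals(ndt: int, tau_load: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Sorted i.i.d. exponential arrival times (min) for ``ndt`` factors.

    ``tau_load = 0`` loads everything at t=0.  The expected loaded count
    at time t is ``ndt * (1 - exp(-t/tau_load))``.
    """
    if ndt < 0:
        raise ValueError(f"ndt must be >= 0, got {ndt}")
    if tau_load < 0:
        raise ValueError(f"tau_load must be >= 0, got {tau_load}")
    if tau_load == 0:
        return np.zeros(ndt)
    return np.sort(rng.exponential(tau_load, size=ndt))


def firing_probability(kon: float, dt: float, n_pori: int) -> float:
    """Per-step firing probability of one free factor among n_pori origins.

    ``p = 1 - (1 - kon*dt)**n_pori``; the complement is computed with
    ``expm1`` for accuracy at small ``kon*dt``.
    """
    if kon < 0 or dt < 0:
        raise ValueError("kon and dt must be >= 0")
    if kon * dt > 1:
        raise ValueError(f"kon*dt = {kon * dt} > 1: time step too coarse")
    if n_pori < 0:
        raise ValueError(f"n_pori must be >= 0, got {n_pori}")
    if n_pori == 0 or kon * dt == 0:
        return 0.0
    return float(-np.expm1(n_pori * np.log1p(-kon * dt)))


class SimState:
    """Mutable replication state of one S-phase at a given time.

    Holds the global bubble arrays (replicated intervals with fork
    activity flags on their edges), the potential-origin arrays, the
    factor pool and the cumulative event counters.  Constructed by
    `run_simulation` / `new_state`; advanced in place by `step`.
    """

    def __init__(self, params: SimParams, ndt: int | None = None):
        g = params.genome
        self.params = params
        self.ndt = params.ndt if ndt is None else int(ndt)
        self.time = 0.0
        # global axis: chromosomes end-to-end with inert gaps
        lengths = np.array([c.length for c in g.chromosomes])
        self.offsets = np.concatenate([[0.0], np.cumsum(lengths + _CHROM_GAP_KB)[:-1]])
        self.chrom_lo = self.offsets
        self.chrom_hi = self.offsets + lengths
        self.chrom_ids = [c.id for c in g.chromosomes]
        self.total_length = float(lengths.sum())

        by_chrom = g.positions_by_chromosome()
        pos_parts, gid_chrom = [], []
        for ci, cid in enumerate(self.chrom_ids):
            p = by_chrom[cid]
            pos_parts.append(p + self.offsets[ci])
            gid_chrom.extend([ci] * len(p))
        self.ori_pos = np.concatenate(pos_parts) if pos_parts else np.empty(0)
        self.ori_chrom = np.asarray(gid_chrom, dtype=np.int32)
        order = np.argsort(self.ori_pos, kind="stable")
        self.ori_pos = self.ori_pos[order]
        self.ori_chrom = self.ori_chrom[order]
        self.ori_status = np.zeros(len(self.ori_pos), dtype=np.int8)  # 0/1/2

        # compact potential-origin view (global positions + index into ori_*)
        self.pot_pos = self.ori_pos.copy()
        self.pot_idx = np.arange(len(self.ori_pos))

        # bubbles: replicated [left, right] with fork-activity flags and
        # the chromosome walls that bound them
        z = np.empty(0)
        self.bb_left, self.bb_right = z.copy(), z.copy()
        self.bb_lact = np.empty(0, dtype=bool)
        self.bb_ract = np.empty(0, dtype=bool)
        self.bb_lo, self.bb_hi = z.copy(), z.copy()

        self.pool = FactorPool()
        self.n_fired = 0
        self.n_passivated = 0
        self.n_merges = 0
        self.events: list[tuple[int, str, float]] = []  # (origin idx, event, time)

    # -- derived views ------------------------------------------------------
    @property
    def n_pori(self) -> int:
        """Unreplicated potential origins Np-ori(t)."""
        return len(self.pot_pos)

    @property
    def n_forks(self) -> int:
        return int(self.bb_lact.sum() + self.bb_ract.sum())

    @property
    def l_replicated(self) -> float:
        return float(np.sum(self.bb_right - self.bb_left))

    @property
    def l_unreplicated(self) -> float:
        """Length of unreplicated DNA, kb."""
        return max(self.total_length - self.l_replicated, 0.0)

    @property
    def done(self) -> bool:
        return self.l_unreplicated <= 1e-9

    def replicated_intervals(self) -> dict[str, list[tuple[float, float]]]:
        """Per-chromosome disjoint replicated intervals in local kb."""
        out: dict[str, list[tuple[float, float]]] = {c: [] for c in self.chrom_ids}
        ci = np.searchsorted(self.chrom_lo, self.bb_left, side="right") - 1
        for i in range(len(self.bb_left)):
            off = self.offsets[ci[i]]
            out[self.chrom_ids[ci[i]]].append(
                (self.bb_left[i] - off, self.bb_right[i] - off)
            )
        return out

    def forks(self) -> pd.DataFrame:
        """Active forks as (chrom, position kb, direction) rows."""
        rows = []
        ci = np.searchsorted(self.chrom_lo, self.bb_left, side="right") - 1
        for i in range(len(self.bb_left)):
            off = self.offsets[ci[i]]
            cid = self.chrom_ids[ci[i]]
            if self.bb_lact[i]:
                rows.append((cid, self.bb_left[i] - off, "left"))
            if self.bb_ract[i]:
                rows.append((cid, self.bb_right[i] - off, "right"))
        return pd.DataFrame(rows, columns=["chrom", "position", "direction"])

    def event_log(self) -> pd.DataFrame:
        """Per-origin event log: chrom, position (kb), event, time (min)."""
        rows = [
            (self.chrom_ids[self.ori_chrom[i]],
             self.ori_pos[i] - self.offsets[self.ori_chrom[i]], ev, t)
            for i, ev, t in self.events
        ]
        return pd.DataFrame(rows, columns=["chrom", "position", "event", "time"])


def new_state(params: SimParams, ndt: int | None = None) -> SimState:
    """Fresh pre-S-phase state (no factor loaded, nothing replicated)."""
    return SimState(params, ndt=ndt)


def attempt_firings(state: SimState, params: SimParams,
                    rng: np.random.Generator) -> SimState:
    """Fire origins for the current step (phase 2 of the loop).

    Each free factor succeeds independently with the per-step probability
    from `firing_probability` evaluated at the step-start ``Np_ori``;
    successful factors pick distinct uniformly random potential origins
    (surplus successes beyond the available origins are no-ops).
    Mutates and returns ``state``.
    """
    n_pot = state.n_pori
    if state.pool.n_free == 0 or n_pot == 0:
        return state
    p = firing_probability(params.kon, params.dt, n_pot)
    k = int(rng.binomial(state.pool.n_free, p))
    k = min(k, n_pot)
    if k == 0:
        return state
    chosen = np.sort(rng.choice(n_pot, size=k, replace=False))
    xs = state.pot_pos[chosen]
    gidx = state.pot_idx[chosen]
    state.ori_status[gidx] = 1
    t_fire = state.time + params.dt
    state.events.extend((int(i), "fired", t_fire) for i in gidx)
    state.pot_pos = np.delete(state.pot_pos, chosen)
    state.pot_idx = np.delete(state.pot_idx, chosen)

    ci = np.searchsorted(state.chrom_lo, xs, side="right") - 1
    ins = np.searchsorted(state.bb_left, xs)
    state.bb_left = np.insert(state.bb_left, ins, xs)
    state.bb_right = np.insert(state.bb_right, ins, xs)
    state.bb_lact = np.insert(state.bb_lact, ins, True)
    state.bb_ract = np.insert(state.bb_ract, ins, True)
    state.bb_lo = np.insert(state.bb_lo, ins, state.chrom_lo[ci])
    state.bb_hi = np.insert(state.bb_hi, ins, state.chrom_hi[ci])

    state.pool.n_free -= k
    state.pool.n_bound_halves += 2 * k
    state.n_fired += k
    return state


def advance_forks(state: SimState, params: SimParams) -> SimState:
    """Propagate every fork by v*dt (phase 3 of the loop).

    Newly covered DNA becomes replicated; potential origins inside it are
    passivated; converging forks whose swept segments touch or overlap
    merge (both removed, one factor released); forks hitting a chromosome
    end are discarded.  Mutates and returns ``state``.
    """
    nb = len(state.bb_left)
    if nb == 0:
        return state
    vdt = params.v * params.dt
    left, right = state.bb_left, state.bb_right
    lact, ract = state.bb_lact, state.bb_ract

    left = np.where(lact, left - vdt, left)
    right = np.where(ract, right + vdt, right)
    # chromosome-end discards
    hit_lo = lact & (left <= state.bb_lo)
    hit_hi = ract & (right >= state.bb_hi)
    left = np.where(hit_lo, state.bb_lo, left)
    right = np.where(hit_hi, state.bb_hi, right)
    lact = lact & ~hit_lo
    ract = ract & ~hit_hi
    n_disc = int(hit_lo.sum() + hit_hi.sum())
    if n_disc:
        state.pool.n_bound_halves -= n_disc
        if params.recycle_at_ends:
            state.pool.n_recycle_halves += n_disc
            pairs = state.pool.n_recycle_halves // 2
            state.pool.n_recycle_halves -= 2 * pairs
            state.pool.n_free += pairs
        else:
            state.pool.n_lost_halves += n_disc

    # merge converging forks: chain bubbles whose intervals touch/overlap
    if nb > 1:
        cm = np.maximum.accumulate(right)
        starts = np.empty(nb, dtype=bool)
        starts[0] = True
        starts[1:] = left[1:] > cm[:-1]
        if not starts.all():
            gidx = np.flatnonzero(starts)
            last = np.append(gidx[1:], nb) - 1
            n_merges = nb - len(gidx)
            left = left[gidx]
            right = right[last]  # rights are non-decreasing within a step
            lact = lact[gidx]
            ract = ract[last]
            state.bb_lo = state.bb_lo[gidx]
            state.bb_hi = state.bb_hi[last]
            state.pool.n_free += n_merges
            state.pool.n_bound_halves -= 2 * n_merges
            state.n_merges += n_merges

    state.bb_left, state.bb_right = left, right
    state.bb_lact, state.bb_ract = lact, ract

    # passivate potential origins now inside replicated DNA
    if len(state.pot_pos):
        j = np.searchsorted(state.bb_left, state.pot_pos, side="right")
        covered = (j > 0) & (state.pot_pos <= state.bb_right[np.maximum(j - 1, 0)])
        if covered.any():
            gidx = state.pot_idx[covered]
            state.ori_status[gidx] = 2
            t_pass = state.time + params.dt
            state.events.extend((int(i), "passivated", t_pass) for i in gidx)
            state.n_passivated += len(gidx)
            state.pot_pos = state.pot_pos[~covered]
            state.pot_idx = state.pot_idx[~covered]
    return state


def step(state: SimState, params: SimParams, rng: np.random.Generator,
         n_arrivals: int = 0) -> SimState:
    """One time step: load arrivals, attempt firings, advance forks.

    ``n_arrivals`` is the number of factors whose loading time falls in
    this step.  Time advances by ``dt``.  Mutates and returns ``state``.
    """
    if n_arrivals:
        state.pool.n_loaded += n_arrivals
        state.pool.n_free += n_arrivals
    attempt_firings(state, params, rng)
    advance_forks(state, params)
    state.time += params.dt
    return state


@dataclass
class KineticsRecord:
    """Per-step time series of one simulated S-phase.

    All series share the grid ``times`` (step-start times plus one
    terminal point).  ``n_fired`` / ``n_passivated`` count events during
    the step starting at each grid point (0 on the terminal point);
    ``nfd``, ``np_ori`` and ``l_unrep`` are sampled at the grid point
    itself (``nfd`` after that step's factor arrivals, so it is the free
    pool the firing phase sees).
    """

    times: np.ndarray
    n_fired: np.ndarray
    n_passivated: np.ndarray
    nfd: np.ndarray
    np_ori: np.ndarray
    l_unrep: np.ndarray
    dt: float
    replication_time: float
    total_length: float
    n_origins_initial: int
    ndt_used: int
    events: pd.DataFrame = field(repr=False)

    @property
    def total_fired(self) -> int:
        return int(self.n_fired.sum())

    @property
    def total_passivated(self) -> int:
        return int(self.n_passivated.sum())


def run_simulation(params: SimParams, rng: np.random.Generator,
                   ndt: int | None = None,
                   check_invariants: bool = False) -> KineticsRecord:
    """Simulate one complete S-phase and record its kinetics.

    Iterates `step` until no unreplicated DNA remains.  ``ndt`` overrides
    ``params.ndt`` for this run (used by Poisson-NDT ensembles).  With
    ``check_invariants`` the factor-conservation identity is asserted
    after every step (slow; for tests).

    Raises
    ------
    SimulationStalledError
        If replication can never complete (no forks, no free or pending
        factors, or no origins on an unreplicated chromosome), or past
        ``params.max_time``.
    """
    state = new_state(params, ndt=ndt)
    ndt_run = state.ndt
    if params.loading_mode == "stochastic":
        arrivals = sample_factor_arrivals(ndt_run, params.tau_load, rng)
    else:
        arrivals = None

    times, fired_s, pass_s, nfd_s, npori_s, lunrep_s = [], [], [], [], [], []
    ai = 0  # arrival pointer
    n_steps_max = int(np.ceil(params.max_time / params.dt))
    for _ in range(n_steps_max):
        t = state.time
        if arrivals is not None:
            n_new = int(np.searchsorted(arrivals, t, side="right")) - ai
        else:
            if params.tau_load > 0:
                target = int(round(ndt_run * -np.expm1(-t / params.tau_load)))
            else:
                target = ndt_run
            n_new = target - state.pool.n_loaded
        if n_new:
            state.pool.n_loaded += n_new
            state.pool.n_free += n_new
            ai += n_new

        times.append(t)
        nfd_s.append(state.pool.n_free)
        npori_s.append(state.n_pori)
        lunrep_s.append(state.l_unreplicated)

        f0, p0 = state.n_fired, state.n_passivated
        attempt_firings(state, params, rng)
        advance_forks(state, params)
        state.time = t + params.dt
        fired_s.append(state.n_fired - f0)
        pass_s.append(state.n_passivated - p0)

        if check_invariants:
            state.pool.check()
        if state.done:
            break
        pending = ndt_run - state.pool.n_loaded
        if state.n_forks == 0 and pending == 0 and (
            state.pool.n_free == 0 or state.n_pori == 0
        ):
            raise SimulationStalledError(
                f"no possible event at t={state.time:.2f} min with "
                f"{state.l_unreplicated:.3f} kb unreplicated"
            )
    else:
        raise SimulationStalledError(
            f"replication incomplete at max_time={params.max_time} min"
        )

    # terminal grid point
    times.append(state.time)
    fired_s.append(0)
    pass_s.append(0)
    nfd_s.append(state.pool.n_free)
    npori_s.append(state.n_pori)
    lunrep_s.append(0.0)

    return KineticsRecord(
        times=np.asarray(times),
        n_fired=np.asarray(fired_s),
        n_passivated=np.asarray(pass_s),
        nfd=np.asarray(nfd_s),
        np_ori=np.asarray(npori_s),
        l_unrep=np.asarray(lunrep_s),
        dt=params.dt,
        replication_time=state.time,
        total_length=state.total_length,
        n_origins_initial=len(state.ori_pos),
        ndt_used=ndt_run,
        events=state.event_log(),
    )


def run_ensemble(params: SimParams, n_runs: int, master_seed: int,
                 bin_width: float = 0.5,
                 keep_events: bool = False) -> "EnsembleKinetics":
    """Run ``n_runs`` independent S-phases and pool their kinetics.

    Per-run random streams are spawned deterministically from
    ``master_seed`` (`numpy.random.SeedSequence`), so the same seed gives
    bit-identical ensembles on any machine.  In ``ndt_mode="poisson"``
    each run draws its factor count from Poisson(``params.ndt``); genomes
    with resampled placement (uniform/periodic) get fresh origin
    positions every run, file-based maps stay fixed.

    Returns an `observables.EnsembleKinetics` binned at ``bin_width``.
    """
    from .observables import pool_ensemble

    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    streams = np.random.SeedSequence(master_seed).spawn(n_runs)
    records = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        ndt_run = int(rng.poisson(params.ndt)) if params.ndt_mode == "poisson" else None
        genome_run = params.genome.resample(rng)
        p_run = replace(params, genome=genome_run) if genome_run is not params.genome \
            else params
        rec = run_simulation(p_run, rng, ndt=ndt_run)
        if not keep_events:
            rec.events = rec.events.iloc[0:0]
        records.append(rec)
    return pool_ensemble(records, bin_width=bin_width, params=params,
                         master_seed=master_seed)
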