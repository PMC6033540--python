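"""Kinetic observables of simulated S-phases.

The central quantity is the firing rate per length of unreplicated DNA,

    I_S(t) = N_fired(t, t+dt) / (L_unrep(t) * dt),

estimated here per time bin as a ratio of sums — total firings in the bin
divided by the total unreplicated DNA-time in the bin — and pooled across
runs the same way.  Ratio-of-sums keeps the estimator finite when
individual runs approach full replication (their denominator vanishes);
a run that has finished simply stops contributing.  Uncertainties come
from a seeded run-level bootstrap.

Also provided: the maximum Imax of the pooled curve (with a small-
denominator tail guard), the normalized p-ori density and free-factor
series, the passivated/activated origin ratio, the replication-time
distribution and the density of activated origins per kb of genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .theory import critical_free_factors

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import KineticsRecord, SimParams

__all__ = [
    "EnsembleKinetics",
    "firing_rate_series",
    "pool_firing_rate",
    "pool_ensemble",
    "estimate_imax",
    "passivation_activation_ratio",
    "replication_time_summary",
    "activated_origin_density",
    "kinetics_table",
]


def _bin_matrices(records: Sequence["KineticsRecord"], bin_width: float):
    """Per-run, per-bin sums needed by every pooled observable.

    Returns (edges, F, D, P, R, N, U) where per run r and bin b:
    F = firings, D = unreplicated DNA-time (kb*min), P = passivations,
    R = p-ori-count-time (count*min), N = free-factor-time (count*min),
    U = time simulated while unreplicated DNA remained (min).
    """
    t_end = max(rec.replication_time for rec in records)
    n_bins = max(int(np.ceil(t_end / bin_width - 1e-9)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    shape = (len(records), n_bins)
    F = np.zeros(shape)
    D = np.zeros(shape)
    P = np.zeros(shape)
    R = np.zeros(shape)
    N = np.zeros(shape)
    U = np.zeros(shape)
    for r, rec in enumerate(records):
        t = rec.times[:-1]  # step-start times; terminal point carries no step
        b = np.minimum((t / bin_width).astype(int), n_bins - 1)
        dt = rec.dt
        alive = rec.l_unrep[:-1] > 0
        F[r] = np.bincount(b, weights=rec.n_fired[:-1], minlength=n_bins)
        P[r] = np.bincount(b, weights=rec.n_passivated[:-1], minlength=n_bins)
        D[r] = np.bincount(b, weights=rec.l_unrep[:-1] * dt, minlength=n_bins)
        R[r] = np.bincount(b[alive], weights=rec.np_ori[:-1][alive] * dt,
                           minlength=n_bins)
        N[r] = np.bincount(b[alive], weights=rec.nfd[:-1][alive] * dt,
                           minlength=n_bins)
        U[r] = np.bincount(b[alive], weights=np.full(alive.sum(), dt),
                           minlength=n_bins)
    return edges, F, D, P, R, N, U


def firing_rate_series(record: "KineticsRecord",
                       bin_width: float) -> pd.DataFrame:
    """I_S(t) of a single run, binned at ``bin_width`` minutes.

    Per bin, I = (total firings) / (total L_unrep*dt); bins after the run
    has completed (zero unreplicated DNA throughout) are dropped.

    Returns a DataFrame with columns ``t`` (bin midpoint, min) and ``I``
    (1/(kb*min)).
    """
    if bin_width < record.dt:
        raise ValueError(
            f"bin_width ({bin_width}) must be >= the simulation dt ({record.dt})"
        )
    edges, F, D, *_ = _bin_matrices([record], bin_width)
    mask = D[0] > 0
    t_mid = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"t": t_mid[mask], "I": F[0][mask] / D[0][mask]})


def pool_firing_rate(records: Sequence["KineticsRecord"], bin_width: float,
                     n_boot: int = 200, boot_seed: int = 0):
    """Ensemble I_S(t) with bootstrap standard errors.

    Ratio of sums across runs per bin; standard errors from ``n_boot``
    run-level bootstrap resamples (seeded, so reproducible).

    Returns (t_mid, I, I_stderr) arrays over bins with nonzero
    unreplicated DNA-time.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    edges, F, D, *_ = _bin_matrices(records, bin_width)
    mask = D.sum(axis=0) > 0
    t_mid = 0.5 * (edges[:-1] + edges[1:])[mask]
    i_pool = F.sum(axis=0)[mask] / D.sum(axis=0)[mask]
    rng = np.random.default_rng(np.random.SeedSequence([boot_seed, 0xB007]))
    n = len(records)
    boots = np.empty((n_boot, mask.sum()))
    for bi in range(n_boot):
        idx = rng.integers(0, n, size=n)
        num = F[idx].sum(axis=0)[mask]
        den = D[idx].sum(axis=0)[mask]
        boots[bi] = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return t_mid, i_pool, boots.std(axis=0, ddof=1)


@dataclass
class EnsembleKinetics:
    """Pooled kinetics of an ensemble of independent S-phase runs.

    Curves are binned at ``bin_width``; ``t`` holds bin midpoints for
    bins during which at least one run was still replicating.  Normalized
    curves follow the model's natural scales: p-ori density by rho0 and
    free factors by the critical threshold NFD* = v/(kon/rho0 ... i.e.
    v*rho0/kon).  ``pass_act_ratio`` is NaN in bins with no activation.
    """

    bin_width: float
    t: np.ndarray
    i_pooled: np.ndarray
    i_stderr: np.ndarray
    rho_norm: np.ndarray
    nfd_norm: np.ndarray
    pass_act_ratio: np.ndarray
    unrep_frac: np.ndarray
    replication_times: np.ndarray
    n_runs: int
    rho0: float
    nfd_star: float
    total_length: float
    per_run: pd.DataFrame = field(repr=False)
    records: list = field(repr=False, default_factory=list)
    master_seed: int | None = None

    @property
    def mean_replication_time(self) -> float:
        return float(np.mean(self.replication_times))


def pool_ensemble(records: Sequence["KineticsRecord"], bin_width: float,
                  params: "SimParams | None" = None,
                  master_seed: int | None = None,
                  n_boot: int = 200) -> EnsembleKinetics:
    """Reduce raw run records to pooled ensemble observables."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    edges, F, D, P, R, N, U = _bin_matrices(records, bin_width)
    mask = D.sum(axis=0) > 0
    t_mid = 0.5 * (edges[:-1] + edges[1:])[mask]
    i_pool = F.sum(axis=0)[mask] / D.sum(axis=0)[mask]

    boot_seed = 0 if master_seed is None else int(master_seed) % (2**31)
    _, _, i_se = pool_firing_rate(records, bin_width, n_boot=n_boot,
                                  boot_seed=boot_seed)

    # time-averaged density / free-factor curves over runs still replicating
    Rs, Ds, Ns, Us = (A.sum(axis=0)[mask] for A in (R, D, N, U))
    rho = np.divide(Rs, Ds, out=np.full_like(Rs, np.nan), where=Ds > 0)
    nfd = np.divide(Ns, Us, out=np.full_like(Ns, np.nan), where=Us > 0)

    fired_b = F.sum(axis=0)[mask]
    pass_b = P.sum(axis=0)[mask]
    ratio = np.divide(pass_b, fired_b, out=np.full_like(pass_b, np.nan),
                      where=fired_b > 0)

    L = float(np.mean([rec.total_length for rec in records]))
    rho0 = float(np.mean([rec.n_origins_initial / rec.total_length
                          for rec in records]))
    if params is not None:
        nfd_star = critical_free_factors(params.v, params.kon, 1.0 / rho0)
    else:
        nfd_star = np.nan
    unrep_frac = D.mean(axis=0)[mask] / (bin_width * L)

    per_run = pd.DataFrame({
        "replication_time": [rec.replication_time for rec in records],
        "n_fired": [rec.total_fired for rec in records],
        "n_passivated": [rec.total_passivated for rec in records],
        "n_origins": [rec.n_origins_initial for rec in records],
        "ndt_used": [rec.ndt_used for rec in records],
        "total_length": [rec.total_length for rec in records],
    })
    return EnsembleKinetics(
        bin_width=bin_width,
        t=t_mid,
        i_pooled=i_pool,
        i_stderr=i_se,
        rho_norm=rho / rho0,
        nfd_norm=nfd / nfd_star if np.isfinite(nfd_star) else nfd,
        pass_act_ratio=ratio,
        unrep_frac=unrep_frac,
        replication_times=per_run["replication_time"].to_numpy(),
        n_runs=len(records),
        rho0=rho0,
        nfd_star=float(nfd_star),
        total_length=L,
        per_run=per_run,
        records=list(records),
        master_seed=master_seed,
    )


def estimate_imax(ensemble: EnsembleKinetics,
                  tail_exclusion: float = 0.05) -> tuple[float, float]:
    """Maximum of the pooled I(t) and the bin time where it occurs.

    Bins where the mean unreplicated fraction has dropped to
    ``tail_exclusion`` or below are excluded: with almost no unreplicated
    DNA left the rate estimate is a small-count/small-denominator ratio
    and would otherwise dominate the maximum spuriously.
    """
    keep = ensemble.unrep_frac > tail_exclusion
    if not keep.any():
        raise ValueError("all bins fall below the tail-exclusion threshold")
    i = ensemble.i_pooled[keep]
    t = ensemble.t[keep]
    j = int(np.argmax(i))
    return float(i[j]), float(t[j])


def passivation_activation_ratio(source, bin_width: float | None = None,
                                 mode: str = "per_bin") -> pd.DataFrame:
    """Ratio of passivated to activated origins over time.

    ``mode="per_bin"`` divides the counts within each bin;
    ``mode="cumulative"`` divides the running totals.  Bins (or times)
    with zero activations in the denominator are NaN, never zero.

    ``source`` may be an `EnsembleKinetics` (per-bin mode uses its
    pooled counts) or a sequence of records / single record with
    ``bin_width`` given.
    """
    if mode not in ("per_bin", "cumulative"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(source, EnsembleKinetics):
        records = source.records
        bin_width = source.bin_width
        if mode == "per_bin":
            return pd.DataFrame({"t": source.t, "ratio": source.pass_act_ratio})
    else:
        records = [source] if hasattr(source, "times") else list(source)
        if bin_width is None:
            raise ValueError("bin_width required when passing raw records")
    edges, F, D, P, *_ = _bin_matrices(records, bin_width)
    mask = D.sum(axis=0) > 0
    t_mid = 0.5 * (edges[:-1] + edges[1:])[mask]
    fired = F.sum(axis=0)[mask]
    passv = P.sum(axis=0)[mask]
    if mode == "cumulative":
        fired = np.cumsum(fired)
        passv = np.cumsum(passv)
    ratio = np.divide(passv, fired, out=np.full_like(passv, np.nan),
                      where=fired > 0)
    return pd.DataFrame({"t": t_mid, "ratio": ratio})


def replication_time_summary(
        ensemble: EnsembleKinetics) -> tuple[float, float, np.ndarray]:
    """Mean, standard deviation and raw samples of the replication time."""
    t = ensemble.replication_times
    sd = float(np.std(t, ddof=1)) if len(t) >= 2 else float("nan")
    return float(np.mean(t)), sd, t


def activated_origin_density(ensemble: EnsembleKinetics) -> float:
    """Mean over runs of (origins fired) / (genome length), 1/kb."""
    pr = ensemble.per_run
    return float(np.mean(pr["n_fired"] / pr["total_length"]))


def kinetics_table(ensemble: EnsembleKinetics) -> pd.DataFrame:
    """Pooled curves as one exportable table (see `io.write_results`)."""
    return pd.DataFrame({
        "t_min": ensemble.t,
        "I": ensemble.i_pooled,
        "I_stderr": ensemble.i_stderr,
        "rho_norm": ensemble.rho_norm,
        "nfd_norm": ensemble.nfd_norm,
        "pass_act_ratio": ensemble.pass_act_ratio,
        "unrep_frac": ensemble.unrep_frac,
    })
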