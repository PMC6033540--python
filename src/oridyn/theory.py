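"""Closed-form predictions of the well-mixed replication model.

The model couples two time scales: the characteristic time to fire a
potential origin, ``tc = 1/(kon * NFD)``, and the time for a fork to
replicate the DNA separating two neighboring p-oris, ``tr = d/v``.  As
long as ``tc > tr`` (equivalently ``NFD < NFD* = v/(kon*d)``) the p-ori
density over unreplicated DNA stays constant; once the free-factor count
exceeds NFD* the density is depleted faster than DNA is consumed and the
firing rate I(t) turns over.  At the turnover,

    Imax = kon * rho0 * NFD*  ~=  v * rho0**2

with ``d ~= 1/rho0`` (exact for periodically spaced origins).  Imax is
thus predicted from two measurable quantities, the fork speed and the
initial p-ori density.
"""

from __future__ import annotations

from dataclasses import replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SimParams

__all__ = [
    "critical_free_factors",
    "predicted_imax",
    "bimolecular_rate",
    "density_criterion",
    "rescale_parameters",
    "two_compartment_imax",
    "empirical_mean_spacing",
    "per_mb",
]


def per_mb(rate_per_kb: float) -> float:
    """Convert a rate density from 1/kb (internal unit) to 1/Mb (display)."""
    return rate_per_kb * 1000.0


def critical_free_factors(v: float, kon: float, d: float) -> float:
    """Critical free-factor count NFD* = v / (kon * d).

    Below NFD* the unreplicated p-ori density is constant in time; above
    it, origins are consumed faster than DNA is replicated and the density
    (hence I(t)) declines.

    Parameters
    ----------
    v : fork speed, kb/min.
    kon : productive-interaction rate, 1/min.
    d : mean distance between unreplicated p-oris, kb (``1/rho0`` for a
        periodic origin layout).
    """
    if kon <= 0 or d <= 0:
        raise ValueError(f"need kon > 0 and d > 0, got kon={kon}, d={d}")
    if v < 0:
        raise ValueError(f"fork speed must be >= 0, got {v}")
    return v / (kon * d)


def predicted_imax(v: float, rho0: float) -> float:
    """Predicted maximal firing rate Imax = v * rho0**2, in 1/(kb*min)."""
    if v < 0 or rho0 < 0:
        raise ValueError("v and rho0 must be non-negative")
    return v * rho0 * rho0


def bimolecular_rate(kon: float, nfd: float, rho: float) -> float:
    """Instantaneous firing rate per unreplicated length, I = kon * NFD * rho.

    ``rho`` is the p-ori density over unreplicated DNA, 1/kb.  At the
    turnover point (``nfd = NFD*``, ``rho = rho0``, ``d = 1/rho0``) this
    equals `predicted_imax`.
    """
    if kon < 0 or nfd < 0 or rho < 0:
        raise ValueError("all inputs must be non-negative")
    return kon * nfd * rho


def density_criterion(v: float, kon: float, nfd: float, d: float) -> str:
    """Classify the kinetic regime at free-factor count ``nfd``.

    Returns ``"constant-density"`` when ``d/v < 1/(kon*nfd)`` (firing slower
    than inter-origin replication, p-ori density conserved) and
    ``"density-depleting"`` otherwise.  ``nfd = 0`` is constant-density.
    """
    if v <= 0 or kon <= 0 or d <= 0:
        raise ValueError("v, kon and d must be positive")
    if nfd < 0:
        raise ValueError("nfd must be >= 0")
    if nfd == 0 or nfd < critical_free_factors(v, kon, d):
        return "constant-density"
    return "density-depleting"


def rescale_parameters(params: "SimParams", alpha: float) -> "SimParams":
    """Rescale (L -> alpha*L, NDT -> alpha*NDT, kon -> kon/alpha).

    This transformation preserves the S-phase duration
    ``Tphase ~ L / (2 v NDT)`` and the firing rate I(t), allowing large
    genomes to be simulated at reduced size.  rho0 (and therefore the
    predicted Imax) is unchanged.  A warning is emitted when
    ``alpha * NDT`` is not an integer; the count is rounded.
    """
    import warnings

    from .genome import GenomeSpec, periodic_genome, uniform_genome

    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    ndt_scaled = params.ndt * alpha
    ndt_new = int(round(ndt_scaled))
    if abs(ndt_scaled - ndt_new) > 1e-9:
        warnings.warn(
            f"alpha*NDT = {ndt_scaled} is not an integer; rounding to {ndt_new}",
            stacklevel=2,
        )
    g = params.genome
    if g.placement == "fixed":
        raise ValueError("rescaling is defined for resampled (uniform/periodic) genomes")
    chrom = g.chromosomes[0]
    rng = np.random.default_rng(0)  # positions are redrawn per run anyway
    rho_req = g._requested_rho0 if g.placement == "periodic" else g.rho0
    builder = periodic_genome if g.placement == "periodic" else uniform_genome
    genome_new = builder(chrom.length * alpha, rho_req, rng, chrom_id=chrom.id)
    return replace(params, genome=genome_new, ndt=ndt_new, kon=params.kon / alpha)


def two_compartment_imax(v: float, rho_early: float) -> float:
    """Upper bound on Imax for a genome split into early/late compartments.

    When half the genome carries a high p-ori density ``rho_early`` and the
    other half a much lower one, firing comes almost entirely from the
    dense half while the unreplicated-length denominator still counts the
    sparse half, capping the global rate at ``0.5 * v * rho_early**2``.
    """
    if v < 0 or rho_early < 0:
        raise ValueError("v and rho_early must be non-negative")
    return 0.5 * v * rho_early * rho_early


def empirical_mean_spacing(positions_by_chrom: dict[str, np.ndarray]) -> float:
    """Mean nearest-neighbor spacing d between origins, pooled over chromosomes.

    Offered for non-periodic layouts where ``d`` deviates from ``1/rho0``.
    """
    gaps: list[np.ndarray] = []
    for pos in positions_by_chrom.values():
        if len(pos) >= 2:
            gaps.append(np.diff(np.sort(pos)))
    if not gaps:
        raise ValueError("need at least two origins on one chromosome")
    return float(np.mean(np.concatenate(gaps)))
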