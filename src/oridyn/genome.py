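"""Genome and potential-origin configurations.

Chromosomes are 1D segments measured in kb, with continuous coordinates in
the half-open interval [0, L).  Potential origins (p-oris) are licensed
point loci on those segments; during S-phase each one either *fires*
(initiates a pair of divergent forks) or is *passivated* (overrun by a
fork coming from elsewhere).

Three ways to build a genome are provided:

* random-uniform placement (embryonic-style genomes where origin positions
  differ from cell cycle to cell cycle),
* periodic placement (exactly one origin per consecutive 1/rho0 segment,
  jittered uniformly inside the segment to avoid synchronization artifacts),
* a tab-separated origin-map file in an OriDB-like dialect, for organisms
  such as *S. cerevisiae* whose origins sit at fixed mapped positions.

A fixture writer emits files in the same dialect so the reader can be
exercised without any external download.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_CATEGORIES",
    "Chromosome",
    "GenomeSpec",
    "OriginMapError",
    "place_origins_uniform",
    "place_origins_periodic",
    "read_origin_file",
    "generate_fixture_origin_file",
    "uniform_genome",
    "periodic_genome",
    "YEAST_CHROM_LENGTHS_KB",
]

#: Origin annotation categories accepted in origin-map files, plus the
#: label used for programmatically generated origins.
STATUS_CATEGORIES = ("Confirmed", "Likely", "Dubious", "Synthetic")

#: S. cerevisiae (sacCer) chromosome lengths in kb, chromosomes I–XVI.
#: Used by fixtures and examples that need a realistic 16-chromosome genome.
YEAST_CHROM_LENGTHS_KB = (
    230.2, 813.2, 316.6, 1531.9, 576.9, 270.2, 1090.9, 562.6,
    439.9, 745.8, 666.8, 1078.2, 924.4, 784.3, 1091.3, 948.1,
)


class OriginMapError(ValueError):
    """Raised for malformed origin-map files or inconsistent coordinates."""


@dataclass(frozen=True)
class Chromosome:
    """A chromosome as a 1D segment of DNA.

    Parameters
    ----------
    id : str
        Label (e.g. ``"chr1"``).
    length : float
        Length in kb; coordinates live in ``[0, length)``.
    """

    id: str
    length: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"chromosome {self.id!r}: length must be > 0, got {self.length}")


@dataclass(frozen=True)
class GenomeSpec:
    """A genome together with its potential-origin map.

    ``origins`` is a DataFrame with columns ``chrom`` (str), ``position``
    (float, kb) and ``status`` (category label), sorted by (chrom order,
    position), one row per p-ori.  ``placement`` records how the map was
    built: ``"uniform"`` and ``"periodic"`` genomes re-sample origin
    positions for every simulated S-phase, ``"fixed"`` genomes (file-based
    maps) keep them identical across runs.
    """

    chromosomes: tuple[Chromosome, ...]
    origins: pd.DataFrame = field(repr=False)
    placement: str = "fixed"

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        lengths = {c.id: c.length for c in self.chromosomes}
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome ids")
        df = self.origins
        for col in ("chrom", "position", "status"):
            if col not in df.columns:
                raise ValueError(f"origin table missing column {col!r}")
        for chrom, pos in zip(df["chrom"], df["position"]):
            if chrom not in lengths:
                raise OriginMapError(f"origin on unknown chromosome {chrom!r}")
            if not (0 <= pos < lengths[chrom]):
                raise OriginMapError(
                    f"origin at {pos} kb outside chromosome {chrom!r} [0, {lengths[chrom]})"
                )
        if df.duplicated(subset=["chrom", "position"]).any():
            raise OriginMapError("two origins share an identical (chromosome, position)")

    @property
    def total_length(self) -> float:
        """Total genome length L in kb."""
        return float(sum(c.length for c in self.chromosomes))

    @property
    def n_origins(self) -> int:
        """Number of potential origins Np-ori(t=0)."""
        return int(len(self.origins))

    @property
    def rho0(self) -> float:
        """Initial p-ori density rho0 = Np-ori(0) / L in 1/kb."""
        return self.n_origins / self.total_length

    def positions_by_chromosome(self) -> dict[str, np.ndarray]:
        """Sorted origin positions (kb) keyed by chromosome id."""
        out: dict[str, np.ndarray] = {c.id: np.empty(0) for c in self.chromosomes}
        for chrom, grp in self.origins.groupby("chrom", sort=False):
            out[str(chrom)] = np.sort(grp["position"].to_numpy(dtype=float))
        return out

    def resample(self, rng: np.random.Generator) -> "GenomeSpec":
        """Redraw origin positions for a new S-phase.

        Uniform and periodic genomes get fresh positions at the same
        density; fixed (file-based) genomes are returned unchanged.
        """
        if self.placement == "fixed":
            return self
        chrom = self.chromosomes[0]
        if len(self.chromosomes) != 1:  # pragma: no cover - constructors enforce this
            raise ValueError("resampling genomes only supported for single chromosomes")
        if self.placement == "uniform":
            return uniform_genome(chrom.length, self.rho0, rng, chrom_id=chrom.id)
        if self.placement == "periodic":
            # rho0 of a periodic genome is floor(L*rho0)/L; recover the
            # requested density from the segment structure instead.
            rho_req = self._requested_rho0 if self._requested_rho0 else self.rho0
            return periodic_genome(chrom.length, rho_req, rng, chrom_id=chrom.id)
        raise ValueError(f"unknown placement {self.placement!r}")

    # stashed by the periodic constructor so resampling keeps the exact
    # requested density rather than the floor-quantized realized one
    _requested_rho0: float = 0.0


def _origin_frame(chrom_ids: Sequence[str], positions: Sequence[float],
                  statuses: Sequence[str]) -> pd.DataFrame:
    df = pd.DataFrame({
        "chrom": list(chrom_ids),
        "position": np.asarray(positions, dtype=float),
        "status": list(statuses),
    })
    return df.reset_index(drop=True)


def place_origins_uniform(length: float, rho0: float,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Place ``round(length * rho0)`` origins i.i.d. uniform on [0, length).

    Duplicate positions (a measure-zero event with float coordinates) are
    resolved by redrawing, so the origin count is exact.

    Returns the origin table (chrom column left as ``"chr1"``), sorted by
    position.
    """
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    if rho0 < 0:
        raise ValueError(f"rho0 must be >= 0, got {rho0}")
    n = int(round(length * rho0))
    pos = rng.uniform(0.0, length, size=n)
    # resolve duplicates by redraw (keeps the count exact)
    while n > 1:
        uniq = np.unique(pos)
        if uniq.size == n:
            break
        extra = rng.uniform(0.0, length, size=n - uniq.size)
        pos = np.concatenate([uniq, extra])
    pos = np.sort(pos)
    return _origin_frame(["chr1"] * n, pos, ["Synthetic"] * n)


def place_origins_periodic(length: float, rho0: float,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Place exactly one origin per consecutive non-overlapping 1/rho0 segment.

    Within each segment the position is uniform, which avoids spurious
    synchronization between neighboring origins.  A trailing partial
    segment carries no origin, so the count is ``floor(length * rho0)``.
    """
    if rho0 <= 0 or length < 1.0 / rho0:
        raise ValueError(
            f"need length >= 1/rho0 > 0, got length={length}, rho0={rho0}"
        )
    seg = 1.0 / rho0
    n = int(np.floor(length * rho0))
    starts = np.arange(n) * seg
    pos = starts + rng.uniform(0.0, seg, size=n)
    return _origin_frame(["chr1"] * n, pos, ["Synthetic"] * n)


def uniform_genome(length: float, rho0: float, rng: np.random.Generator,
                   chrom_id: str = "chr1") -> GenomeSpec:
    """Single-chromosome genome with uniformly placed origins."""
    df = place_origins_uniform(length, rho0, rng)
    df["chrom"] = chrom_id
    return GenomeSpec((Chromosome(chrom_id, float(length)),), df, placement="uniform")


def periodic_genome(length: float, rho0: float, rng: np.random.Generator,
                    chrom_id: str = "chr1") -> GenomeSpec:
    """Single-chromosome genome with periodically placed origins."""
    df = place_origins_periodic(length, rho0, rng)
    df["chrom"] = chrom_id
    spec = GenomeSpec((Chromosome(chrom_id, float(length)),), df, placement="periodic")
    object.__setattr__(spec, "_requested_rho0", float(rho0))
    return spec


# ---------------------------------------------------------------------------
# Origin-map file dialect
#
# Tab-separated, UTF-8.  Comment lines start with '#'.  A comment of the
# special form "#chrom <name> <length_kb>" declares a chromosome and its
# length; when absent, lengths fall back to the max end coordinate seen on
# that chromosome.  Data columns (BED3+2-like ordering):
#     chrom  start_kb  end_kb  name  status
# with status in {Confirmed, Likely, Dubious}.  Coordinates are kb.
# ---------------------------------------------------------------------------

def read_origin_file(path: str | Path,
                     categories: Iterable[str],
                     interval_to_point: str = "midpoint") -> GenomeSpec:
    """Read an OriDB-style origin map, keeping only the requested categories.

    Each origin interval ``(start, end)`` is collapsed to a point: its
    midpoint by default, or its start coordinate with
    ``interval_to_point="start"`` (the mapping literature does not settle
    which convention underlies published origin lists, so both are offered).

    Raises
    ------
    ValueError
        If ``categories`` is empty.
    OriginMapError
        For malformed lines (with the 1-based line number) or origins
        outside their chromosome.
    """
    categories = set(categories)
    if not categories:
        raise ValueError("categories must be a nonempty set of status labels")
    unknown = categories - set(STATUS_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown status categories: {sorted(unknown)}")
    if interval_to_point not in ("midpoint", "start"):
        raise ValueError("interval_to_point must be 'midpoint' or 'start'")

    declared: dict[str, float] = {}
    rows: list[tuple[str, float, float, str]] = []
    seen_order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "chrom":
                    if len(parts) != 3:
                        raise OriginMapError(
                            f"line {lineno}: bad chromosome header {line!r}"
                        )
                    try:
                        declared[parts[1]] = float(parts[2])
                    except ValueError as exc:
                        raise OriginMapError(
                            f"line {lineno}: bad chromosome length in {line!r}"
                        ) from exc
                    if parts[1] not in seen_order:
                        seen_order.append(parts[1])
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise OriginMapError(
                    f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, _name, status = fields
            try:
                start, end = float(start_s), float(end_s)
            except ValueError as exc:
                raise OriginMapError(f"line {lineno}: non-numeric coordinates") from exc
            if status not in ("Confirmed", "Likely", "Dubious"):
                raise OriginMapError(f"line {lineno}: unknown status {status!r}")
            if end < start:
                raise OriginMapError(f"line {lineno}: end < start")
            if chrom not in seen_order:
                seen_order.append(chrom)
            rows.append((chrom, start, end, status))

    lengths = dict(declared)
    for chrom, start, end, _ in rows:
        if chrom not in lengths:
            lengths[chrom] = 0.0
        if chrom not in declared:
            lengths[chrom] = max(lengths[chrom], end)
    chroms = tuple(Chromosome(cid, lengths[cid]) for cid in seen_order)

    kept = [(c, s, e, st) for (c, s, e, st) in rows if st in categories]
    if interval_to_point == "midpoint":
        pts = [(c, 0.5 * (s + e), st) for (c, s, e, st) in kept]
    else:
        pts = [(c, s, st) for (c, s, e, st) in kept]
    # validate against declared lengths before constructing
    for c, p, _ in pts:
        if not (0 <= p < lengths[c]):
            raise OriginMapError(
                f"origin at {p} kb outside chromosome {c!r} [0, {lengths[c]})"
            )
    order = {cid: i for i, cid in enumerate(seen_order)}
    pts.sort(key=lambda t: (order[t[0]], t[1]))
    df = _origin_frame([p[0] for p in pts], [p[1] for p in pts], [p[2] for p in pts])
    return GenomeSpec(chroms, df, placement="fixed")


def generate_fixture_origin_file(
    path: str | Path,
    lengths: Sequence[float],
    counts_per_status: Mapping[str, int],
    rng: np.random.Generator,
    chrom_ids: Sequence[str] | None = None,
    interval_halfwidth: float = 0.25,
) -> Path:
    """Write a synthetic origin-map file in the dialect of `read_origin_file`.

    Origins of each status are distributed over chromosomes proportionally
    to length (multinomial), placed uniformly, and written as short
    intervals of half-width ``interval_halfwidth`` kb centered on the point
    position (clipped to the chromosome), so that midpoint collapse
    round-trips exactly.

    This is a synthetic stand-in for a curated origin database export; it
    reproduces the file dialect and category structure, not real mapped
    origin coordinates.
    """
    lengths = [float(x) for x in lengths]
    if any(x <= 0 for x in lengths):
        raise ValueError("chromosome lengths must be positive")
    if chrom_ids is None:
        chrom_ids = [f"chr{i + 1}" for i in range(len(lengths))]
    if len(chrom_ids) != len(lengths):
        raise ValueError("chrom_ids and lengths must have equal length")
    bad = set(counts_per_status) - {"Confirmed", "Likely", "Dubious"}
    if bad:
        raise ValueError(f"unknown status categories: {sorted(bad)}")

    probs = np.asarray(lengths) / sum(lengths)
    buf = io.StringIO()
    for cid, ln in zip(chrom_ids, lengths):
        buf.write(f"#chrom {cid} {ln:.3f}\n")
    records: list[tuple[int, float, str]] = []  # (chrom index, position, status)
    for status in ("Confirmed", "Likely", "Dubious"):
        n = int(counts_per_status.get(status, 0))
        if n == 0:
            continue
        per_chrom = rng.multinomial(n, probs)
        for ci, k in enumerate(per_chrom):
            pos = rng.uniform(0.0, lengths[ci], size=k)
            records.extend((ci, float(p), status) for p in pos)
    records.sort(key=lambda t: (t[0], t[1]))
    counter = 0
    for ci, pos, status in records:
        ln = lengths[ci]
        half = min(interval_halfwidth, pos, (ln - pos) / 2)
        start, end = pos - half, pos + half
        counter += 1
        buf.write(
            f"{chrom_ids[ci]}\t{start:.6f}\t{end:.6f}\tori{counter:05d}\t{status}\n"
        )
    path = Path(path)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path
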