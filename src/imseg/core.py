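"""Domain types and I/O for per-CpG count tracks and genomic region sets.

Coordinates are 0-based, half-open (BED convention) throughout the package.
A CpG position refers to the cytosine of the CG dinucleotide on the forward
strand; MeDIP and MRE read counts are strand-collapsed upstream, and input
counts are assumed already deduplicated and mapping-quality filtered.

The central container is :class:`CpGTrack`: one sample's ordered per-CpG
MeDIP-seq and MRE-seq read densities. Tracks are read from a headerless
4-column TSV (``chrom  pos  medip  mre``); region sets use BED3+ text.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "REGION_STATES",
    "ParseError",
    "CpGSite",
    "CpGTrack",
    "GenomicRegion",
    "DetectionParams",
    "read_cpg_counts",
    "write_cpg_counts",
    "normalize_track",
    "read_regions",
    "write_regions",
]

#: Recognised methylation-state tags for regions.
REGION_STATES = ("IM", "methylated", "unmethylated", "neither")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class CpGSite:
    """A single CpG with its (possibly normalized) assay read densities."""

    chrom: str
    pos: int
    medip: float
    mre: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"CpG position must be >= 0, got {self.pos}")
        if self.medip < 0 or self.mre < 0:
            raise ValueError("read densities must be non-negative")


@dataclass
class CpGTrack:
    """Ordered per-CpG paired MeDIP/MRE read densities for one sample.

    Sites are stored as parallel numpy arrays, grouped by chromosome and
    strictly increasing in position within each chromosome. ``medip_total``
    and ``mre_total`` are the raw per-assay totals (sums before any
    normalization); :func:`normalize_track` rescales the densities but keeps
    the raw totals.
    """

    sample_id: str
    chrom: np.ndarray
    pos: np.ndarray
    medip: np.ndarray
    mre: np.ndarray
    medip_total: float
    mre_total: float

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.medip = np.asarray(self.medip, dtype=np.float64)
        self.mre = np.asarray(self.mre, dtype=np.float64)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.medip) == len(self.mre) == n):
            raise ValueError("track arrays must have equal length")
        if n and self.pos.min() < 0:
            raise ValueError("CpG positions must be >= 0")
        if n and (self.medip.min() < 0 or self.mre.min() < 0):
            raise ValueError("read densities must be non-negative")
        for _, sl in self.iter_chromosomes():
            p = self.pos[sl]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"positions must be strictly increasing within a chromosome "
                    f"(sample {self.sample_id!r})"
                )

    # -- construction ---------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        chrom: Sequence[str],
        pos: Sequence[int],
        medip: Sequence[float],
        mre: Sequence[float],
    ) -> "CpGTrack":
        """Build a validated track, sorting by (chrom, pos) as needed."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        medip = np.asarray(medip, dtype=np.float64)
        mre = np.asarray(mre, dtype=np.float64)
        if len(pos):
            order = np.lexsort((pos, chrom.astype(str)))
            if not np.array_equal(order, np.arange(len(pos))):
                chrom, pos = chrom[order], pos[order]
                medip, mre = medip[order], mre[order]
            same = (chrom[1:] == chrom[:-1]) & (pos[1:] == pos[:-1])
            if np.any(same):
                i = int(np.flatnonzero(same)[0])
                raise ParseError(
                    f"duplicate CpG coordinate {chrom[i]}:{pos[i]} in sample {sample_id!r}"
                )
        return cls(
            sample_id=sample_id,
            chrom=chrom,
            pos=pos,
            medip=medip,
            mre=mre,
            medip_total=float(medip.sum()),
            mre_total=float(mre.sum()),
        )

    # -- views ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sites(self) -> Iterator[CpGSite]:
        for c, p, m, r in zip(self.chrom, self.pos, self.medip, self.mre):
            yield CpGSite(str(c), int(p), float(m), float(r))

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(str(c))
        return out

    def iter_chromosomes(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(chrom, slice)`` for each contiguous chromosome block."""
        n = len(self.pos)
        start = 0
        for i in range(1, n + 1):
            if i == n or self.chrom[i] != self.chrom[start]:
                yield str(self.chrom[start]), slice(start, i)
                start = i

    def replace_counts(self, medip: np.ndarray, mre: np.ndarray) -> "CpGTrack":
        return dataclasses.replace(
            self, medip=np.asarray(medip, float), mre=np.asarray(mre, float)
        )


@dataclass
class GenomicRegion:
    """A scored half-open genomic interval with an optional methylation state.

    ``support`` counts distinct contributing samples and is meaningful only
    for reference-set regions (0 elsewhere).
    """

    chrom: str
    start: int
    end: int
    score: float = 0.0
    sample_id: str = ""
    state: str = "neither"
    support: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region start must be < end, got [{self.start}, {self.end})"
            )
        if not np.isfinite(self.score):
            raise ValueError("region score must be finite")
        if self.state not in REGION_STATES:
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DetectionParams:
    """Scoring constants and cutoffs for the IM segmentation algorithm.

    medip_target, mre_target
        Library-size normalization targets for total MeDIP and MRE read
        counts (defaults 50 M and 35 M).
    overlap_weight
        Scale ``w`` applied to the per-CpG reward/penalty.
    gap_penalty_rate
        Penalty per base pair between consecutive CpGs (default 0.01/bp).
    min_score, min_length
        Call filters; the length cutoff is enforced at the reference-set
        stage, not on raw per-sample calls.
    min_ref_samples, merge_gap
        Reference-set assembly: minimum distinct supporting samples and the
        maximum gap (bp) merged across samples.
    """

    medip_target: float = 50_000_000.0
    mre_target: float = 35_000_000.0
    overlap_weight: float = 1.0
    gap_penalty_rate: float = 0.01
    min_score: float = 8.0
    min_length: int = 100
    min_ref_samples: int = 2
    merge_gap: int = 100

    def __post_init__(self) -> None:
        for name in (
            "medip_target",
            "mre_target",
            "overlap_weight",
            "gap_penalty_rate",
            "min_score",
            "min_length",
            "min_ref_samples",
            "merge_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# CpG count track I/O
# ---------------------------------------------------------------------------

def read_cpg_counts(path: str | Path, sample_id: str | None = None) -> CpGTrack:
    """Read a 4-column ``chrom pos medip mre`` TSV into a validated track.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. Unsorted
    input is sorted with a warning; duplicate coordinates raise
    :class:`ParseError` with the offending coordinate.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    chroms: list[str] = []
    poss: list[int] = []
    medips: list[float] = []
    mres: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 columns (chrom pos medip mre), "
                    f"got {len(parts)}"
                )
            try:
                pos = int(parts[1])
                medip = float(parts[2])
                mre = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if pos < 0 or medip < 0 or mre < 0:
                raise ParseError(f"{path}:{lineno}: negative value")
            chroms.append(parts[0])
            poss.append(pos)
            medips.append(medip)
            mres.append(mre)
    if poss:
        key = list(zip(chroms, poss))
        if key != sorted(key):
            warnings.warn(
                f"{path}: input not sorted by (chrom, pos); sorting internally",
                stacklevel=2,
            )
    return CpGTrack.from_arrays(sample_id, chroms, poss, medips, mres)


def write_cpg_counts(track: CpGTrack, path: str | Path) -> None:
    """Write a track back to the 4-column TSV dialect (LF line endings)."""
    with open(path, "w", newline="\n") as fh:
        for c, p, m, r in zip(track.chrom, track.pos, track.medip, track.mre):
            fh.write(f"{c}\t{p}\t{m:g}\t{r:g}\n")


def normalize_track(track: CpGTrack, params: DetectionParams) -> CpGTrack:
    """Rescale per-CpG densities so assay totals hit the library-size targets.

    MeDIP densities are multiplied by ``medip_target / medip_total`` and MRE
    densities by ``mre_target / mre_total``. Normalized densities stay
    real-valued (no re-rounding); the raw totals are retained on the result.
    """
    if track.medip_total <= 0 or track.mre_total <= 0:
        raise ValueError(
            "cannot normalize a track with zero total reads in either assay"
        )
    f_medip = params.medip_target / track.medip_total
    f_mre = params.mre_target / track.mre_total
    return track.replace_counts(track.medip * f_medip, track.mre * f_mre)


# ---------------------------------------------------------------------------
# Region set I/O (BED3+ dialect)
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> list[GenomicRegion]:
    """Read BED3+ into regions.

    Column 4 (name) is interpreted as the state tag when it matches one of
    ``REGION_STATES``, otherwise it is kept as ``sample_id``. Column 5 is the
    score, column 7 (if present) the sample support count.
    """
    regions: list[GenomicRegion] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} must be < end {end}"
                )
            state, sample_id = "neither", ""
            if len(parts) > 3 and parts[3] != ".":
                if parts[3] in REGION_STATES:
                    state = parts[3]
                else:
                    sample_id = parts[3]
            score = 0.0
            if len(parts) > 4 and parts[4] != ".":
                score = float(parts[4])
            support = 0
            if len(parts) > 6:
                support = int(parts[6])
            regions.append(
                GenomicRegion(
                    chrom=parts[0],
                    start=start,
                    end=end,
                    score=score,
                    sample_id=sample_id,
                    state=state,
                    support=support,
                )
            )
    return regions


def write_regions(
    regions: Sequence[GenomicRegion], path: str | Path, *, support: bool | None = None
) -> None:
    """Write regions as BED6 (name=state, score, strand ``.``).

    A seventh support column is appended when ``support=True`` or (default)
    when any region carries support > 0, so reference sets round-trip.
    """
    if support is None:
        support = any(r.support > 0 for r in regions)
    with open(path, "w", newline="\n") as fh:
        for r in regions:
            row = f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\t{r.score:g}\t."
            if support:
                row += f"\t{r.support}"
            fh.write(row + "\n")
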