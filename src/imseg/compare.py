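"""Methylation-state region calling and chromatin/expression association.

Given a sample's CpG track and a set of candidate regions (typically the
reference IM list), a region is *unmethylated* in that sample when at least
75% of its CpGs individually carry >= 4 MRE reads and zero MeDIP reads, and
*methylated* under the mirror-image rule. Regions passing neither rule keep
state ``neither``. These state sets anchor three downstream comparisons:

* signal profiles — RPKM of a read track (histone ChIP, DNase) in 100 bp
  bins over +/-5 kb around each region centre;
* gene/exon association — regions paired with transcripts whose TSS lies
  within 10 kb (nearest-edge distance) and with exons within 1 kb, feeding
  whole-gene RPKM and relative exon expression R_e / R_t comparisons with a
  two-sided Wilcoxon rank-sum test;
* sample distance matrices (Jaccard on binary IM presence, Canberra on read
  counts) with average-linkage clustering, and CpG-level overlap enrichment
  of two region sets against a permutation null.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core import CpGTrack, GenomicRegion

__all__ = [
    "ExpressionRecord",
    "SignalProfile",
    "OverlapEnrichment",
    "call_state_regions",
    "rpkm",
    "bin_signal_profile",
    "associate_regions_to_genes",
    "associate_regions_to_exons",
    "relative_exon_expression",
    "group_rank_test",
    "sample_distance_matrix",
    "average_linkage",
    "overlap_enrichment",
]


@dataclass
class ExpressionRecord:
    """RPKM of a transcript or exon (exons carry their parent's RPKM too)."""

    feature_id: str
    feature_kind: str  # "transcript" | "exon"
    chrom: str
    start: int
    end: int
    read_count: int
    rpkm: float
    transcript_id: str | None = None
    transcript_rpkm: float | None = None

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError("RPKM must be non-negative")
        if self.feature_kind not in ("transcript", "exon"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")


@dataclass
class SignalProfile:
    """Binned signal matrix around region centres."""

    region_set_label: str
    bin_width: int
    flank: int
    matrix: np.ndarray  # regions x bins, RPKM
    bin_mean: np.ndarray
    bin_sem: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


@dataclass
class OverlapEnrichment:
    """CpG-level overlap of two region sets against a relocation null."""

    observed: int
    expected: float
    fold_enrichment: float
    empirical_p: float
    chi2_stat: float
    chi2_p: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# State calling
# ---------------------------------------------------------------------------

def call_state_regions(
    track: CpGTrack,
    regions: Sequence[GenomicRegion],
    min_reads: float = 4,
    frac_cpgs: float = 0.75,
) -> list[GenomicRegion]:
    """Assign methylated / unmethylated / neither states per region.

    The 75% rule is evaluated per CpG: a CpG supports the unmethylated state
    when it alone has >= ``min_reads`` MRE reads and zero MeDIP reads
    (symmetrically for methylated). Regions containing no track CpGs are
    tagged ``neither`` with a warning. The two per-CpG conditions are
    mutually exclusive, so with ``frac_cpgs > 0.5`` no region can satisfy
    both rules.
    """
    chrom_index: dict[str, slice] = dict(track.iter_chromosomes())
    out: list[GenomicRegion] = []
    for region in regions:
        sl = chrom_index.get(region.chrom)
        state = "neither"
        if sl is not None:
            pos = track.pos[sl]
            lo = int(np.searchsorted(pos, region.start, side="left"))
            hi = int(np.searchsorted(pos, region.end, side="left"))
            if hi > lo:
                m = track.medip[sl][lo:hi]
                r = track.mre[sl][lo:hi]
                frac_unmeth = np.mean((r >= min_reads) & (m == 0))
                frac_meth = np.mean((m >= min_reads) & (r == 0))
                if frac_unmeth >= frac_cpgs:
                    state = "unmethylated"
                elif frac_meth >= frac_cpgs:
                    state = "methylated"
            else:
                warnings.warn(
                    f"region {region.chrom}:{region.start}-{region.end} contains "
                    "no CpGs in the track; state set to 'neither'",
                    stacklevel=2,
                )
        else:
            warnings.warn(
                f"region chromosome {region.chrom!r} absent from track; "
                "state set to 'neither'",
                stacklevel=2,
            )
        out.append(dataclasses.replace(region, state=state))
    return out


# ---------------------------------------------------------------------------
# RPKM and signal profiles
# ---------------------------------------------------------------------------

def rpkm(read_count: float, feature_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_bp <= 0:
        raise ValueError("feature length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return read_count * 1e9 / (feature_length_bp * total_mapped_reads)


def _read_midpoints(
    signal_reads: Sequence[GenomicRegion | tuple],
) -> dict[str, np.ndarray]:
    """Sorted read midpoints per chromosome (interval midpoint, integer bp)."""
    per_chrom: dict[str, list[int]] = {}
    for read in signal_reads:
        if isinstance(read, GenomicRegion):
            chrom, start, end = read.chrom, read.start, read.end
        else:
            chrom, start, end = read[0], int(read[1]), int(read[2])
        per_chrom.setdefault(chrom, []).append((start + end) // 2)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in per_chrom.items()}


def bin_signal_profile(
    regions: Sequence[GenomicRegion],
    signal_reads: Sequence[GenomicRegion | tuple],
    total_mapped_reads: float,
    bin_width: int = 100,
    flank: int = 5000,
    region_set_label: str = "",
) -> SignalProfile:
    """RPKM of a read track in fixed bins around each region centre.

    Bins tile ``[centre - flank, centre + flank)``; each read is assigned to
    the bin containing its midpoint (reads outside the window contribute
    nothing). Per-bin mean and standard error summarize the region set.
    """
    if not regions:
        raise ValueError("need at least one region")
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    mids = _read_midpoints(signal_reads)
    matrix = np.zeros((len(regions), n_bins))
    for i, region in enumerate(regions):
        centre = (region.start + region.end) // 2
        wstart = centre - flank
        chrom_mids = mids.get(region.chrom)
        if chrom_mids is None or not len(chrom_mids):
            continue
        lo = np.searchsorted(chrom_mids, wstart, side="left")
        hi = np.searchsorted(chrom_mids, wstart + 2 * flank, side="left")
        if hi > lo:
            bins = (chrom_mids[lo:hi] - wstart) // bin_width
            counts = np.bincount(bins, minlength=n_bins)
            matrix[i] = counts * 1e9 / (bin_width * total_mapped_reads)
    bin_mean = matrix.mean(axis=0)
    if len(regions) > 1:
        bin_sem = matrix.std(axis=0, ddof=1) / np.sqrt(len(regions))
    else:
        bin_sem = np.zeros(n_bins)
    return SignalProfile(
        region_set_label=region_set_label,
        bin_width=bin_width,
        flank=flank,
        matrix=matrix,
        bin_mean=bin_mean,
        bin_sem=bin_sem,
    )


# ---------------------------------------------------------------------------
# Gene / exon association
# ---------------------------------------------------------------------------

def _point_to_region_distance(region: GenomicRegion, point: int) -> int:
    """bp from a point to the nearest base of a half-open region (0 inside)."""
    return max(region.start - point, point - (region.end - 1), 0)


def _interval_gap(
    a_start: int, a_end: int, b_start: int, b_end: int
) -> int:
    """Gap in bp between two half-open intervals (0 when overlapping)."""
    return max(b_start - a_end, a_start - b_end, 0)


def associate_regions_to_genes(
    regions: Sequence[GenomicRegion],
    tss_table: pd.DataFrame,
    window: int = 10_000,
) -> list[tuple[GenomicRegion, str]]:
    """Pairs (region, transcript_id) with TSS within ``window`` bp.

    ``tss_table`` needs columns ``transcript_id``, ``chrom``, ``tss`` (and
    optionally ``strand``, unused for the distance). Distance is from the
    TSS point to the nearest region edge, 0 when the region overlaps it.
    """
    required = {"transcript_id", "chrom", "tss"}
    if not required.issubset(tss_table.columns):
        raise ValueError(f"tss_table needs columns {sorted(required)}")
    pairs: list[tuple[GenomicRegion, str]] = []
    by_chrom = {c: g for c, g in tss_table.groupby("chrom")}
    for region in regions:
        g = by_chrom.get(region.chrom)
        if g is None:
            continue
        for tx, tss in zip(g["transcript_id"], g["tss"]):
            if _point_to_region_distance(region, int(tss)) <= window:
                pairs.append((region, str(tx)))
    return pairs


def associate_regions_to_exons(
    regions: Sequence[GenomicRegion],
    exon_table: pd.DataFrame,
    window: int = 1_000,
) -> list[tuple[GenomicRegion, str]]:
    """Pairs (region, exon_id) whose interval gap is within ``window`` bp.

    ``exon_table`` needs columns ``exon_id``, ``chrom``, ``start``, ``end``.
    """
    required = {"exon_id", "chrom", "start", "end"}
    if not required.issubset(exon_table.columns):
        raise ValueError(f"exon_table needs columns {sorted(required)}")
    pairs: list[tuple[GenomicRegion, str]] = []
    by_chrom = {c: g for c, g in exon_table.groupby("chrom")}
    for region in regions:
        g = by_chrom.get(region.chrom)
        if g is None:
            continue
        for exon_id, start, end in zip(g["exon_id"], g["start"], g["end"]):
            if _interval_gap(region.start, region.end, int(start), int(end)) <= window:
                pairs.append((region, str(exon_id)))
    return pairs


def relative_exon_expression(r_e: float, r_t: float) -> float:
    """Exon RPKM relative to its parent transcript, R_e / R_t.

    A proxy for exon inclusion: 1 means the exon is expressed at the level
    of its transcript, 0 means it is skipped. Transcripts with zero RPKM are
    excluded upstream (this function raises).
    """
    if r_t <= 0:
        raise ValueError("transcript RPKM must be positive (R_t = 0 is excluded)")
    if r_e < 0:
        raise ValueError("exon RPKM must be non-negative")
    return r_e / r_t


def group_rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P value.

    Exact for combined n <= 20 with no ties, normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


# ---------------------------------------------------------------------------
# Sample distances and overlap enrichment
# ---------------------------------------------------------------------------

def sample_distance_matrix(
    profile_matrix: np.ndarray, metric: str = "jaccard"
) -> np.ndarray:
    """Pairwise sample distances over a samples x features matrix.

    ``jaccard`` (binary presence/absence: 1 - |intersection| / |union|)
    requires a 0/1 matrix; ``canberra`` is sum |x-y| / (|x|+|y|) over
    features with a nonzero denominator.
    """
    m = np.asarray(profile_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("profile matrix must be 2-D (samples x features)")
    if metric == "jaccard":
        if not np.all(np.isin(m, (0.0, 1.0))):
            raise ValueError("jaccard distance requires a binary matrix")
        d = pdist(m.astype(bool), metric="jaccard")
    elif metric == "canberra":
        d = pdist(m, metric="canberra")
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'jaccard' or 'canberra'")
    return squareform(d)


def average_linkage(distance_matrix: np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical clustering of a square distance matrix.

    Returns the scipy linkage matrix.
    """
    return hierarchy.linkage(squareform(distance_matrix, checks=False), method="average")


def _coverage_mask(
    regions: Sequence[tuple[str, int, int]], universe: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Boolean per-universe-CpG coverage by a region set."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        per_chrom.setdefault(chrom, []).append((start, end))
    masks = []
    for chrom in sorted(universe):
        pos = np.asarray(universe[chrom])
        mask = np.zeros(len(pos), dtype=bool)
        ivals = sorted(per_chrom.get(chrom, []))
        # merge, then stab with searchsorted
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if merged:
            starts = np.array([m[0] for m in merged])
            ends = np.array([m[1] for m in merged])
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            mask[ok] = pos[ok] < ends[idx[ok]]
        masks.append(mask)
    return np.concatenate(masks) if masks else np.zeros(0, dtype=bool)


def overlap_enrichment(
    set_a: Sequence[GenomicRegion],
    set_b: Sequence[GenomicRegion],
    cpg_universe: Mapping[str, np.ndarray],
    n_permutations: int = 100,
    seed: int = 0,
) -> OverlapEnrichment:
    """Fold enrichment of CpG-level co-coverage of two region sets.

    The statistic is the number of universe CpGs covered by both sets. The
    null relocates each region of ``set_a`` (length preserved) uniformly
    within its chromosome's universe span; fold enrichment is observed /
    mean(null) and the empirical P is the permutation rank with the +1
    correction. A chi-squared statistic on the 2x2 CpG coverage table
    (in A x in B) is reported alongside.
    """
    if not set_a or not set_b:
        raise ValueError("both region sets must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    universe = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in cpg_universe.items()}
    if not universe or all(len(p) == 0 for p in universe.values()):
        raise ValueError("CpG universe is empty")

    a_tuples = [(r.chrom, r.start, r.end) for r in set_a]
    mask_a = _coverage_mask(a_tuples, universe)
    mask_b = _coverage_mask([(r.chrom, r.start, r.end) for r in set_b], universe)
    observed = int(np.sum(mask_a & mask_b))

    both = observed
    a_only = int(mask_a.sum()) - both
    b_only = int(mask_b.sum()) - both
    neither = len(mask_a) - both - a_only - b_only
    try:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(
            [[both, a_only], [b_only, neither]]
        )
    except ValueError:  # degenerate margins
        chi2_stat, chi2_p = float("nan"), float("nan")

    spans = {
        c: (int(p[0]), int(p[-1]) + 1) for c, p in universe.items() if len(p)
    }
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        relocated: list[tuple[str, int, int]] = []
        for chrom, start, end in a_tuples:
            if chrom not in spans:
                continue
            lo, hi = spans[chrom]
            length = end - start
            max_start = max(hi - length, lo + 1)
            new_start = int(rng.integers(lo, max_start))
            relocated.append((chrom, new_start, new_start + length))
        mask_perm = _coverage_mask(relocated, universe)
        null[k] = np.sum(mask_perm & mask_b)
    expected = float(null.mean())
    fold = observed / expected if expected > 0 else float("inf")
    if expected == 0:
        warnings.warn("null expectation is zero; fold enrichment is infinite", stacklevel=2)
    empirical_p = float((1 + np.sum(null >= observed)) / (n_permutations + 1))
    return OverlapEnrichment(
        observed=observed,
        expected=expected,
        fold_enrichment=fold,
        empirical_p=empirical_p,
        chi2_stat=float(chi2_stat),
        chi2_p=float(chi2_p),
        n_permutations=n_permutations,
        seed=seed,
    )
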