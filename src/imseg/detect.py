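"""Maximal-scoring-segment detection of intermediate methylation (IM) regions.

Intermediate methylation shows up as clusters of CpGs carrying *both*
MeDIP-seq (methylated) and MRE-seq (unmethylated) signal. Each CpG receives a
signed score increment: a reward when the two assays overlap and a penalty
when only one fires, plus a distance penalty between consecutive CpGs:

    delta_i = +w * min(medip_i, mre_i)   if medip_i > 0 and mre_i > 0
              -w * max(medip_i, mre_i)   if exactly one assay is positive
               0                         if both are zero
    gap_i   = lambda * (pos_i - pos_{i-1})       (0 at a chromosome start)

IM calls are the disjoint maximal scoring subsequences of the penalized
sequence ``x_i = delta_i - gap_i`` (Ruzzo & Tompa's linear-time algorithm).
Within a maximal segment the cumulative score peaks at the last CpG, so each
call ends at its highest-scoring position and its score equals the running
maximum.

Score/length cutoffs are calibrated against tracks in which the paired
(medip, mre) count tuples are randomly reassigned to the observed CpG
positions: the least stringent cutoff pair whose estimated false-positive
rate (shuffled passing calls / observed passing calls, averaged over
shuffles) falls below the target is selected.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .core import CpGTrack, DetectionParams, GenomicRegion

__all__ = [
    "ScoreDelta",
    "IMCall",
    "CalibrationResult",
    "score_deltas",
    "find_im_segments",
    "detect_im",
    "shuffle_counts",
    "apply_filters",
    "calibrate_cutoffs",
    "build_reference_set",
]


@dataclass(frozen=True)
class ScoreDelta:
    """Per-CpG signed score increment and inter-CpG distance penalty."""

    pos: int
    delta: float
    gap_penalty: float


@dataclass
class IMCall:
    """One IM segment: a scored region plus its peak CpG bookkeeping."""

    region: GenomicRegion
    max_score: float
    peak_pos: int
    n_cpgs: int

    def __post_init__(self) -> None:
        if self.max_score <= 0:
            raise ValueError("IM call score must be positive")
        if not (self.region.start <= self.peak_pos < self.region.end):
            raise ValueError("peak position must fall inside the call region")


@dataclass
class CalibrationResult:
    """Cutoffs chosen against paired-shuffle null tracks.

    ``fpr_estimate`` is mean(shuffled passing calls) / observed passing calls
    at the chosen cutoffs. ``degenerate`` flags the case where no grid point
    reached the target rate (pure-noise input); the most stringent grid point
    is then reported.
    """

    chosen_min_score: float
    chosen_min_length: int
    fpr_estimate: float
    null_score_dist: np.ndarray
    null_length_dist: np.ndarray
    n_shuffles: int
    seed: int
    degenerate: bool = False
    n_observed_calls: int = 0


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _delta_arrays(
    pos: np.ndarray, medip: np.ndarray, mre: np.ndarray, params: DetectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (delta, gap_penalty) for one chromosome."""
    w = params.overlap_weight
    both = (medip > 0) & (mre > 0)
    either = (medip > 0) | (mre > 0)
    delta = np.where(
        both,
        w * np.minimum(medip, mre),
        np.where(either, -w * np.maximum(medip, mre), 0.0),
    )
    gap = np.empty_like(delta)
    gap[0] = 0.0
    if len(pos) > 1:
        gap[1:] = params.gap_penalty_rate * np.diff(pos)
    return delta, gap


def _check_normalized(track: CpGTrack, params: DetectionParams) -> None:
    medip_sum = float(track.medip.sum())
    mre_sum = float(track.mre.sum())
    ok = np.isclose(medip_sum, params.medip_target, rtol=1e-6) and np.isclose(
        mre_sum, params.mre_target, rtol=1e-6
    )
    if not ok:
        warnings.warn(
            f"track {track.sample_id!r} totals ({medip_sum:g}, {mre_sum:g}) do not "
            f"match normalization targets ({params.medip_target:g}, "
            f"{params.mre_target:g}); scores are on the raw scale",
            stacklevel=3,
        )


def score_deltas(
    track: CpGTrack, params: DetectionParams | None = None
) -> list[ScoreDelta]:
    """Per-CpG score increments for a (normalized) track.

    The gap penalty resets to 0 at each chromosome start. Emits a warning
    (not an error) when assay totals do not match the normalization targets.
    """
    params = params or DetectionParams()
    _check_normalized(track, params)
    out: list[ScoreDelta] = []
    for _, sl in track.iter_chromosomes():
        delta, gap = _delta_arrays(
            track.pos[sl], track.medip[sl], track.mre[sl], params
        )
        out.extend(
            ScoreDelta(int(p), float(d), float(g))
            for p, d, g in zip(track.pos[sl], delta, gap)
        )
    return out


# ---------------------------------------------------------------------------
# Ruzzo–Tompa maximal scoring subsequences
# ---------------------------------------------------------------------------

def _maximal_segments(x: np.ndarray) -> list[tuple[int, int, float]]:
    """All disjoint maximal scoring subsequences of ``x``.

    Returns ``(i, j, score)`` with inclusive indices, sorted by position.
    Linear-time list algorithm: each candidate segment k keeps the cumulative
    totals L_k (before its start) and R_k (at its end); a new positive entry
    merges leftward while it dominates (L_j < L_k and R_j < R_k).
    """
    segs: list[list[float]] = []  # [start, end, L, R]
    cum = 0.0
    for k, v in enumerate(x):
        if v <= 0:
            cum += v
            continue
        cur = [float(k), float(k), cum, cum + v]
        cum += v
        while True:
            j = len(segs) - 1
            while j >= 0 and segs[j][2] >= cur[2]:
                j -= 1
            if j < 0 or segs[j][3] >= cur[3]:
                segs.append(cur)
                break
            cur = [segs[j][0], cur[1], segs[j][2], cur[3]]
            del segs[j:]
    return [(int(s[0]), int(s[1]), s[3] - s[2]) for s in segs]


def find_im_segments(
    deltas: Sequence[ScoreDelta], chrom: str = "chrom", sample_id: str = ""
) -> list[IMCall]:
    """IM calls from an ordered single-chromosome delta sequence.

    Each maximal segment becomes a call: the region runs from its first CpG
    to its peak (= last) CpG + 1, and the score is the segment total, i.e.
    the running-score maximum. Calls are disjoint and sorted.
    """
    if not deltas:
        return []
    pos = np.fromiter((d.pos for d in deltas), dtype=np.int64, count=len(deltas))
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("delta positions must be strictly increasing")
    x = np.fromiter(
        (d.delta - d.gap_penalty for d in deltas), dtype=float, count=len(deltas)
    )
    calls: list[IMCall] = []
    for i, j, score in _maximal_segments(x):
        region = GenomicRegion(
            chrom=chrom,
            start=int(pos[i]),
            end=int(pos[j]) + 1,
            score=score,
            sample_id=sample_id,
            state="IM",
        )
        calls.append(
            IMCall(region=region, max_score=score, peak_pos=int(pos[j]), n_cpgs=j - i + 1)
        )
    return calls


def detect_im(
    track: CpGTrack, params: DetectionParams | None = None, *, quiet: bool = False
) -> list[IMCall]:
    """Run the segmenter across all chromosomes of a track."""
    params = params or DetectionParams()
    if not quiet:
        _check_normalized(track, params)
    calls: list[IMCall] = []
    for chrom, sl in track.iter_chromosomes():
        pos = track.pos[sl]
        delta, gap = _delta_arrays(pos, track.medip[sl], track.mre[sl], params)
        x = delta - gap
        for i, j, score in _maximal_segments(x):
            region = GenomicRegion(
                chrom=chrom,
                start=int(pos[i]),
                end=int(pos[j]) + 1,
                score=score,
                sample_id=track.sample_id,
                state="IM",
            )
            calls.append(
                IMCall(
                    region=region,
                    max_score=score,
                    peak_pos=int(pos[j]),
                    n_cpgs=j - i + 1,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Shuffle null and cutoff calibration
# ---------------------------------------------------------------------------

def shuffle_counts(track: CpGTrack, seed: int) -> CpGTrack:
    """Randomly reassign the paired (medip, mre) tuples to the CpG positions.

    The multiset of count pairs is preserved exactly; only their placement
    changes. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(track))
    return track.replace_counts(track.medip[perm], track.mre[perm])


def apply_filters(
    calls: Sequence[IMCall],
    min_score: float = 8.0,
    min_length: int = 100,
    enforce_length: bool = False,
) -> list[IMCall]:
    """Retain calls with score >= min_score (and length >= min_length when
    ``enforce_length`` is set; by default the length cutoff is deferred to
    the reference-set stage). Order is preserved."""
    out = []
    for c in calls:
        if c.max_score < min_score:
            continue
        if enforce_length and c.region.length < min_length:
            continue
        out.append(c)
    return out


DEFAULT_SCORE_GRID = tuple(np.arange(1.0, 20.0 + 1e-9, 0.5))
DEFAULT_LENGTH_GRID = (0, 100, 200)


def calibrate_cutoffs(
    track: CpGTrack,
    params: DetectionParams | None = None,
    n_shuffles: int = 1000,
    target_fpr: float = 0.01,
    seed: int = 0,
    score_grid: Sequence[float] = DEFAULT_SCORE_GRID,
    length_grid: Sequence[int] = DEFAULT_LENGTH_GRID,
) -> CalibrationResult:
    """Choose (min_score, min_length) against paired-shuffle null tracks.

    Detection runs once on the observed track and once per shuffled track.
    For each grid point the estimated FPR is the mean number of shuffled
    calls passing the cutoffs divided by the number of observed calls
    passing. The least stringent qualifying pair wins, ordering grid points
    by (min_score, min_length) ascending. When no pair qualifies the most
    stringent point is returned with ``degenerate=True``.
    """
    params = params or DetectionParams()
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = detect_im(track, params)
    if not observed:
        raise ValueError("no IM calls on the observed track; FPR is undefined")
    obs_scores = np.array([c.max_score for c in observed])
    obs_lengths = np.array([c.region.length for c in observed])

    rng = np.random.default_rng(seed)
    shuffle_seeds = rng.integers(0, 2**31 - 1, size=n_shuffles)
    null_scores: list[np.ndarray] = []
    null_lengths: list[np.ndarray] = []
    for s in shuffle_seeds:
        calls = detect_im(shuffle_counts(track, int(s)), params, quiet=True)
        null_scores.append(np.array([c.max_score for c in calls]))
        null_lengths.append(np.array([c.region.length for c in calls]))
    null_score_dist = np.concatenate(null_scores) if null_scores else np.empty(0)
    null_length_dist = np.concatenate(null_lengths) if null_lengths else np.empty(0)

    chosen: tuple[float, int] | None = None
    chosen_fpr = np.inf
    for s in sorted(score_grid):
        for l in sorted(length_grid):
            n_obs = int(np.sum((obs_scores >= s) & (obs_lengths >= l)))
            if n_obs == 0:
                continue
            mean_null = (
                np.sum((null_score_dist >= s) & (null_length_dist >= l)) / n_shuffles
            )
            fpr = mean_null / n_obs
            if fpr < target_fpr:
                chosen = (float(s), int(l))
                chosen_fpr = float(fpr)
                break
        if chosen is not None:
            break

    degenerate = chosen is None
    if degenerate:
        s, l = float(max(score_grid)), int(max(length_grid))
        n_obs = int(np.sum((obs_scores >= s) & (obs_lengths >= l)))
        mean_null = (
            np.sum((null_score_dist >= s) & (null_length_dist >= l)) / n_shuffles
        )
        chosen = (s, l)
        chosen_fpr = float(mean_null / n_obs) if n_obs else float("inf")
        warnings.warn(
            "calibration could not reach the target false-positive rate; "
            "returning the most stringent grid point",
            stacklevel=2,
        )

    return CalibrationResult(
        chosen_min_score=chosen[0],
        chosen_min_length=chosen[1],
        fpr_estimate=chosen_fpr,
        null_score_dist=null_score_dist,
        null_length_dist=null_length_dist,
        n_shuffles=n_shuffles,
        seed=seed,
        degenerate=degenerate,
        n_observed_calls=len(observed),
    )


# ---------------------------------------------------------------------------
# Reference set assembly
# ---------------------------------------------------------------------------

def build_reference_set(
    per_sample_calls: Mapping[str, Sequence[IMCall | GenomicRegion]],
    merge_gap: int = 100,
    min_samples: int = 2,
    min_length: int = 100,
) -> list[GenomicRegion]:
    """Merge per-sample IM calls into a multi-sample reference list.

    Calls from all samples are pooled and transitively merged whenever the
    gap between two is <= ``merge_gap``; each merged cluster's ``support`` is
    the number of distinct samples contributing at least one call. Clusters
    need ``support >= min_samples`` and ``length >= min_length`` to be kept.

    Regions that already carry a support count (a previously assembled
    reference set) contribute that count instead of a single sample, which
    makes re-assembly of a reference set idempotent.
    """
    items: list[tuple[str, int, int, float, str, int]] = []
    for sample, calls in per_sample_calls.items():
        for c in calls:
            region = c.region if isinstance(c, IMCall) else c
            items.append(
                (
                    region.chrom,
                    region.start,
                    region.end,
                    float(region.score),
                    sample,
                    int(region.support),
                )
            )
    items.sort(key=lambda t: (t[0], t[1], t[2]))

    out: list[GenomicRegion] = []
    cluster: list[tuple[str, int, int, float, str, int]] = []

    def _flush() -> None:
        if not cluster:
            return
        start = min(t[1] for t in cluster)
        end = max(t[2] for t in cluster)
        score = max(t[3] for t in cluster)
        named = {t[4] for t in cluster if t[5] == 0}
        carried = sum(t[5] for t in cluster if t[5] > 0)
        support = len(named) + carried
        if support >= min_samples and (end - start) >= min_length:
            out.append(
                GenomicRegion(
                    chrom=cluster[0][0],
                    start=start,
                    end=end,
                    score=score,
                    state="IM",
                    support=support,
                )
            )

    cur_chrom: str | None = None
    cur_end = -np.inf
    for item in items:
        chrom, start, end = item[0], item[1], item[2]
        if chrom != cur_chrom or start - cur_end > merge_gap:
            _flush()
            cluster = [item]
            cur_chrom = chrom
            cur_end = end
        else:
            cluster.append(item)
            cur_end = max(cur_end, end)
    _flush()
    return out
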