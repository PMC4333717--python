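"""Seeded generators of synthetic methylomes with planted ground truth.

The generator emulates the structure the detection pipeline is built for: a
chromosome of clustered CpG positions where planted regions are fully
methylated (high MeDIP, near-zero MRE), fully unmethylated (the reverse) or
intermediately methylated (moderate counts in both assays). The background
between planted regions mirrors the bimodal bulk methylome: most background
CpGs are fully methylated, a minority fully unmethylated, and a small rest
carry essentially no signal. Read counts are independent Poisson draws with
state-specific per-assay means; counts are generated on the normalized
read-density scale, so detection runs with the normalization targets set to
the track totals. Allelic tables draw binomial read-allele counts under an
ASM scheme (assays segregate alleles, allele purity < 1) or an AIM scheme
(both assays 50/50), and expression tables place one transcript and one exon
near each planted region with state-dependent expression and exon-inclusion
distributions.

All draws flow from ``SimulationConfig.seed`` through independent named
streams, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .allelic import AllelicCounts
from .core import CpGTrack, GenomicRegion
from .detect import IMCall

__all__ = [
    "DEFAULT_RATES",
    "SimulationConfig",
    "TrueSNP",
    "TruthSet",
    "RecoveryResult",
    "default_benchmark_config",
    "simulate_genome",
    "simulate_counts",
    "simulate_allelic",
    "simulate_expression",
    "evaluate_recovery",
]

#: Poisson read-density means per (MeDIP, MRE) assay for each planted state.
DEFAULT_RATES: dict[str, tuple[float, float]] = {
    "IM": (4.0, 4.0),
    "M": (8.0, 0.1),
    "U": (0.1, 8.0),
}

_STATE_TAG = {"IM": "IM", "M": "methylated", "U": "unmethylated"}

# Expression model defaults: whole-transcript RPKM is log-normal with a
# state-dependent log-mean (unmethylated > IM > methylated), while relative
# exon inclusion is Beta with the reverse ordering (methylated exons are the
# most included).
_EXPR_LOG_MEAN = {"U": np.log(30.0), "IM": np.log(10.0), "M": np.log(3.0)}
_EXPR_LOG_SD = 0.8
_INCLUSION_BETA = {"M": (9.0, 1.0), "IM": (6.0, 4.0), "U": (3.0, 7.0)}


@dataclass
class SimulationConfig:
    """Planted-genome layout, rate model and seed.

    region_plan
        Ordered ``(state, n_cpgs)`` tuples, state in {"M", "U", "IM"}.
    mean_gap_region / mean_gap_background
        Mean inter-CpG spacing (geometric, bp) inside planted regions and in
        the background between them. Region CpGs are denser, mimicking the
        CpG clustering of real IM loci.
    background_cpgs_between
        Background CpGs inserted before, between and after planted regions
        (ignored when ``n_cpgs`` fixes the total).
    background_meth_frac / background_unmeth_frac
        Mixture weights of the bimodal background: each background CpG is
        fully methylated / fully unmethylated (drawing from the M / U rate
        pairs) with these probabilities, and otherwise silent at
        ``background_rate``.
    n_cpgs
        Optional total CpG count; background CpGs are then distributed
        evenly around the planted regions. Errors if the plan needs more
        CpGs than this.
    allelic_plan
        ``(scheme, n_snps, coverage)`` tuples, scheme in {"ASM", "AIM"},
        assigned in order to the planted IM regions.
    """

    region_plan: Sequence[tuple[str, int]]
    seed: int
    chrom: str = "chr1"
    start_pos: int = 1000
    mean_gap_region: float = 40.0
    mean_gap_background: float = 120.0
    background_cpgs_between: int = 20
    n_cpgs: int | None = None
    rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    background_rate: tuple[float, float] = (0.1, 0.1)
    background_meth_frac: float = 0.70
    background_unmeth_frac: float = 0.25
    allelic_plan: Sequence[tuple[str, int, int]] = ()
    allele_purity: float = 0.95

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        for state, n in self.region_plan:
            if state not in ("M", "U", "IM"):
                raise ValueError(f"unknown planted state {state!r}")
            if n < 1:
                raise ValueError("each planted region needs >= 1 CpG")
        for rate_pair in list(self.rates.values()) + [self.background_rate]:
            if min(rate_pair) < 0:
                raise ValueError("Poisson rates must be >= 0")
        if not 0.5 < self.allele_purity <= 1.0:
            raise ValueError("allele purity must be in (0.5, 1]")
        if not (
            0 <= self.background_meth_frac
            and 0 <= self.background_unmeth_frac
            and self.background_meth_frac + self.background_unmeth_frac <= 1
        ):
            raise ValueError("background mixture weights must sum to <= 1")
        n_region = sum(n for _, n in self.region_plan)
        if self.n_cpgs is not None and n_region > self.n_cpgs:
            raise ValueError(
                f"region plan needs {n_region} CpGs but n_cpgs={self.n_cpgs}"
            )
        n_im = sum(s == "IM" for s, _ in self.region_plan)
        if len(self.allelic_plan) > n_im:
            raise ValueError("more allelic plan entries than planted IM regions")
        for scheme, n_snps, cov in self.allelic_plan:
            if scheme not in ("ASM", "AIM"):
                raise ValueError(f"unknown allelic scheme {scheme!r}")
            if n_snps < 0 or cov < 0:
                raise ValueError("n_snps and coverage must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one named stream."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass(frozen=True)
class TrueSNP:
    snp_id: str
    chrom: str
    pos: int
    scheme: str  # "ASM" | "AIM"
    coverage: int


@dataclass
class TruthSet:
    """Planted genome: CpG positions, true region spans, true SNP classes."""

    chrom: str
    positions: np.ndarray
    cpg_states: np.ndarray  # per-CpG plan state: "background", "M", "U", "IM"
    regions: list[GenomicRegion]
    snps: list[TrueSNP]

    def im_regions(self) -> list[GenomicRegion]:
        return [r for r in self.regions if r.state == "IM"]


def default_benchmark_config(
    seed: int,
    n_im: int = 50,
    n_m: int = 50,
    n_u: int = 50,
    cpgs_per_region: int = 10,
    **kwargs,
) -> SimulationConfig:
    """Study-default planted genome: 50 IM regions among 100 M/U regions.

    Regions carry 10 CpGs each (~350 bp at the default spacing, the scale of
    typical IM loci), laid out in a seeded random order.
    """
    plan = ["IM"] * n_im + ["M"] * n_m + ["U"] * n_u
    order = np.random.default_rng(np.random.SeedSequence((seed, 99))).permutation(
        len(plan)
    )
    region_plan = tuple((plan[i], cpgs_per_region) for i in order)
    return SimulationConfig(region_plan=region_plan, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Genome and counts
# ---------------------------------------------------------------------------

def _gaps(rng: np.random.Generator, n: int, mean_gap: float) -> np.ndarray:
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    return rng.geometric(1.0 / mean_gap, size=n).astype(np.int64)


def simulate_genome(config: SimulationConfig) -> TruthSet:
    """Lay out CpG positions and planted region spans (deterministic in seed)."""
    rng = config.rng(0)
    n_regions = len(config.region_plan)
    n_region_cpgs = sum(n for _, n in config.region_plan)
    if config.n_cpgs is not None:
        n_bg_total = config.n_cpgs - n_region_cpgs
        blocks = np.full(n_regions + 1, n_bg_total // (n_regions + 1), dtype=int)
        blocks[: n_bg_total % (n_regions + 1)] += 1
    else:
        blocks = np.full(n_regions + 1, config.background_cpgs_between, dtype=int)

    positions: list[int] = []
    states: list[str] = []
    regions: list[GenomicRegion] = []
    pos = config.start_pos

    def _advance(n: int, mean_gap: float, state: str) -> tuple[int, int]:
        nonlocal pos
        first = None
        for g in _gaps(rng, n, mean_gap):
            pos += int(g)
            if first is None:
                first = pos
            positions.append(pos)
            states.append(state)
        return first if first is not None else pos, pos

    for i, (state, n) in enumerate(config.region_plan):
        _advance(blocks[i], config.mean_gap_background, "background")
        first, last = _advance(n, config.mean_gap_region, state)
        regions.append(
            GenomicRegion(
                chrom=config.chrom,
                start=first,
                end=last + 1,
                state=_STATE_TAG[state],
            )
        )
    _advance(blocks[n_regions], config.mean_gap_background, "background")

    # Bimodal background: most CpGs fully methylated, a minority fully
    # unmethylated, the rest silent.
    state_arr = np.array(states, dtype=object)
    bg = np.flatnonzero(state_arr == "background")
    if len(bg):
        u = rng.random(len(bg))
        state_arr[bg[u < config.background_meth_frac]] = "background_M"
        state_arr[
            bg[
                (u >= config.background_meth_frac)
                & (u < config.background_meth_frac + config.background_unmeth_frac)
            ]
        ] = "background_U"
    states = list(state_arr)

    # SNP placement inside planted IM regions, one plan entry per region.
    snps: list[TrueSNP] = []
    im_regions = [r for r in regions if r.state == "IM"]
    snp_i = 0
    for (scheme, n_snps, coverage), region in zip(config.allelic_plan, im_regions):
        span = np.arange(region.start, region.end)
        k = min(n_snps, len(span))
        for p in sorted(rng.choice(span, size=k, replace=False)):
            snps.append(
                TrueSNP(
                    snp_id=f"snp{snp_i}",
                    chrom=config.chrom,
                    pos=int(p),
                    scheme=scheme,
                    coverage=coverage,
                )
            )
            snp_i += 1

    return TruthSet(
        chrom=config.chrom,
        positions=np.array(positions, dtype=np.int64),
        cpg_states=np.array(states, dtype=object),
        regions=regions,
        snps=snps,
    )


def simulate_counts(truth: TruthSet, config: SimulationConfig) -> CpGTrack:
    """Poisson per-CpG MeDIP/MRE counts with state-dependent means."""
    rng = config.rng(1)
    n = len(truth.positions)
    medip_rate = np.empty(n)
    mre_rate = np.empty(n)
    rates = dict(config.rates)
    rates["background"] = config.background_rate
    rates["background_M"] = config.rates["M"]
    rates["background_U"] = config.rates["U"]
    for state, (m_rate, r_rate) in rates.items():
        mask = truth.cpg_states == state
        medip_rate[mask] = m_rate
        mre_rate[mask] = r_rate
    medip = rng.poisson(medip_rate).astype(float)
    mre = rng.poisson(mre_rate).astype(float)
    return CpGTrack.from_arrays(
        sample_id=f"sim_{config.seed}",
        chrom=np.full(n, truth.chrom, dtype=object),
        pos=truth.positions,
        medip=medip,
        mre=mre,
    )


# ---------------------------------------------------------------------------
# Allelic and expression tables
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_allelic(truth: TruthSet, config: SimulationConfig) -> list[AllelicCounts]:
    """Binomial allele x assay read draws for the planted SNPs.

    ASM: MeDIP reads favour one allele and MRE the other, each at the
    configured purity (default 0.95); which allele is methylated is random.
    AIM: both assays draw alleles 50/50. SNPs with zero coverage yield no
    record (nothing to classify downstream).
    """
    rng = config.rng(2)
    out: list[AllelicCounts] = []
    for snp in truth.snps:
        cov = snp.coverage
        if cov == 0:
            continue
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        if snp.scheme == "ASM":
            methylated_is_ref = bool(rng.random() < 0.5)
            p_medip_ref = config.allele_purity if methylated_is_ref else 1 - config.allele_purity
            medip_ref = int(rng.binomial(cov, p_medip_ref))
            mre_ref = int(rng.binomial(cov, 1 - p_medip_ref))
        else:  # AIM
            medip_ref = int(rng.binomial(cov, 0.5))
            mre_ref = int(rng.binomial(cov, 0.5))
        out.append(
            AllelicCounts(
                snp_id=snp.snp_id,
                chrom=snp.chrom,
                pos=snp.pos,
                ref_allele=str(ref),
                alt_allele=str(alt),
                medip_ref=medip_ref,
                medip_alt=cov - medip_ref,
                mre_ref=mre_ref,
                mre_alt=cov - mre_ref,
            )
        )
    return out


def simulate_expression(
    truth: TruthSet, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One transcript and one exon per planted region, expression by state.

    Returns ``(tss_table, exon_table)``. The TSS sits within 10 kb of its
    region and the exon overlaps it, so the standard association windows
    recover the pairing. Transcript RPKM is log-normal with log-mean ordered
    unmethylated > IM > methylated; exon RPKM is ``inclusion * transcript
    RPKM`` with Beta-distributed inclusion ordered methylated > IM >
    unmethylated.
    """
    rng = config.rng(3)
    plan_states = [s for s, _ in config.region_plan]
    genes = []
    exons = []
    for i, (region, state) in enumerate(zip(truth.regions, plan_states)):
        tss = max(0, region.start - int(rng.integers(0, 5000)))
        r_t = float(rng.lognormal(_EXPR_LOG_MEAN[state], _EXPR_LOG_SD))
        a, b = _INCLUSION_BETA[state]
        inclusion = float(rng.beta(a, b))
        genes.append(
            {
                "transcript_id": f"tx{i}",
                "chrom": region.chrom,
                "strand": "+",
                "tss": tss,
                "rpkm": r_t,
                "true_state": region.state,
            }
        )
        exons.append(
            {
                "exon_id": f"tx{i}_e1",
                "transcript_id": f"tx{i}",
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "rpkm_exon": inclusion * r_t,
                "rpkm_transcript": r_t,
                "true_state": region.state,
            }
        )
    return pd.DataFrame(genes), pd.DataFrame(exons)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    precision: float
    recall: float
    median_boundary_error: float
    n_true: int
    n_calls: int
    n_matched: int


def _overlap(a: GenomicRegion, b: GenomicRegion) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def evaluate_recovery(
    calls: Sequence[IMCall | GenomicRegion],
    truth: TruthSet,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryResult:
    """Precision/recall of IM calls against the planted IM regions.

    A call matches a true IM region when their reciprocal overlap is at
    least ``min_reciprocal_overlap`` (50% by default, the usual DMR
    benchmarking criterion); matching is one-to-one, greedy by overlap.
    Boundary error per matched pair is the mean of the start and end edge
    offsets in bp; the median over pairs is reported. With no calls the
    recall is 0 and precision NaN (flagged with a warning).
    """
    call_regions = [c.region if isinstance(c, IMCall) else c for c in calls]
    true_im = truth.im_regions()
    if not call_regions:
        if true_im:
            warnings.warn("no calls: precision is undefined", stacklevel=2)
        return RecoveryResult(
            precision=float("nan"),
            recall=0.0 if true_im else float("nan"),
            median_boundary_error=float("nan"),
            n_true=len(true_im),
            n_calls=0,
            n_matched=0,
        )
    candidates = []
    for i, call in enumerate(call_regions):
        for j, t in enumerate(true_im):
            ov = _overlap(call, t)
            if ov / call.length >= min_reciprocal_overlap and ov / t.length >= min_reciprocal_overlap:
                candidates.append((ov, i, j))
    candidates.sort(reverse=True)
    used_calls: set[int] = set()
    used_true: set[int] = set()
    boundary_errors: list[float] = []
    for ov, i, j in candidates:
        if i in used_calls or j in used_true:
            continue
        used_calls.add(i)
        used_true.add(j)
        call, t = call_regions[i], true_im[j]
        boundary_errors.append(
            (abs(call.start - t.start) + abs(call.end - t.end)) / 2
        )
    n_matched = len(used_true)
    return RecoveryResult(
        precision=len(used_calls) / len(call_regions),
        recall=n_matched / len(true_im) if true_im else float("nan"),
        median_boundary_error=float(np.median(boundary_errors))
        if boundary_errors
        else float("nan"),
        n_true=len(true_im),
        n_calls=len(call_regions),
        n_matched=n_matched,
    )
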