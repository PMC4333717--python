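"""Allele-specific vs allele-independent methylation calls at heterozygous SNPs.

At a heterozygous SNP inside an intermediate-methylation region, reads from
the two assays can segregate the alleles (allele-specific methylation, ASM:
MeDIP reads carry one allele, MRE reads the other) or sample both alleles
evenly (allele-independent methylation, AIM). Classification works from the
2x2 assay x allele read-count table:

                 ref   alt
        MeDIP     a     b
        MRE       c     d

Heterozygosity requires a minimum coverage of 9 reads in each assay, at most
100 MRE reads (PCR-bias guard), and each allele reaching at least 30% of the
reads of MeDIP or of MRE. ASM requires >=75% of MeDIP reads on one allele,
>=75% of MRE reads on the other, and a significant cross-assay skew
(two-sided Fisher's exact P < 0.01). AIM requires both assays' major-allele
fractions <= 70% and no significant skew (P > 0.01). The 70%/75% gap and the
opposing P cutoffs make ASM and AIM mutually exclusive by construction.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicRegion

__all__ = [
    "AllelicCounts",
    "AllelicParams",
    "SNPClassification",
    "RegionAllelicCall",
    "call_heterozygous",
    "fisher_exact_2x2",
    "classify_snp",
    "classify_region",
    "allelic_preference_correlation",
    "read_allelic_counts",
    "write_snp_classifications",
]

STATUS_NOT_HET = "not_het"
STATUS_HET_UNCLASSIFIED = "het_unclassified"
STATUS_ASM = "ASM"
STATUS_AIM = "AIM"

VERDICT_AMBIGUOUS = "ambiguous_ignored"
VERDICT_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class AllelicCounts:
    """Per-SNP allele x assay read counts."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    medip_ref: int
    medip_alt: int
    mre_ref: int
    mre_alt: int

    def __post_init__(self) -> None:
        if min(self.medip_ref, self.medip_alt, self.mre_ref, self.mre_alt) < 0:
            raise ValueError("allelic read counts must be non-negative")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def medip_total(self) -> int:
        return self.medip_ref + self.medip_alt

    @property
    def mre_total(self) -> int:
        return self.mre_ref + self.mre_alt


@dataclass
class AllelicParams:
    """Thresholds for heterozygosity and ASM/AIM classification."""

    min_cov: int = 9
    mre_max_cov: int = 100
    het_min_frac: float = 0.30
    asm_min_frac: float = 0.75
    aim_max_frac: float = 0.70
    alpha: float = 0.01
    region_min_snps: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.het_min_frac < 0.5 < self.aim_max_frac < self.asm_min_frac < 1):
            raise ValueError(
                "expected 0 < het_min_frac < 0.5 < aim_max_frac < asm_min_frac < 1"
            )
        if self.min_cov < 1 or self.mre_max_cov < self.min_cov:
            raise ValueError("invalid coverage bounds")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SNPClassification:
    """ASM/AIM verdict for one SNP."""

    snp_id: str
    chrom: str
    pos: int
    status: str
    fisher_p: float
    medip_major_frac: float
    mre_major_frac: float


@dataclass
class RegionAllelicCall:
    """Region-level verdict from the SNPs it contains."""

    region: GenomicRegion
    n_asm: int
    n_aim: int
    verdict: str


def call_heterozygous(c: AllelicCounts, p: AllelicParams | None = None) -> bool:
    """True when the SNP passes coverage bounds and both alleles are seen.

    Each allele must be represented in at least ``het_min_frac`` of MeDIP
    reads or of MRE reads (the two alleles may qualify through different
    assays — at an ASM locus each assay is nearly allele-pure).
    """
    p = p or AllelicParams()
    if c.medip_total < p.min_cov or c.mre_total < p.min_cov:
        return False
    if c.mre_total > p.mre_max_cov:
        return False
    for a_medip, a_mre in ((c.medip_ref, c.mre_ref), (c.medip_alt, c.mre_alt)):
        seen = (
            a_medip / c.medip_total >= p.het_min_frac
            or a_mre / c.mre_total >= p.het_min_frac
        )
        if not seen:
            return False
    return True


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact P for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins
    that are at most as probable as the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table has no defined P value")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def classify_snp(c: AllelicCounts, p: AllelicParams | None = None) -> SNPClassification:
    """Classify one SNP as not_het / het_unclassified / ASM / AIM."""
    p = p or AllelicParams()
    medip_major = max(c.medip_ref, c.medip_alt) / c.medip_total if c.medip_total else float("nan")
    mre_major = max(c.mre_ref, c.mre_alt) / c.mre_total if c.mre_total else float("nan")
    if c.medip_total + c.mre_total > 0:
        fisher_p = fisher_exact_2x2(c.medip_ref, c.medip_alt, c.mre_ref, c.mre_alt)
    else:
        fisher_p = float("nan")
    base = dict(
        snp_id=c.snp_id,
        chrom=c.chrom,
        pos=c.pos,
        fisher_p=fisher_p,
        medip_major_frac=medip_major,
        mre_major_frac=mre_major,
    )
    if not call_heterozygous(c, p):
        return SNPClassification(status=STATUS_NOT_HET, **base)

    # Allele the MeDIP assay favours (ties count as fraction 0.5, never ASM).
    medip_major_is_ref = c.medip_ref >= c.medip_alt
    mre_opposite_frac = (
        (c.mre_alt if medip_major_is_ref else c.mre_ref) / c.mre_total
    )
    if (
        medip_major >= p.asm_min_frac
        and mre_opposite_frac >= p.asm_min_frac
        and fisher_p < p.alpha
    ):
        return SNPClassification(status=STATUS_ASM, **base)
    if medip_major <= p.aim_max_frac and mre_major <= p.aim_max_frac and fisher_p > p.alpha:
        return SNPClassification(status=STATUS_AIM, **base)
    return SNPClassification(status=STATUS_HET_UNCLASSIFIED, **base)


def classify_region(
    region: GenomicRegion,
    snps: Sequence[SNPClassification],
    p: AllelicParams | None = None,
) -> RegionAllelicCall:
    """Region verdict: ASM needs >= ``region_min_snps`` ASM SNPs and no AIM
    SNPs (and symmetrically for AIM); regions with both kinds are ignored."""
    p = p or AllelicParams()
    for s in snps:
        if s.chrom != region.chrom or not (region.start <= s.pos < region.end):
            raise ValueError(
                f"SNP {s.snp_id} at {s.chrom}:{s.pos} lies outside region "
                f"{region.chrom}:{region.start}-{region.end}"
            )
    n_asm = sum(s.status == STATUS_ASM for s in snps)
    n_aim = sum(s.status == STATUS_AIM for s in snps)
    if n_asm > 0 and n_aim > 0:
        verdict = VERDICT_AMBIGUOUS
    elif n_asm >= p.region_min_snps:
        verdict = STATUS_ASM
    elif n_aim >= p.region_min_snps:
        verdict = STATUS_AIM
    else:
        verdict = VERDICT_UNCLASSIFIED
    return RegionAllelicCall(region=region, n_asm=n_asm, n_aim=n_aim, verdict=verdict)


def allelic_preference_correlation(
    snp_skews_a: Mapping[str, float], snp_skews_b: Mapping[str, float]
) -> float:
    """Pearson correlation of reference-allele read fractions at shared SNPs.

    Positive values mean the two signals sit on the same allele. Returns NaN
    (with a warning) when either signal has zero variance across the shared
    SNPs; requires at least 3 shared SNPs.
    """
    shared = sorted(set(snp_skews_a) & set(snp_skews_b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared SNPs, got {len(shared)}")
    a = np.array([snp_skews_a[k] for k in shared], dtype=float)
    b = np.array([snp_skews_b[k] for k in shared], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            "allelic preference correlation undefined: zero variance in a signal",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_SNP_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "medip_ref",
    "medip_alt",
    "mre_ref",
    "mre_alt",
]


def read_allelic_counts(path: str | Path) -> list[AllelicCounts]:
    """Read the 9-column SNP table (header optional)."""
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    has_header = first.split()[:1] == ["snp_id"]
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=0 if has_header else None,
        names=None if has_header else _SNP_COLUMNS,
        comment="#",
    )
    missing = set(_SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return [
        AllelicCounts(
            snp_id=str(r.snp_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            medip_ref=int(r.medip_ref),
            medip_alt=int(r.medip_alt),
            mre_ref=int(r.mre_ref),
            mre_alt=int(r.mre_alt),
        )
        for r in df.itertuples(index=False)
    ]


def write_snp_classifications(
    counts: Sequence[AllelicCounts],
    classifications: Sequence[SNPClassification],
    path: str | Path,
) -> None:
    """Write the input table plus ``status`` and ``fisher_p`` columns."""
    rows = []
    for c, s in zip(counts, classifications):
        rows.append(
            {
                "snp_id": c.snp_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "medip_ref": c.medip_ref,
                "medip_alt": c.medip_alt,
                "mre_ref": c.mre_ref,
                "mre_alt": c.mre_alt,
                "status": s.status,
                "fisher_p": s.fisher_p,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
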