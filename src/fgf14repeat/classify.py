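"""Allele and individual classification.

Converts allele calls into configuration classes (pure expansion vs
complex configuration split at a 100-unit embedded run), penetrance bands
(>=300 full, 250-299 incomplete, 200-249 uncertain, below otherwise),
rule-based repeat-primed-PCR (RP-PCR) outcome predictions, and SNP
genotypes, then aggregates everything into one call per individual.

The RP-PCR thresholds are inferred brackets, not measured values: the
largest published run with a negative trace is 83 units, inconclusive
traces accompany runs of 134-167, and the smallest pure expansion with a
positive trace is 191 units.  All thresholds are configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .extraction import AnchoredRead
from .locus import LocusTemplate
from .profiling import (
    AlleleCall,
    TractProfile,
    cluster_alleles,
    profile_read,
    select_uniform_region,
)


class ConfigClass(str, Enum):
    PURE = "PURE"
    COMPLEX_RUN_GE100 = "COMPLEX_RUN_GE100"
    COMPLEX_RUN_LT100 = "COMPLEX_RUN_LT100"


class Band(str, Enum):
    FULL = "FULL"
    INCOMPLETE = "INCOMPLETE"
    UNCERTAIN = "UNCERTAIN"
    BELOW = "BELOW"


#: RP-PCR outcomes, best-first.
RP_ORDER = ("positive", "inconclusive", "negative")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Unit-count and purity thresholds used by every classifier."""

    full_penetrance_min: int = 300
    incomplete_min: int = 250
    uncertain_min: int = 200
    complex_run_split: int = 100
    purity_min_for_pure: float = 0.95
    rp_positive_min_run: int = 191
    rp_inconclusive_min_run: int = 100
    gel_bp: int = 750

    def __post_init__(self) -> None:
        if not (
            self.full_penetrance_min
            > self.incomplete_min
            > self.uncertain_min
            > self.complex_run_split
            > 0
        ):
            raise ValueError("penetrance/complex thresholds must be decreasing")
        if not 0 < self.purity_min_for_pure <= 1:
            raise ValueError("purity_min_for_pure must be in (0, 1]")


def classify_configuration(
    allele: AlleleCall, thresholds: ClassificationThresholds
) -> ConfigClass:
    """Pure expansion vs complex configuration (split by embedded run)."""
    if allele.purity >= thresholds.purity_min_for_pure:
        return ConfigClass.PURE
    if allele.longest_run_units >= thresholds.complex_run_split:
        return ConfigClass.COMPLEX_RUN_GE100
    return ConfigClass.COMPLEX_RUN_LT100


def penetrance_band(
    unit_count: float, thresholds: ClassificationThresholds
) -> Band:
    """Penetrance band of a unit count (inclusive integer bands)."""
    if unit_count < 0:
        raise ValueError(f"unit count must be >= 0, got {unit_count}")
    if unit_count >= thresholds.full_penetrance_min:
        return Band.FULL
    if unit_count >= thresholds.incomplete_min:
        return Band.INCOMPLETE
    if unit_count >= thresholds.uncertain_min:
        return Band.UNCERTAIN
    return Band.BELOW


def _rp_score(allele: AlleleCall, thresholds: ClassificationThresholds) -> float:
    """Length of contiguous GAA available to the RP-PCR primer."""
    score = allele.longest_run_units
    if classify_configuration(allele, thresholds) is ConfigClass.PURE:
        score = max(score, allele.unit_count_median)
    return score


def predict_rp_pcr(
    alleles: list[AlleleCall], thresholds: ClassificationThresholds
) -> str:
    """Rule-based RP-PCR outcome for an individual (best across alleles)."""
    if not alleles:
        raise ValueError("predict_rp_pcr needs at least one allele")
    best = "negative"
    for allele in alleles:
        score = _rp_score(allele, thresholds)
        if score >= thresholds.rp_positive_min_run:
            return "positive"
        if score >= thresholds.rp_inconclusive_min_run:
            best = "inconclusive"
    return best


def genotype_snp_base(
    reads: list[AnchoredRead],
    template: LocusTemplate,
    min_coverage: int = 3,
    min_majority: float = 0.8,
) -> str:
    """Majority SNP base over one allele's reads, or "unknown".

    The SNP is located by its offset from the leftmost upstream anchor
    match (anchor-relative, no global alignment).  Reads that do not cover
    the site are skipped; "unknown" when coverage < ``min_coverage`` or the
    majority base falls below ``min_majority``.
    """
    offsets = template.up_anchor_offsets
    votes: Counter = Counter()
    for read in reads:
        if not read.up_anchor_hits:
            continue
        anchor_idx, pos = min(read.up_anchor_hits, key=lambda h: h[1])
        site = pos + (template.snp_offset - offsets[anchor_idx - 1])
        if 0 <= site < len(read.sequence):
            votes[read.sequence[site]] += 1
    total = sum(votes.values())
    if total < min_coverage:
        return "unknown"
    base, count = votes.most_common(1)[0]
    if count / total < min_majority:
        return "unknown"
    return base


def combine_snp_genotype(allele_bases: list[str]) -> str:
    """Diploid genotype string from per-allele majority bases.

    With a single visible allele (e.g. the short allele was not amplified)
    the genotype is reported as homozygous for the observed base.
    """
    known = [b for b in allele_bases if b in ("T", "A")]
    if not known or len(known) < len(allele_bases):
        return "unknown"
    if len(known) == 1:
        known = known * 2
    return "/".join(sorted(known, reverse=True))  # T before A


@dataclass
class AlleleSummary:
    """One allele of an individual call, with its classification."""

    call: AlleleCall
    configuration_class: ConfigClass
    band: Band
    snp_base: str


@dataclass
class IndividualCall:
    """Per-sample diploid call."""

    sample_id: str
    group: str
    alleles: list[AlleleSummary]
    rp_pcr_prediction: str
    snp_genotype: str
    flags: list[str] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)


def call_individual(
    sample_id: str,
    reads: list[tuple[str, str]],
    template: LocusTemplate,
    thresholds: ClassificationThresholds | None = None,
    group: str = "",
    max_mismatches: int = 0,
    min_reads: int = 3,
    split_gap_units: int = 10,
) -> IndividualCall:
    """Extraction -> profiling -> selection -> clustering -> classification.

    Deterministic composition of the per-read stages; emits one call per
    sample.  With no accepted locus reads the call carries no alleles and
    the ``no_locus_reads`` flag.
    """
    from .extraction import extract_repeat_reads

    if thresholds is None:
        thresholds = ClassificationThresholds()
    anchored, summary = extract_repeat_reads(reads, template, max_mismatches)
    by_id = {a.read_id: a for a in anchored}
    profiles: list[TractProfile] = []
    unsized = 0
    for a in anchored:
        prof, _reason = profile_read(a, template)
        if prof is None:
            unsized += 1
        else:
            profiles.append(prof)
    selected, n_discarded = select_uniform_region(profiles, min_reads=min_reads)
    calls, n_dropped = cluster_alleles(
        selected, split_gap_units=split_gap_units, min_reads=min_reads
    )
    flags: list[str] = []
    if not anchored:
        flags.append("no_locus_reads")
    elif not calls:
        flags.append("no_allele_call")
    if n_dropped:
        flags.append("low_coverage_cluster_dropped")
    summaries: list[AlleleSummary] = []
    for call in calls:
        call.snp_base = genotype_snp_base(
            [by_id[rid] for rid in call.read_ids if rid in by_id], template
        )
        summaries.append(
            AlleleSummary(
                call=call,
                configuration_class=classify_configuration(call, thresholds),
                band=penetrance_band(call.unit_count_median, thresholds),
                snp_base=call.snp_base,
            )
        )
    rp = predict_rp_pcr(calls, thresholds) if calls else "negative"
    genotype = (
        combine_snp_genotype([s.snp_base for s in summaries])
        if summaries
        else "unknown"
    )
    return IndividualCall(
        sample_id=sample_id,
        group=group,
        alleles=summaries,
        rp_pcr_prediction=rp,
        snp_genotype=genotype,
        flags=flags,
        stage_counts={
            "reads_in": len(reads),
            "accepted": len(anchored),
            "sized": len(profiles),
            "unsized": unsized,
            "selected": len(selected),
            "discarded_by_selection": n_discarded,
            "alleles": len(calls),
        },
    )
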