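"""Named allele configurations and cohort presets.

The constructors here define the study conditions used throughout the test
suite and examples: a wild-type short allele, pure (GAA)N expansions, and
complex configurations with pure-GAA runs at both tract ends separated by a
GCAGAA interruption region.  The cohort preset mirrors the published
per-category counts for the three study groups (undiagnosed ataxia, MSA,
healthy controls).
"""

from __future__ import annotations

import math

import numpy as np

from .simulate import AlleleConfig, CohortSpec, ErrorModel, GroupSpec, RepeatBlock

#: Wild-type short allele; normal FGF14 alleles sit well below 50 units.
WILD_TYPE_UNITS = 25


def wild_type(units: int = WILD_TYPE_UNITS) -> AlleleConfig:
    return AlleleConfig((RepeatBlock("GAA", units),), "T", f"wt{units}")


def pure(units: int, snp: str = "T") -> AlleleConfig:
    """Pure (GAA)N expansion; pure expansions carry the wild-type SNP (T)."""
    return AlleleConfig((RepeatBlock("GAA", units),), snp, f"pure{units}")


def complex_config(
    up_run: int,
    down_run: int,
    total_units: int = 230,
    snp: str = "A",
    label: str | None = None,
) -> AlleleConfig:
    """Complex configuration with pure GAA runs at both tract ends.

    The interruption region is (GCAGAA)c followed by one (GCA)2GAA block;
    the trailing (GCA)2GAA segments unambiguously under greedy longest-match
    tokenization so the downstream run length is recovered exactly.  ``c``
    is padded so the tract reaches ``total_units`` GAA-equivalents (the
    published complex alleles were all LR-PCR positive, i.e. > 200 units);
    interior interruption sizes are not reported and are a fixed choice
    here.
    """
    c = max(1, math.ceil((total_units - up_run - down_run - 3) / 2))
    blocks = (
        RepeatBlock("GAA", up_run),
        RepeatBlock("GCAGAA", c),
        RepeatBlock("GCAGCAGAA", 1),
        RepeatBlock("GAA", down_run),
    )
    if label is None:
        label = f"complex{up_run}_{down_run}"
    return AlleleConfig(blocks, snp, label)


def _spread_runs(lo: int, hi: int, n: int) -> list[int]:
    """n integer run lengths spanning [lo, hi] with both endpoints exact."""
    return [int(round(v)) for v in np.linspace(lo, hi, n)]


def table1_cohort_spec(
    depth: int = 20,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Cohort whose truth mirrors the published Table-1 category counts.

    Groups: undiagnosed ataxia (n=476), MSA (n=548), healthy (n=455).
    Per-category allele sizes use the printed values where the paper prints
    them (e.g. the single 269-unit MSA expansion, the 191-unit ataxia
    allele, terminal runs 34/167, 27/134, 27/160, 31/140) and spread the
    remaining category members across the printed ranges.  Expanded alleles
    are paired with a wild-type allele; use ``exact_counts=True`` in
    :func:`~fgf14repeat.simulate.simulate_cohort` to reproduce the counts
    exactly.
    """
    if error_model is None:
        error_model = ErrorModel(seed=seed)
    configs: dict[str, AlleleConfig] = {}

    def add(cfg: AlleleConfig) -> str:
        configs[cfg.label] = cfg
        return cfg.label

    wt = add(wild_type())

    def group(name: str, n: int, expanded: list[AlleleConfig]) -> GroupSpec:
        counts: dict[str, int] = {}
        for cfg in expanded:
            label = add(cfg)
            counts[label] = counts.get(label, 0) + 1
        counts[wt] = 2 * n - sum(counts.values())
        return GroupSpec(name, n, allele_counts=counts)

    # Undiagnosed ataxia: 6x pure >=250 (five of them >=300; printed range
    # 251-361), 2x pure 200-249 (212-240), 1x pure 191, 1x complex with a
    # 167-unit downstream run, 14x complex with runs 24-83.
    ataxia_expanded = (
        [pure(u) for u in (251, 300, 312, 325, 340, 361)]
        + [pure(u) for u in (212, 240)]
        + [pure(191)]
        + [complex_config(34, 167)]
        + [
            complex_config(10, r, label=f"ataxia_lt100_{i}_{r}")
            for i, r in enumerate(_spread_runs(24, 83, 14))
        ]
    )
    # MSA: 1x pure 269, 1x complex 27/134, 34x complex runs 21-83.
    msa_expanded = (
        [pure(269)]
        + [complex_config(27, 134)]
        + [
            complex_config(10, r, label=f"msa_lt100_{i}_{r}")
            for i, r in enumerate(_spread_runs(21, 83, 34))
        ]
    )
    # Healthy: 1x pure 254, 1x pure 245, 2x complex (27/160, 31/140),
    # 24x complex runs 23-75.
    healthy_expanded = (
        [pure(254), pure(245)]
        + [complex_config(27, 160), complex_config(31, 140)]
        + [
            complex_config(10, r, label=f"healthy_lt100_{i}_{r}")
            for i, r in enumerate(_spread_runs(23, 75, 24))
        ]
    )
    groups = (
        group("ataxia", 476, ataxia_expanded),
        group("msa", 548, msa_expanded),
        group("healthy", 455, healthy_expanded),
    )
    return CohortSpec(
        groups=groups,
        configs=configs,
        depth_range=(depth, depth),
        error_model=error_model,
        seed=seed,
    )
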