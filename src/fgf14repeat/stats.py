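"""Cohort-level frequency tables and statistics.

``frequency_table`` aggregates per-individual calls into the published
table shape: per group, the LR-PCR-positive count and the five expanded
categories (pure >=250, pure 200-249, pure <200, complex configuration
with a >=100-unit embedded run, complex without).  An individual with two
expanded alleles is counted once, under its highest-priority category.

``fisher_exact`` implements the two-sided test by the small-p (point
probability) convention with exact integer hypergeometric enumeration;
``spearman_exact`` uses midranks with a full permutation p-value for
n <= 8 and the large-sample approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import Band, ConfigClass, IndividualCall

#: Table categories in counting priority order (highest first).
CATEGORIES = (
    "pure_ge250",
    "pure_200_249",
    "pure_lt200",
    "complex_run_ge100",
    "complex_run_lt100",
)

#: An allele below this unit count is never reported as expanded (separates
#: expansions from the wild-type allele distribution; aligned with the
#: 100-unit complex-run split).
DEFAULT_EXPANDED_MIN_UNITS = 100


def round_half_up_pct(count: int, n: int) -> float:
    """Percentage count/n rounded half-up to one decimal (table format)."""
    if n == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _category(summary, expanded_min_units: int) -> str | None:
    """Table category of one allele summary, or None if not expanded."""
    units = summary.call.unit_count_median
    if units < expanded_min_units:
        return None
    if summary.configuration_class is ConfigClass.PURE:
        if units >= 250:
            return "pure_ge250"
        if units >= 200:
            return "pure_200_249"
        return "pure_lt200"
    if summary.configuration_class is ConfigClass.COMPLEX_RUN_GE100:
        return "complex_run_ge100"
    return "complex_run_lt100"


def _representative_units(summary) -> int:
    """The unit value the table reports for one allele.

    Pure categories report total units; complex categories report the
    longest embedded pure-GAA run, matching how complex alleles are sized
    in the published table.
    """
    if summary.configuration_class is ConfigClass.PURE:
        return int(round(summary.call.unit_count_median))
    return int(round(summary.call.longest_run_units))


def frequency_table(
    calls: list[IndividualCall],
    groups: list[str] | None = None,
    expanded_min_units: int = DEFAULT_EXPANDED_MIN_UNITS,
) -> pd.DataFrame:
    """Per-group expanded-repeat frequency table.

    One row per group with columns ``n``, ``lrpcr_positive`` (+ ``_pct``),
    and for each category a count, a percentage, and the min-max range of
    representative unit values.  ``lrpcr_positive`` equals the sum of the
    category counts (each individual counted once, highest priority
    category wins).
    """
    if groups is None:
        seen: list[str] = []
        for call in calls:
            if call.group not in seen:
                seen.append(call.group)
        groups = seen
    known = set(groups)
    for call in calls:
        if call.group not in known:
            raise ValueError(f"unknown group label {call.group!r}")
    rows = []
    for group in groups:
        members = [c for c in calls if c.group == group]
        counts = {cat: 0 for cat in CATEGORIES}
        ranges: dict[str, list[int]] = {cat: [] for cat in CATEGORIES}
        for call in members:
            best_cat = None
            best_units = None
            for summary in call.alleles:
                cat = _category(summary, expanded_min_units)
                if cat is None:
                    continue
                if best_cat is None or CATEGORIES.index(cat) < CATEGORIES.index(best_cat):
                    best_cat = cat
                    best_units = _representative_units(summary)
            if best_cat is not None:
                counts[best_cat] += 1
                ranges[best_cat].append(best_units)
        n = len(members)
        positive = sum(counts.values())
        row: dict = {"group": group, "n": n, "lrpcr_positive": positive,
                     "lrpcr_positive_pct": round_half_up_pct(positive, n)}
        for cat in CATEGORIES:
            row[cat] = counts[cat]
            row[f"{cat}_pct"] = round_half_up_pct(counts[cat], n)
            if ranges[cat]:
                row[f"{cat}_min"] = min(ranges[cat])
                row[f"{cat}_max"] = max(ranges[cat])
            else:
                row[f"{cat}_min"] = row[f"{cat}_max"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


@dataclass(frozen=True)
class ExactTestResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


def fisher_exact(a: int, b: int, c: int, d: int) -> ExactTestResult:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    The p-value sums the hypergeometric probabilities, over all tables
    with the observed margins, of every table whose point probability is
    at most that of the observed table (small-p convention).  Point
    probabilities are compared as exact integer numerators, so ties are
    handled without floating-point tolerance; the returned p is the
    correctly rounded float of an exact rational.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)
    }
    obs = numerators[a]
    p = Fraction(
        sum(v for v in numerators.values() if v <= obs), math.comb(n, c1)
    )
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ExactTestResult(((a, b), (c, d)), odds, float(p))


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  # "exact_permutation" or "asymptotic"


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_exact(x, y, exact_max_n: int = 8) -> SpearmanResult:
    """Spearman correlation with an exact permutation p for small n.

    Midranks handle ties.  For n <= ``exact_max_n`` the two-sided p is the
    exact fraction of the n! permutations of one variable whose |rho|
    reaches the observed |rho|; beyond that the large-sample approximation
    of :func:`scipy.stats.spearmanr` is used.  A constant vector leaves
    rho undefined (ValueError).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rho = _rank_rho(x, y)
    if math.isnan(rho):
        raise ValueError("constant vector: rho undefined")
    if n <= exact_max_n:
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        count = 0
        total = 0
        observed = abs(rho)
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= observed - 1e-12:
                count += 1
            total += 1
        return SpearmanResult(rho, count / total, n, "exact_permutation")
    res = sps.spearmanr(x, y)
    return SpearmanResult(rho, float(res.pvalue), n, "asymptotic")


@dataclass(frozen=True)
class BiasRecord:
    sample_id: str
    lrpcr_median_units: float
    wgs_median_units: float

    @property
    def difference(self) -> float:
        return self.wgs_median_units - self.lrpcr_median_units


def sizing_bias(
    lrpcr: dict[str, float], wgs: dict[str, float]
) -> tuple[list[BiasRecord], dict[str, float]]:
    """Per-sample WGS-minus-LR-PCR sizing differences plus a summary.

    Both dicts map sample id to the median unit count from that assay;
    the sample sets must match exactly.
    """
    if set(lrpcr) != set(wgs):
        missing = set(lrpcr) ^ set(wgs)
        raise ValueError(f"unmatched sample ids: {sorted(missing)}")
    records = [
        BiasRecord(sid, lrpcr[sid], wgs[sid]) for sid in sorted(lrpcr)
    ]
    diffs = [r.difference for r in records]
    summary = {
        "min_difference": min(diffs),
        "max_difference": max(diffs),
        "median_difference": float(np.median(diffs)),
    }
    return records, summary


def snp_association(
    calls: list[IndividualCall],
    expanded_min_units: int = DEFAULT_EXPANDED_MIN_UNITS,
) -> tuple[pd.DataFrame, int]:
    """Configuration-class x SNP-allele table over expanded alleles.

    Rows: pure vs complex; columns: T vs A (unknown bases excluded).
    Discordance counts pure-with-A plus complex-with-T alleles (the
    published association is pure -> T, complex -> A).
    """
    table = pd.DataFrame(
        0, index=["pure", "complex"], columns=["T", "A"], dtype=int
    )
    for call in calls:
        for summary in call.alleles:
            if _category(summary, expanded_min_units) is None:
                continue
            if summary.snp_base not in ("T", "A"):
                continue
            kind = (
                "pure"
                if summary.configuration_class is ConfigClass.PURE
                else "complex"
            )
            table.loc[kind, summary.snp_base] += 1
    discordance = int(table.loc["pure", "A"] + table.loc["complex", "T"])
    return table, discordance
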