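import itertools
import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from fgf14repeat import fisher_exact, sizing_bias, spearman_exact
from fgf14repeat.classify import AlleleSummary, Band, ConfigClass, IndividualCall
from fgf14repeat.profiling import AlleleCall
from fgf14repeat.stats import (
    frequency_table,
    round_half_up_pct,
    snp_association,
)

from oracles import fisher_two_sided_enumeration


def _call(sample, group, alleles):
    return IndividualCall(
        sample_id=sample, group=group, alleles=alleles,
        rp_pcr_prediction="negative", snp_genotype="T/T",
    )


def _summary(units, klass, run=None, snp="T"):
    run = run if run is not None else (units if klass is ConfigClass.PURE else 0)
    purity = 1.0 if klass is ConfigClass.PURE else 0.5
    call = AlleleCall(
        allele_index=1, n_reads=10, unit_count_median=units,
        unit_count_range=(units, units), purity=purity,
        upstream_run_units=run, downstream_run_units=run,
        longest_run_units=run,
    )
    band = Band.BELOW
    return AlleleSummary(call, klass, band, snp)


class TestFrequencyTable:
    def test_counts_percentages_and_ranges(self):
        calls = [
            _call("a1", "ataxia", [_summary(251, ConfigClass.PURE)]),
            _call("a2", "ataxia", [_summary(361, ConfigClass.PURE)]),
            _call("a3", "ataxia", [_summary(25, ConfigClass.PURE)]),  # wild type
            _call("a4", "ataxia", []),
        ]
        table = frequency_table(calls)
        row = table.loc["ataxia"]
        assert row["n"] == 4
        assert row["lrpcr_positive"] == 2
        assert row["pure_ge250"] == 2
        assert (row["pure_ge250_min"], row["pure_ge250_max"]) == (251, 361)
        assert row["lrpcr_positive_pct"] == 50.0

    def test_compound_het_counted_once_in_best_category(self):
        calls = [
            _call(
                "c1", "g",
                [
                    _summary(312, ConfigClass.PURE),
                    _summary(230, ConfigClass.COMPLEX_RUN_GE100, run=167),
                ],
            )
        ]
        table = frequency_table(calls)
        row = table.loc["g"]
        assert row["lrpcr_positive"] == 1
        assert row["pure_ge250"] == 1
        assert row["complex_run_ge100"] == 0

    def test_complex_ranges_report_longest_run(self):
        calls = [
            _call("x", "g", [_summary(230, ConfigClass.COMPLEX_RUN_LT100, run=83)])
        ]
        row = frequency_table(calls).loc["g"]
        assert row["complex_run_lt100_min"] == 83

    def test_unknown_group_rejected(self):
        calls = [_call("s", "mystery", [])]
        with pytest.raises(ValueError):
            frequency_table(calls, groups=["known"])

    def test_empty_cohort_all_zeros(self):
        table = frequency_table([], groups=["g"])
        row = table.loc["g"]
        assert row["n"] == 0 and row["lrpcr_positive"] == 0
        assert row["lrpcr_positive_pct"] == 0.0

    def test_percentages_recompute_from_counts(self):
        assert round_half_up_pct(24, 455) == 5.3  # half-up at the boundary
        assert round_half_up_pct(28, 455) == 6.2
        assert round_half_up_pct(6, 476) == 1.3
        assert round_half_up_pct(36, 548) == 6.6


class TestFisherExact:
    def test_degenerate_column_gives_p_one(self):
        assert fisher_exact(0, 10, 0, 10).p_two_sided == 1.0

    def test_perfect_separation_five_five(self):
        res = fisher_exact(5, 0, 0, 5)
        assert res.p_two_sided == pytest.approx(2 / math.comb(10, 5), abs=1e-15)
        assert res.odds_ratio == math.inf

    def test_published_style_table_matches_enumeration_oracle(self):
        res = fisher_exact(6, 470, 1, 454)
        oracle = fisher_two_sided_enumeration(6, 470, 1, 454)
        assert abs(res.p_two_sided - float(oracle)) <= 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(0, 0, 0, 0)

    def test_odds_ratio_conventions(self):
        assert fisher_exact(2, 3, 4, 5).odds_ratio == pytest.approx(10 / 12)
        assert fisher_exact(1, 0, 1, 1).odds_ratio == math.inf
        assert fisher_exact(0, 1, 1, 1).odds_ratio == 0.0

    def test_exhaustive_equality_with_oracle_small_margins(self):
        """Every 2x2 table with both row margins <= 12 matches the
        Fraction-enumeration oracle exactly (the wider <=40 sweep lives in
        the acceptance suite)."""
        for r1, r2 in itertools.product(range(13), repeat=2):
            if r1 + r2 == 0:
                continue
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    b, d = r1 - a, r2 - c
                    p = fisher_exact(a, b, c, d).p_two_sided
                    oracle = fisher_two_sided_enumeration(a, b, c, d)
                    assert abs(p - float(oracle)) <= 1e-14

    def test_matches_scipy_on_random_tables(self):
        rng = random.Random(7)
        for _ in range(200):
            a, b, c, d = (rng.randint(0, 60) for _ in range(4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact(a, b, c, d)
            _, p = sps.fisher_exact([[a, b], [c, d]])
            assert ours.p_two_sided == pytest.approx(p, rel=1e-9, abs=1e-12)


class TestSpearman:
    def test_perfectly_decreasing(self):
        res = spearman_exact([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res.rho == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_n6(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman_exact(x, y)
        assert res.method == "exact_permutation"
        rho_obs = abs(sps.spearmanr(x, y).statistic)
        count = sum(
            1
            for perm in itertools.permutations(y)
            if abs(sps.spearmanr(x, perm).statistic) >= rho_obs - 1e-12
        )
        assert res.p == pytest.approx(count / math.factorial(6), abs=1e-12)
        assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_midranks_hand_computed_four_points(self):
        # x = [1, 2, 2, 3] -> ranks [1, 2.5, 2.5, 4]
        # y = [1, 2, 3, 3] -> ranks [1, 2, 3.5, 3.5]
        # rho = cov / (sx sy) = (3.75/4) / (4.5/4) = 5/6
        res = spearman_exact([1, 2, 2, 3], [1, 2, 3, 3])
        assert res.rho == pytest.approx(float(Fraction(5, 6)), abs=1e-12)

    def test_sign_flips_when_one_variable_negated(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res = spearman_exact(x, y)
        flipped = spearman_exact(x, -y)
        assert flipped.rho == pytest.approx(-res.rho)
        assert 0.0 <= res.p <= 1.0
        assert -1.0 <= res.rho <= 1.0

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])


class TestSizingBias:
    def test_published_medians_give_14_and_11(self):
        records, summary = sizing_bias(
            {"msa": 269, "ataxia": 307}, {"msa": 283, "ataxia": 318}
        )
        diffs = {r.sample_id: r.difference for r in records}
        assert diffs == {"msa": 14, "ataxia": 11}
        assert summary["min_difference"] == 11
        assert summary["max_difference"] == 14

    def test_identical_sizes_zero(self):
        records, _ = sizing_bias({"s": 100}, {"s": 100})
        assert records[0].difference == 0

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            sizing_bias({"a": 1}, {"b": 1})


class TestSnpAssociation:
    def test_concordant_cohort_zero_discordance(self):
        calls = [
            _call("p", "g", [_summary(300, ConfigClass.PURE, snp="T")]),
            _call("c", "g", [_summary(230, ConfigClass.COMPLEX_RUN_LT100, run=50, snp="A")]),
        ]
        table, discordance = snp_association(calls)
        assert discordance == 0
        assert table.loc["pure", "T"] == 1
        assert table.loc["complex", "A"] == 1

    def test_one_flipped_allele(self):
        calls = [
            _call("p", "g", [_summary(300, ConfigClass.PURE, snp="A")]),
        ]
        _, discordance = snp_association(calls)
        assert discordance == 1

    def test_empty(self):
        table, discordance = snp_association([])
        assert discordance == 0 and table.values.sum() == 0
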