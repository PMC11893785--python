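import random
import statistics

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgf14repeat import (
    ErrorModel,
    build_allele_sequence,
    cluster_alleles,
    count_units,
    extract_repeat_reads,
    find_anchors,
    locate_junctions,
    profile_read,
    select_uniform_region,
    simulate_reads,
    terminal_runs,
    tokenize_tract,
    waterfall_matrix,
)
from fgf14repeat.locus import MOTIFS
from fgf14repeat.presets import complex_config, pure
from fgf14repeat.profiling import NOISE

from oracles import min_noise_dp


def _profiles_for(template, config, depth=20, error=None, seed=0, label="allele"):
    seq = build_allele_sequence(template, config)
    reads = simulate_reads(seq, depth, error or ErrorModel(seed=seed), label=label)
    anchored, _ = extract_repeat_reads(reads, template)
    profiles = []
    for a in anchored:
        prof, _ = profile_read(a, template)
        if prof is not None:
            profiles.append(prof)
    return profiles


class TestLocateJunctionsAndCountUnits:
    def test_pure_269_gap_is_798(self, template):
        seq = build_allele_sequence(template, pure(269))
        (up_end, down_start), _ = locate_junctions(seq, template)
        assert down_start - up_end == 3 * (269 - 3) == 798
        assert count_units(up_end, down_start) == 269

    def test_minimal_three_unit_tract_gap_zero(self, template):
        seq = build_allele_sequence(template, pure(3))
        (up_end, down_start), _ = locate_junctions(seq, template)
        assert down_start - up_end == 0
        assert count_units(up_end, down_start) == 3

    def test_gap_927_is_312_units(self):
        assert count_units(100, 100 + 927) == 312

    def test_substitution_in_junction_fails_with_reason(self, template):
        seq = build_allele_sequence(template, pure(50))
        pos = seq.find(template.junction_up)
        broken = seq[:pos] + "C" + seq[pos + 1 :]
        located, reason = locate_junctions(broken, template)
        assert located is None
        assert reason == "no_upstream_junction"

    def test_negative_gap_is_error(self):
        with pytest.raises(ValueError):
            count_units(10, 5)

    def test_sizing_round_trip_all_n_3_to_500(self, template):
        """String-count oracle: error-free pure (GAA)N sizes to exactly N."""
        for n in range(3, 501):
            seq = build_allele_sequence(template, pure(n))
            (up_end, down_start), _ = locate_junctions(seq, template)
            assert count_units(up_end, down_start) == n
            # oracle: count GAA triplets in the constructed tract
            tract = seq[len(template.up_flank) : -len(template.down_flank)]
            assert tract.count("GAA") * "x" == n * "x"


class TestTokenizer:
    def test_pure_gaa(self, template):
        tokens = tokenize_tract("GAA" * 10, template)
        assert [t.motif for t in tokens] == ["GAA"] * 10

    def test_gcagaa_only(self, template):
        tokens = tokenize_tract("GCAGAA" * 5, template)
        assert [t.motif for t in tokens] == ["GCAGAA"] * 5

    def test_longest_match_example(self, template):
        seq = "GCAGAAGAAGAAGAA" * 2 + "GAA" * 4
        tokens = tokenize_tract(seq, template)
        assert [t.motif for t in tokens] == ["GCAGAAGAAGAAGAA"] * 2 + ["GAA"] * 4
        assert min_noise_dp(seq, MOTIFS) == 0

    def test_nine_mer_tie_break_order(self, template):
        # (GCA)2GAA is tried before GCA(GAA)2 and wins at its own sequence
        tokens = tokenize_tract("GCAGCAGAA", template)
        assert [t.motif for t in tokens] == ["GCAGCAGAA"]

    def test_noise_positions_emit_single_nt_tokens(self, template):
        tokens = tokenize_tract("GAATTGAA", template)
        assert [t.motif for t in tokens] == ["GAA", NOISE, NOISE, "GAA"]

    def test_greedy_matches_min_noise_dp_on_motif_concatenations(self, template):
        """Greedy tiling achieves the DP-minimal noise (zero) on error-free
        concatenations of up to 20 random motif blocks."""
        rng = random.Random(42)
        for _ in range(300):
            blocks = [
                rng.choice(MOTIFS) * rng.randint(1, 8)
                for _ in range(rng.randint(1, 20))
            ]
            seq = "".join(blocks)
            tokens = tokenize_tract(seq, template)
            noise = sum(t.end - t.start for t in tokens if t.motif == NOISE)
            assert noise == min_noise_dp(seq, MOTIFS) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_tokens_partition_arbitrary_sequences(self, seq):
        template = __import__("fgf14repeat").default_template()
        tokens = tokenize_tract(seq, template)
        pos = 0
        for tok in tokens:
            assert tok.start == pos
            assert tok.end > tok.start
            pos = tok.end
        assert pos == len(seq)
        rebuilt = "".join(
            seq[t.start : t.end] for t in tokens
        )
        assert rebuilt == seq

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    def test_greedy_noise_never_beats_dp(self, seq):
        template = __import__("fgf14repeat").default_template()
        tokens = tokenize_tract(seq, template)
        noise = sum(t.end - t.start for t in tokens if t.motif == NOISE)
        assert noise >= min_noise_dp(seq, MOTIFS)


class TestTerminalRuns:
    def test_complex_with_runs_at_both_ends(self, template):
        tract = complex_config(34, 167).tract(template)
        up, down, longest = terminal_runs(tokenize_tract(tract, template))
        assert (up, down, longest) == (34, 167, 167)

    def test_pure_tract(self, template):
        runs = terminal_runs(tokenize_tract("GAA" * 100, template))
        assert runs == (100, 100, 100)

    def test_no_gaa_blocks(self, template):
        runs = terminal_runs(tokenize_tract("GCAGAA" * 50, template))
        assert runs == (0, 0, 0)

    def test_short_noise_is_transparent_to_runs(self, template):
        # 2 noise nt inside a run do not break it and add no units
        tract = "GAA" * 10 + "TT" + "GAA" * 20
        up, down, longest = terminal_runs(tokenize_tract(tract, template))
        assert (up, down, longest) == (30, 30, 30)

    def test_three_noise_nt_break_a_run(self, template):
        tract = "GAA" * 10 + "TTT" + "GAA" * 20
        up, down, longest = terminal_runs(tokenize_tract(tract, template))
        assert (up, down, longest) == (10, 20, 20)

    def test_interior_run_counts_only_as_longest(self, template):
        tract = (
            "GCAGAA" * 2 + "GCAGCAGAA" + "GAA" * 40
            + "GCAGCAGAA" + "GCAGAA" * 2
        )
        up, down, longest = terminal_runs(tokenize_tract(tract, template))
        assert up == 0 and down == 0
        assert longest == 40


class TestPurityAndProfiles:
    def test_purity_one_for_pure_and_zero_for_gcagaa(self, template):
        prof_pure = _profiles_for(template, pure(60), depth=1)[0]
        assert prof_pure.purity == 1.0
        assert prof_pure.noise_fraction == 0.0
        # a tract of GCAGAA only (terminal GAA blocks needed for junctions)
        tokens = tokenize_tract("GCAGAA" * 30, template)
        gaa_nt = sum(t.end - t.start for t in tokens if t.motif == "GAA")
        assert gaa_nt == 0

    def test_unit_count_matches_token_units(self, template):
        prof = _profiles_for(template, complex_config(27, 134), depth=1)[0]
        token_units = sum(
            (t.end - t.start) // 3 for t in prof.tokens if t.motif != NOISE
        )
        assert prof.unit_count == token_units == 230


class TestSelectUniformRegion:
    def _fake_profiles(self, template, lengths):
        profiles = []
        for i, n_units in enumerate(lengths):
            seq = build_allele_sequence(template, pure(n_units))
            anchored, _ = find_anchors(f"r{i:03d}", seq, template)
            prof, _ = profile_read(anchored, template)
            profiles.append(prof)
        return profiles

    def test_identical_lengths_all_selected(self, template):
        profiles = self._fake_profiles(template, [269] * 30)
        selected, discarded = select_uniform_region(profiles)
        assert len(selected) == 30 and discarded == 0

    def test_shattered_reads_discarded(self, template):
        profiles = self._fake_profiles(
            template, [269, 270, 268] * 9 + [269] + [100, 100]
        )
        selected, discarded = select_uniform_region(profiles)
        assert len(selected) == 28 and discarded == 2
        assert all(p.unit_count >= 268 for p in selected)

    def test_order_independence(self, template):
        profiles = self._fake_profiles(template, [300] * 10 + [100, 100] + [299] * 5)
        sel1, _ = select_uniform_region(profiles)
        sel2, _ = select_uniform_region(list(reversed(profiles)))
        assert {p.read_id for p in sel1} == {p.read_id for p in sel2}

    def test_heterozygote_keeps_both_populations(self, template):
        profiles = self._fake_profiles(template, [25] * 10 + [300] * 10)
        selected, discarded = select_uniform_region(profiles)
        assert len(selected) == 20 and discarded == 0


class TestClusterAlleles:
    def test_compound_het_two_calls(self, template):
        profiles = _profiles_for(template, pure(312), depth=10) + _profiles_for(
            template, complex_config(34, 167), depth=10, seed=1
        )
        calls, dropped = cluster_alleles(profiles)
        assert len(calls) == 2 and dropped == 0
        assert calls[0].unit_count_median == 230  # complex total units
        assert calls[1].unit_count_median == 312
        assert calls[1].allele_index == 2

    def test_homozygous_single_call(self, template):
        profiles = _profiles_for(template, pure(269), depth=12)
        calls, dropped = cluster_alleles(profiles)
        assert len(calls) == 1
        assert calls[0].unit_count_median == 269
        assert calls[0].unit_count_range == (269, 269)

    def test_two_reads_only_no_call(self, template):
        profiles = _profiles_for(template, pure(269), depth=2)
        calls, dropped = cluster_alleles(profiles)
        assert calls == [] and dropped == 2


class TestNoiseRobustness:
    @pytest.mark.parametrize("n", [50, 200, 400])
    def test_median_within_two_units_at_low_error(self, template, n):
        profiles = _profiles_for(
            template, pure(n), depth=20,
            error=ErrorModel(sub_rate=0.005, seed=100 + n),
        )
        assert len(profiles) >= 5
        median = statistics.median(p.unit_count for p in profiles)
        assert abs(median - n) <= 2


class TestWaterfallMatrix:
    def test_lossless_export_sorted_by_length(self, template):
        profiles = _profiles_for(
            template, pure(30), depth=2, label="short"
        ) + _profiles_for(
            template, complex_config(10, 24), depth=2, seed=3, label="long"
        )
        matrix = waterfall_matrix(profiles)
        # row order: ascending tract length, stable by read id
        lengths = matrix.groupby("read_id", sort=False)["end"].max()
        assert list(lengths) == sorted(lengths)
        # tokens reproduce each read's tract exactly
        for prof in profiles:
            rows = matrix[matrix["read_id"] == prof.read_id]
            assert len(rows) == len(prof.tokens)
            assert rows["end"].max() == prof.tract_nt
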