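"""Amplicon quantification: demultiplex, align, windows, tables, zygosity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iterquant import amplicon as amp
from iterquant import synth
from iterquant.amplicon import AmpliconTarget
from iterquant.errors import ConfigurationError, FormatError, InputError
from iterquant.io import FastqRead
from iterquant.synth import AlleleSpec, Haplotype


def fq(seq, qual=None, rid="r"):
    return FastqRead(rid, seq, qual if qual is not None else "I" * len(seq))


# ---------------------------------------------------------------------------
# demultiplexing / quality
# ---------------------------------------------------------------------------


class TestDemultiplex:
    INDEX = {"s1": "AAAAAA", "s2": "CCCCCC", "s3": "GGGGGG"}

    def test_exact_index_assigned_and_trimmed(self):
        reads = [fq("AAAAAA" + "ACGT" * 10)]
        assigned, unassigned, _ = amp.demultiplex(reads, self.INDEX)
        assert len(assigned["s1"]) == 1 and not unassigned
        assert assigned["s1"][0].seq == "ACGT" * 10
        assert len(assigned["s1"][0].qual) == 40

    def test_unmatched_prefix_goes_unassigned(self):
        reads = [fq("TTTTTT" + "ACGT" * 10)]
        assigned, unassigned, _ = amp.demultiplex(reads, self.INDEX, max_mismatch=0)
        assert len(unassigned) == 1
        assert all(not v for v in assigned.values())

    def test_shuffled_tagged_reads_recover_generation_record(self, cas12a_target):
        rng = np.random.default_rng(0)
        reads = []
        for sample, idx in self.INDEX.items():
            spec = AlleleSpec(haplotypes=((Haplotype("reference"), 1.0),), index=idx)
            reads.extend(synth.simulate_reads(cas12a_target, spec, 100, seed=1))
        order = rng.permutation(len(reads))
        shuffled = [reads[i] for i in order]
        assigned, unassigned, stats = amp.demultiplex(shuffled, self.INDEX)
        assert [len(assigned[s]) for s in self.INDEX] == [100, 100, 100]
        assert len(unassigned) == 0
        # conservation: assigned + unassigned = input
        assert stats["n_reads"].sum() == len(shuffled)

    def test_index_collision_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            amp.demultiplex([], {"a": "AAAAAA", "b": "AAAAAC"}, max_mismatch=1)

    def test_non_6nt_index_rejected(self):
        with pytest.raises(ConfigurationError):
            amp.demultiplex([], {"a": "AAAA"})


class TestQualityFilter:
    def test_thresholding_on_mean_quality(self):
        q40 = fq("ACGT" * 10, chr(40 + 33) * 40)
        q20 = fq("ACGT" * 10, chr(20 + 33) * 40)
        passing, failing = amp.quality_filter([q40, q20], 30)
        assert passing == [q40] and failing == [q20]

    def test_mean_quality_boundary_is_inclusive(self):
        half = fq("AC" * 10, chr(20 + 33) * 10 + chr(40 + 33) * 10)
        assert amp.mean_quality(half.qual) == pytest.approx(30.0)
        passing, failing = amp.quality_filter([half], 30)
        assert passing and not failing

    def test_malformed_quality_string_raises_format_error(self):
        bad = FastqRead("r1", "ACGT", "II")
        with pytest.raises(FormatError, match="r1"):
            amp.quality_filter([bad], 30)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def brute_force_affine(target, query, match=2, mismatch=-1, open_=-5, extend=-1):
    """Tiny affine-gap DP (free end gaps on target) returning the best score.

    Independent of the production aligner; only for short fixtures.
    """
    NEG = float("-inf")
    n, m = len(target), len(query)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # match/mismatch state
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target unpaired)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (query unpaired)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading target gap
    for j in range(1, m + 1):
        Y[0][j] = max(M[0][j - 1] + open_, Y[0][j - 1] + extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if target[i - 1] == query[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend)
    # free trailing target gap: best over rows at j = m
    return max(max(M[i][m], Y[i][m]) for i in range(n + 1))


class TestAlignment:
    def test_exact_substring_aligns_gap_free_at_correct_offset(self, cas12a_target):
        sub = cas12a_target.amplicon[5:45]
        a = amp.align_read(fq(sub), cas12a_target)
        assert a.orientation == "+"
        assert a.span == (5, 45)
        assert not a.indels
        assert all(cas12a_target.amplicon[p] == b for p, b in a.bases.items())

    def test_reverse_complement_same_coordinates_flagged(self, cas12a_target):
        sub = cas12a_target.amplicon[5:45]
        rc = amp._revcomp(sub)
        a = amp.align_read(fq(rc), cas12a_target)
        assert a.orientation == "-"
        assert a.span == (5, 45)
        assert not a.indels

    def test_single_deletion_read_yields_one_deletion_gap(self, cas12a_target):
        ampseq = cas12a_target.amplicon
        read = ampseq[:20] + ampseq[23:]  # 3-nt deletion
        a = amp.align_read(fq(read), cas12a_target)
        dels = [i for i in a.indels if i[0] == "del"]
        assert len(dels) == 1
        assert dels[0][2] == 3

    def test_alignment_score_matches_brute_force_dp(self, cas12a_target):
        """Production scores equal an exhaustive small-case DP oracle."""
        ampseq = cas12a_target.amplicon
        cases = [
            ampseq[4:44],                       # exact substring
            ampseq[4:20] + ampseq[23:44],       # deletion
            ampseq[4:24] + "T" + ampseq[24:40], # insertion
            ampseq[4:24].replace("A", "C") + ampseq[24:44],  # mismatches
        ]
        for read in cases:
            if len(read) < 30:
                continue
            a = amp.align_read(fq(read), cas12a_target)
            assert a.score == pytest.approx(brute_force_affine(ampseq, read))

    def test_unalignable_read_returns_none(self, cas12a_target):
        junk = "T" * 40
        assert amp.align_read(fq(junk), cas12a_target) is None

    def test_short_read_rejected(self, cas12a_target):
        with pytest.raises(InputError):
            amp.align_read(fq("ACGTACGT"), cas12a_target)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


class TestQuantificationWindow:
    def make(self, L, w, c):
        spacer = ("ACGT" * 10)[:L]
        ampseq = "TTTTTTTTTT" + spacer + "GGGGGGGGGG"
        return AmpliconTarget("t", ampseq, spacer, window_size=w, window_center=c)

    def test_canonical_base_editing_window(self):
        t = self.make(20, 10, -12)
        assert amp.quantification_window(t) == list(range(4, 14))

    def test_width_one_window(self):
        t = self.make(20, 1, -1)
        assert amp.quantification_window(t) == [19]

    def test_oversized_window_clips_to_spacer(self):
        t = self.make(20, 40, -10)
        assert amp.quantification_window(t) == list(range(1, 21))

    def test_center_outside_spacer_rejected(self):
        with pytest.raises(ConfigurationError):
            amp.quantification_window(self.make(10, 4, -12))

    @given(L=st.integers(10, 30), w=st.integers(1, 40), c=st.integers(-9, -1))
    @settings(max_examples=50, deadline=None)
    def test_window_always_within_spacer_and_at_most_w_wide(self, L, w, c):
        t = self.make(L, w, c)
        win = amp.quantification_window(t)
        assert win == sorted(win)
        assert 1 <= win[0] and win[-1] <= L
        assert len(win) <= w


# ---------------------------------------------------------------------------
# quantification oracles
# ---------------------------------------------------------------------------


def column_oracle(reads, target):
    """Brute-force per-column mismatch count over gap-free full-length reads."""
    window = amp.quantification_window(target)
    counts = {p: {b: 0 for b in "ACGT"} for p in window}
    for read in reads:
        seq = read.seq.upper()
        for p in window:
            a = target.proto_to_amplicon(p)
            base = target.read_base_to_proto(seq[a])
            ref = target.protospacer[p - 1]
            if base != ref:
                counts[p][base] += 1
    return counts


class TestQuantifySubstitutions:
    def _quantify(self, reads, target):
        aligned = [amp.align_read(r, target) for r in reads]
        return amp.quantify_substitutions([a for a in aligned if a], target)

    def test_all_reference_reads_score_zero_everywhere(self, cas12a_target):
        spec = AlleleSpec(haplotypes=((Haplotype("reference"), 1.0),))
        reads = synth.simulate_reads(cas12a_target, spec, 50, seed=0)
        table = self._quantify(reads, cas12a_target)
        assert not table.substitutions.to_numpy().any()
        assert table.unmodified_pct == 100.0

    def test_deterministic_forty_percent_edit(self, cas12a_target):
        pos = cas12a_target.proto_to_amplicon(9)
        spec = AlleleSpec(haplotypes=(
            (Haplotype("edit", substitutions=((pos, "G"),)), 0.4),
            (Haplotype("reference"), 0.6),
        ))
        reads = synth.simulate_reads(cas12a_target, spec, 1000, seed=0)
        table = self._quantify(reads, cas12a_target)
        assert table.percent(9, "G") == pytest.approx(40.0)
        others = table.substitutions.drop(index=9)
        assert not others.to_numpy().any()
        assert table.substitution_only_pct == pytest.approx(40.0)
        assert table.indel_pct == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_table_equals_brute_force_column_counts(self, cas12a_target, seed):
        rng = np.random.default_rng(seed)
        pos_a = cas12a_target.proto_to_amplicon(9)
        pos_b = cas12a_target.proto_to_amplicon(11)
        f = float(rng.uniform(0.1, 0.8))
        spec = AlleleSpec(
            haplotypes=(
                (Haplotype("e", substitutions=((pos_a, "G"), (pos_b, "C"))), f),
                (Haplotype("reference"), 1.0 - f),
            ),
            per_base_error=0.002,
        )
        reads = synth.simulate_reads(cas12a_target, spec, 300, seed=seed + 100)
        table = self._quantify(reads, cas12a_target)
        oracle = column_oracle(reads, cas12a_target)
        n = len(reads)
        for p, per_base in oracle.items():
            for b, count in per_base.items():
                if b == cas12a_target.protospacer[p - 1]:
                    continue
                assert table.percent(p, b) == pytest.approx(100.0 * count / n)

    def test_monotonicity_appending_an_edited_read(self, cas12a_target):
        pos = cas12a_target.proto_to_amplicon(9)
        spec = AlleleSpec(haplotypes=(
            (Haplotype("e", substitutions=((pos, "G"),)), 0.3),
            (Haplotype("reference"), 0.7),
        ))
        reads = synth.simulate_reads(cas12a_target, spec, 100, seed=0)
        before = self._quantify(reads, cas12a_target).percent(9, "G")
        edited_seq = Haplotype("e", substitutions=((pos, "G"),)).apply(cas12a_target.amplicon)
        after = self._quantify(reads + [fq(edited_seq, rid="extra")],
                               cas12a_target).percent(9, "G")
        assert after >= before


class TestQuantifyIndels:
    def _aligned(self, reads, target):
        return [a for a in (amp.align_read(r, target) for r in reads) if a]

    def test_no_gapped_reads_scores_zero(self, cas12a_target):
        spec = AlleleSpec(haplotypes=((Haplotype("reference"), 1.0),))
        reads = synth.simulate_reads(cas12a_target, spec, 40, seed=0)
        pct, dels, ins = amp.quantify_indels(self._aligned(reads, cas12a_target),
                                             cas12a_target)
        assert pct == 0.0 and not dels and not ins

    def test_deterministic_twenty_percent_deletion(self, cas12a_target):
        cut = cas12a_target.proto_to_amplicon(19)  # cleavage site L-4
        spec = AlleleSpec(haplotypes=(
            (Haplotype("del4", deletion=(cut, 4)), 0.2),
            (Haplotype("reference"), 0.8),
        ))
        reads = synth.simulate_reads(cas12a_target, spec, 500, seed=0)
        pct, dels, _ = amp.quantify_indels(self._aligned(reads, cas12a_target),
                                           cas12a_target)
        assert pct == pytest.approx(20.0)
        assert dels == {4: 100}

    def test_indel_outside_window_not_counted(self, cas12a_target):
        # deletion in the amplicon flank, downstream of the spacer
        spec = AlleleSpec(haplotypes=((Haplotype("fardel", deletion=(40, 3)), 1.0),))
        reads = synth.simulate_reads(cas12a_target, spec, 30, seed=0)
        aligned = self._aligned(reads, cas12a_target)
        pct, _, _ = amp.quantify_indels(aligned, cas12a_target)
        assert pct == 0.0
        # but the alignment itself does carry the deletion
        assert all(a.has_indel for a in aligned)


class TestAlleleTable:
    def _alleles(self, reads, target):
        aligned = [a for a in (amp.align_read(r, target) for r in reads) if a]
        return amp.allele_table(aligned, target)

    def test_single_haplotype_is_one_row_at_100(self, cas12a_target):
        spec = AlleleSpec(haplotypes=((Haplotype("reference"), 1.0),))
        reads = synth.simulate_reads(cas12a_target, spec, 25, seed=0)
        table = self._alleles(reads, cas12a_target)
        assert len(table) == 1
        assert table.iloc[0]["percent"] == 100.0
        assert table.iloc[0]["annotation"] == "reference"

    def test_sixty_forty_mixture(self, cas12a_target):
        pos = cas12a_target.proto_to_amplicon(9)
        spec = AlleleSpec(haplotypes=(
            (Haplotype("e", substitutions=((pos, "G"),)), 0.4),
            (Haplotype("reference"), 0.6),
        ))
        reads = synth.simulate_reads(cas12a_target, spec, 500, seed=0)
        table = self._alleles(reads, cas12a_target)
        assert list(table["percent"]) == [60.0, 40.0]
        assert table["count"].sum() == 500
        assert "A9G" in table.iloc[1]["annotation"]

    def test_row_counts_match_window_substring_dictionary(self, cas12a_target):
        pos = cas12a_target.proto_to_amplicon(8)
        spec = AlleleSpec(
            haplotypes=(
                (Haplotype("e", substitutions=((pos, "C"),)), 0.3),
                (Haplotype("reference"), 0.7),
            ),
            per_base_error=0.005,
        )
        reads = synth.simulate_reads(cas12a_target, spec, 200, seed=3)
        table = self._alleles(reads, cas12a_target)
        window = amp.quantification_window(cas12a_target)
        counts = {}
        for r in reads:
            hap = "".join(
                cas12a_target.read_base_to_proto(r.seq[cas12a_target.proto_to_amplicon(p)])
                for p in window
            )
            counts[hap] = counts.get(hap, 0) + 1
        assert dict(zip(table["haplotype"], table["count"])) == counts


class TestZygosity:
    @pytest.mark.parametrize("rate,call", [
        (0.0, "WT"), (10.0, "WT"), (24.999, "WT"),
        (25.0, "HZ"), (50.0, "HZ"), (70.0, "HZ"),
        (70.001, "HM"), (80.0, "HM"), (100.0, "HM"),
    ])
    def test_threshold_rules(self, rate, call):
        assert amp.call_zygosity(rate).call == call

    @pytest.mark.parametrize("rate", [-0.1, 100.1])
    def test_out_of_range_rejected(self, rate):
        with pytest.raises(InputError):
            amp.call_zygosity(rate)

    @given(st.floats(0, 100, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_every_rate_gets_exactly_one_call(self, rate):
        assert amp.call_zygosity(rate).call in {"WT", "HZ", "HM"}


class TestSpacerMismatches:
    def test_identical_sequences_have_no_mismatches(self):
        assert amp.annotate_spacer_mismatches("ACGTACGT", "ACGTACGT") == []

    def test_position_three_is_seed(self):
        assert amp.annotate_spacer_mismatches("ACGTACGTACGT", "ACTTACGTACGT") == [(3, "seed")]

    def test_homeolog_trio_matches_construction_record(self):
        spacer = "TCAGTACGATGCAAGGTCATCGA"
        trio = {
            "A": (spacer, []),
            "B": (spacer[:4] + "A" + spacer[5:], [(5, "seed")]),
            "D": (spacer[:20] + "TTT", [(21, "distal"), (22, "distal"), (23, "distal")]),
        }
        for name, (locus, expected) in trio.items():
            observed = amp.annotate_spacer_mismatches(spacer, locus)
            # drop positions where the random replacement equals the original
            assert [m for m in observed] == [
                m for m in expected if spacer[m[0] - 1] != locus[m[0] - 1]
            ]

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            amp.annotate_spacer_mismatches("ACGT", "ACGTA")


class TestReadConservation:
    def test_every_stage_conserves_reads(self, cas12a_target):
        idx = {"s1": "AAAAAA", "s2": "CCCCCC"}
        reads = []
        for sample, index in idx.items():
            spec = AlleleSpec(haplotypes=((Haplotype("reference"), 1.0),),
                              index=index, quality_mean=31.0, quality_sd=4.0)
            reads.extend(synth.simulate_reads(cas12a_target, spec, 60, seed=5))
        reads.append(fq("T" * 60, rid="junk"))  # unassignable prefix
        assigned, unassigned, _ = amp.demultiplex(reads, idx)
        assert sum(len(v) for v in assigned.values()) + len(unassigned) == len(reads)
        for sample_reads in assigned.values():
            passing, failing = amp.quality_filter(sample_reads, 30)
            aligned = [amp.align_read(r, cas12a_target) for r in passing]
            n_unalignable = sum(a is None for a in aligned)
            assert len(passing) + len(failing) == len(sample_reads)
            assert n_unalignable + sum(a is not None for a in aligned) == len(passing)

    def test_class_partition_sums_to_100(self, cas12a_target):
        cut = cas12a_target.proto_to_amplicon(19)
        pos = cas12a_target.proto_to_amplicon(10)
        spec = AlleleSpec(haplotypes=(
            (Haplotype("sub", substitutions=((pos, "G"),)), 0.3),
            (Haplotype("del", deletion=(cut, 2)), 0.2),
            (Haplotype("reference"), 0.5),
        ))
        reads = synth.simulate_reads(cas12a_target, spec, 200, seed=0)
        aligned = [a for a in (amp.align_read(r, cas12a_target) for r in reads) if a]
        table = amp.quantify_substitutions(aligned, cas12a_target)
        total = table.indel_pct + table.substitution_only_pct + table.unmodified_pct
        assert total == pytest.approx(100.0, abs=1e-6)


class TestMinusStrandTarget:
    def test_positions_report_in_protospacer_sense(self):
        spacer = "TCAGTACGATGCAAGGTCATCGA"
        plus_amplicon = "GATTACAGGA" + "TTTC" + spacer + "ACGGATTGCCAGT"
        minus_amplicon = amp._revcomp(plus_amplicon)
        t = AmpliconTarget("rev", minus_amplicon, spacer, strand="-")
        # edit protospacer position 9 (A->G in spacer sense = T->C on top strand)
        coord = t.proto_to_amplicon(9)
        assert t.read_base_to_proto(minus_amplicon[coord]) == spacer[8]
        hap = Haplotype("e", substitutions=((coord, amp._revcomp("G")),))
        spec = AlleleSpec(haplotypes=((hap, 0.4), (Haplotype("reference"), 0.6)))
        reads = synth.simulate_reads(t, spec, 200, seed=0)
        aligned = [a for a in (amp.align_read(r, t) for r in reads) if a]
        table = amp.quantify_substitutions(aligned, t)
        assert table.percent(9, "G") == pytest.approx(40.0)


def test_quantify_sample_end_to_end(cas9_target):
    pos = cas9_target.proto_to_amplicon(8)  # a window C, C-to-T edit
    assert cas9_target.amplicon[pos] == "C"
    spec = AlleleSpec(haplotypes=(
        (Haplotype("cbe", substitutions=((pos, "T"),)), 0.25),
        (Haplotype("reference"), 0.75),
    ))
    reads = synth.simulate_reads(cas9_target, spec, 400, seed=0)
    result = amp.quantify_sample(reads, cas9_target)
    assert result.n_passing == 400
    assert result.editing.percent(8, "T") == pytest.approx(25.0)
    assert "PAM-distal" in result.editing.convention
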