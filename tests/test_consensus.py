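import io
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnascan.consensus import (
    FinalPartners,
    PairStats,
    accumulate_pairs,
    classify_pairs,
    compute_znorm,
    extract_motifs,
    paired_window_counts,
    remove_crossings,
    resolve_competition,
    write_arc_track,
    write_final_partners,
    write_motif_ct,
    write_motif_dbn,
    write_motifs_gff3,
    zclass,
)
from rnascan.fold import dotbracket_to_pairs
from rnascan.roc import read_ct
from rnascan.scan import WindowMetrics


def mk_window(start, structure, z):
    n = len(structure)
    return WindowMetrics(start, start + n - 1, -1.0, z, 0.1, 1.0, "A" * n, structure)


def finalize(pair_znorm, length, per_nt_z=None):
    stats = [
        PairStats(i=i, j=j, n_windows=1, zsum=z, znorm=z) for (i, j), z in pair_znorm.items()
    ]
    return resolve_competition(stats, length, per_nt_z=per_nt_z)


class TestAccumulate:
    def test_zsum_arithmetic(self):
        w = [mk_window(1, "((...))", -2.0) for _ in range(3)]
        stats = accumulate_pairs(w)
        by_pair = {(s.i, s.j): s for s in stats}
        assert by_pair[(1, 7)].zsum == pytest.approx(-6.0)
        assert by_pair[(1, 7)].n_windows == 3
        assert by_pair[(2, 6)].n_windows == 3

    def test_unobserved_pair_absent(self):
        stats = accumulate_pairs([mk_window(1, "(...).", -1.0)])
        assert {(s.i, s.j) for s in stats} == {(1, 5)}

    def test_two_window_brute_force_oracle(self):
        w1 = mk_window(1, "((...))..", -1.5)
        w2 = mk_window(3, "(...)....", -0.5)
        stats = accumulate_pairs([w1, w2])
        # independent enumeration of (window, pair) occurrences
        expected = Counter()
        zsum = Counter()
        for w in (w1, w2):
            for a, b in dotbracket_to_pairs(w.structure):
                key = (w.start + a, w.start + b)
                expected[key] += 1
                zsum[key] += w.z
        assert {(s.i, s.j): s.n_windows for s in stats} == dict(expected)
        for s in stats:
            assert s.zsum == pytest.approx(zsum[(s.i, s.j)])

    def test_unbalanced_structure_names_window(self):
        bad = mk_window(5, "((...", -1.0)
        with pytest.raises(ValueError, match="window 5"):
            accumulate_pairs([bad])


class TestZnorm:
    def test_pair_denominator(self):
        stats = [PairStats(5, 20, n_windows=3, zsum=-6.0)]
        compute_znorm(stats)
        assert stats[0].znorm == pytest.approx(-2.0)

    def test_competitor_preference(self):
        stats = [
            PairStats(1, 10, n_windows=2, zsum=-4.0),  # znorm -2
            PairStats(1, 12, n_windows=2, zsum=-2.0),  # znorm -1
        ]
        compute_znorm(stats)
        final = resolve_competition(stats, 12)
        assert final.partner[1] == 10
        assert final.partner[12] == 0

    def test_denominator_choice_sensitivity(self):
        # Pair (1,8) seen in 2 windows (z -2 each); position 1 also paired
        # to 10 in a third window (z -1).
        windows = [
            mk_window(1, "(......)..", -2.0),
            mk_window(1, "(......)..", -2.0),
            mk_window(1, "(........)", -1.0),
        ]
        stats = accumulate_pairs(windows)
        by_pair = lambda ss: {(s.i, s.j): s.znorm for s in ss}
        pair_view = by_pair(compute_znorm([s for s in stats]))
        assert pair_view[(1, 8)] == pytest.approx(-2.0)  # zsum -4 / 2 windows
        counts = paired_window_counts(windows, 10)
        assert counts[1] == 3 and counts[8] == 2
        nuc_view = by_pair(
            compute_znorm(accumulate_pairs(windows), "nucleotide", counts)
        )
        # zsum -4 / mean(3, 2) = -1.6 under the nucleotide reading
        assert nuc_view[(1, 8)] == pytest.approx(-1.6)

    def test_nucleotide_denominator_requires_counts(self):
        with pytest.raises(ValueError):
            compute_znorm([PairStats(1, 5, 1, -1.0)], denominator="nucleotide")

    def test_unknown_denominator(self):
        with pytest.raises(ValueError):
            compute_znorm([], denominator="window")


class TestResolveCompetition:
    def test_chain_conflict_greedy(self):
        final = finalize({(1, 10): -2.0, (10, 20): -1.5}, 20)
        assert final.partner[1] == 10
        assert final.partner[20] == 0

    def test_requires_znorm(self):
        with pytest.raises(ValueError, match="znorm"):
            resolve_competition([PairStats(1, 5, 1, -1.0)], 5)

    @given(
        st.dictionaries(
            st.tuples(st.integers(1, 12), st.integers(1, 12)).filter(lambda p: p[0] < p[1]),
            st.floats(-4, 1, allow_nan=False),
            max_size=14,
        )
    )
    @settings(max_examples=120, deadline=None)
    def test_involution_uniqueness_maximality(self, pair_znorm):
        final = finalize(pair_znorm, 12)
        partner = final.partner
        # involution & one partner per nucleotide
        for i in range(1, 13):
            j = partner[i]
            if j:
                assert partner[j] == i
        # maximality: every rejected pair conflicts with an accepted one
        accepted = set(final.pair_znorm)
        for (i, j), _z in pair_znorm.items():
            if (i, j) not in accepted:
                assert partner[i] != 0 or partner[j] != 0

    def test_deterministic_tie_break(self):
        a = finalize({(1, 10): -1.0, (2, 10): -1.0}, 10)
        b = finalize({(2, 10): -1.0, (1, 10): -1.0}, 10)
        assert a.partner[10] == b.partner[10] == 1

    def test_annotation_mixes_pair_and_unpaired_z(self):
        per_nt = np.full(10, -0.25)
        final = finalize({(2, 9): -3.0}, 10, per_nt_z=per_nt)
        assert final.annotation[2] == pytest.approx(-3.0)
        assert final.annotation[9] == pytest.approx(-3.0)
        assert final.annotation[1] == pytest.approx(-0.25)


class TestClassification:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (-2.0, "z<=-2"),
            (-2.5, "z<=-2"),
            (-1.5, "z<=-1"),
            (-1.0, "z<=-1"),
            (-0.2, "z<0"),
            (0.0, "z>=0"),
            (0.7, "z>=0"),
        ],
    )
    def test_boundaries_inclusive(self, z, expected):
        assert zclass(z) == expected

    def test_classify_pairs(self):
        final = finalize({(1, 10): -2.0, (2, 9): -0.5}, 10)
        classes = classify_pairs(final)
        assert classes[(1, 10)] == "z<=-2"
        assert classes[(2, 9)] == "z<0"


class TestCrossings:
    def test_crossing_resolved_by_znorm(self):
        final = finalize({(1, 10): -2.0, (5, 15): -1.0}, 15)
        kept = remove_crossings(final)
        assert kept == [(1, 10)]

    def test_nested_pairs_kept(self):
        final = finalize({(1, 10): -2.0, (2, 9): -1.0}, 10)
        assert remove_crossings(final) == [(1, 10), (2, 9)]


class TestExtractMotifs:
    def test_single_hairpin_at_thresholds(self):
        seq = "G" * 12
        pairs = {(1, 12): -2.5, (2, 11): -2.5, (3, 10): -2.5}
        final = finalize(pairs, 12)
        motifs = extract_motifs(final, -2.0, seq)
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.start, m.end) == (1, 12)
        assert m.min_pair_z == pytest.approx(-2.5)
        assert m.structure == "(((......)))"

    def test_thresholding(self):
        seq = "G" * 12
        final = finalize({(1, 12): -1.5, (2, 11): -1.5}, 12)
        assert extract_motifs(final, -2.0, seq) == []
        assert len(extract_motifs(final, -1.0, seq)) == 1

    def test_monotonicity_minus2_subset_of_minus1(self, rng):
        for _ in range(20):
            n = 40
            pair_znorm = {}
            for _ in range(rng.integers(1, 10)):
                i = int(rng.integers(1, n - 4))
                j = int(rng.integers(i + 4, n + 1))
                pair_znorm[(i, j)] = float(rng.uniform(-3, 0.5))
            final = finalize(pair_znorm, n)
            seq = "A" * n
            m2 = {(m.start, m.end) for m in extract_motifs(final, -2.0, seq)}
            m1 = {(m.start, m.end) for m in extract_motifs(final, -1.0, seq)}
            assert m2 <= m1

    def test_motifs_disjoint_and_sorted(self):
        seq = "A" * 30
        final = finalize({(1, 10): -2.0, (12, 25): -1.5, (14, 20): -2.5}, 30)
        motifs = extract_motifs(final, -1.0, seq)
        assert [(m.start, m.end) for m in motifs] == [(1, 10), (12, 25)]
        spans = [(m.start, m.end) for m in motifs]
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2

    def test_nonnegative_pairs_excluded(self):
        final = finalize({(1, 10): 0.0}, 10)
        assert extract_motifs(final, -1.0, "A" * 10) == []

    def test_isolated_pair_one_pair_motif(self):
        motifs = extract_motifs(finalize({(3, 8): -2.2}, 10), -2.0, "A" * 10)
        assert len(motifs) == 1
        assert motifs[0].pairs == ((3, 8),)

    def test_sequence_length_checked(self):
        with pytest.raises(ValueError):
            extract_motifs(finalize({(1, 5): -2.0}, 10), -1.0, "ACG")


class TestWriters:
    def test_final_partners_tsv(self):
        per_nt = np.array([-0.5] * 10)
        final = finalize({(2, 9): -2.5}, 10, per_nt_z=per_nt)
        buf = io.StringIO()
        write_final_partners(final, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "position\tpartner\tz\tclass"
        assert lines[2].split("\t") == ["2", "9", "-2.5000", "z<=-2"]
        assert lines[1].split("\t") == ["1", "0", "-0.5000", "z<0"]

    def test_gff3(self):
        final = finalize({(3, 14): -2.1}, 20)
        motifs = extract_motifs(final, -2.0, "A" * 20)
        buf = io.StringIO()
        write_motifs_gff3(motifs, buf, seqid="tx1")
        lines = buf.getvalue().splitlines()
        assert lines[0] == "##gff-version 3"
        cols = lines[1].split("\t")
        assert cols[0] == "tx1" and cols[3] == "3" and cols[4] == "14"
        assert "min_pair_z=-2.1000" in cols[8]

    def test_ct_read_back(self, tmp_path):
        seq = "GGGAAAACCC"
        final = finalize({(1, 10): -2.5, (2, 9): -2.5, (3, 8): -2.5}, 10)
        (motif,) = extract_motifs(final, -2.0, seq)
        path = tmp_path / "m.ct"
        write_motif_ct(motif, path, title="toy")
        ct = read_ct(path)
        assert ct.sequence == seq
        assert ct.partner[0] == 10 and ct.partner[9] == 1
        assert ct.partner[4] == 0

    def test_dbn(self):
        final = finalize({(2, 9): -2.5}, 10)
        (motif,) = extract_motifs(final, -2.0, "ACGUACGUAC")
        buf = io.StringIO()
        write_motif_dbn(motif, buf, title="toy")
        name, seq, db = buf.getvalue().splitlines()
        assert name == ">toy"
        assert len(seq) == len(db) == 8

    def test_arc_track(self):
        final = finalize({(1, 10): -2.0, (3, 8): -0.5}, 10)
        buf = io.StringIO()
        write_arc_track(final, buf)
        lines = buf.getvalue().splitlines()
        assert lines[1] == "1\t10\tz<=-2"
        assert lines[2] == "3\t8\tz<0"
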