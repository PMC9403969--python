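import io

import numpy as np
import pytest

from rnascan.roc import (
    CtStructure,
    ReactivityProfile,
    call_paired_at_percentile,
    confusion,
    read_ct,
    read_reactivity,
    roc_curve,
    single_stranded_share,
    top_fraction_mask,
    write_roc_table,
)


def ct_from_dotbracket(db, sequence=None):
    seq = sequence or "A" * len(db)
    partner = [0] * len(db)
    stack = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            i = stack.pop()
            partner[i] = idx + 1
            partner[idx] = i + 1
    return CtStructure(title="t", sequence=seq, partner=tuple(partner))


def profile(values, **kw):
    return ReactivityProfile(values=np.asarray(values, dtype=float), **kw)


class TestCalls:
    def test_zero_percent_calls_nothing(self):
        calls = call_paired_at_percentile(profile([0.1, 0.2, 0.3]), 0)
        assert not calls.any()

    def test_hundred_percent_calls_all_applicable(self):
        p = profile([0.1, np.nan, 0.3])
        calls = call_paired_at_percentile(p, 100)
        assert calls.tolist() == [True, False, True]

    def test_fifty_percent_lowest_half(self):
        calls = call_paired_at_percentile(profile([0.1, 0.2, 0.3, 0.4]), 50)
        assert calls.tolist() == [True, True, False, False]

    def test_tie_break_by_position(self):
        calls = call_paired_at_percentile(profile([0.5, 0.5, 0.5, 0.5]), 50)
        assert calls.tolist() == [True, True, False, False]

    def test_ac_only_restriction(self):
        p = profile([0.1, 0.2, 0.3, 0.4], ac_only=True)
        calls = call_paired_at_percentile(p, 100, sequence="ACGU")
        assert calls.tolist() == [True, True, False, False]

    def test_range_validation(self):
        with pytest.raises(ValueError):
            call_paired_at_percentile(profile([0.1]), 101)


class TestConfusion:
    def test_all_paired_zero_threshold(self):
        ct = ct_from_dotbracket("((....))")
        calls = np.zeros(8, dtype=bool)
        tp, fn, fp, tn = confusion(ct, calls)
        assert tp == 0 and fn == 4

    def test_hand_case(self):
        # CT: positions 1-2 paired, 3-4 unpaired; calls: 1 and 3 paired
        ct = CtStructure("t", "ACGU", (2, 1, 0, 0))
        calls = np.array([True, False, True, False])
        assert confusion(ct, calls) == (1, 1, 1, 1)

    def test_partition_property(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 40))
            partner = [0] * n
            for _ in range(n // 3):
                i, j = rng.choice(n, 2, replace=False)
                if partner[i] == 0 and partner[j] == 0:
                    partner[i], partner[j] = j + 1, i + 1
            ct = CtStructure("t", "A" * n, tuple(partner))
            calls = rng.random(n) < 0.5
            tp, fn, fp, tn = confusion(ct, calls)
            assert tp + fn == int(ct.paired_mask().sum())
            assert fp + tn == n - int(ct.paired_mask().sum())

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(ct_from_dotbracket("(...)"), np.zeros(4, dtype=bool))


class TestRocCurve:
    def test_endpoints(self):
        ct = ct_from_dotbracket("((....))..")
        p = profile(np.linspace(0, 1, 10))
        curve = roc_curve(ct, p)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[100], curve.tpr[100]) == (1.0, 1.0)

    def test_monotone_sweep(self, rng):
        ct = ct_from_dotbracket("((((....))))..((...))")
        p = profile(rng.random(21))
        curve = roc_curve(ct, p)
        assert np.all(np.diff(curve.tpr) >= -1e-12)
        assert np.all(np.diff(curve.fpr) >= -1e-12)

    def test_perfect_profile_auc_one(self):
        db = "((((....))))....((...))"
        ct = ct_from_dotbracket(db)
        values = [1.0 if c == "." else 0.0 for c in db]
        assert roc_curve(ct, profile(values)).auc == pytest.approx(1.0)

    def test_auc_invariant_under_monotone_transform(self, rng):
        db = "((((....))))...((....))"
        ct = ct_from_dotbracket(db)
        vals = rng.random(len(db))
        a1 = roc_curve(ct, profile(vals)).auc
        a2 = roc_curve(ct, profile(np.exp(3 * vals))).auc
        assert a2 == pytest.approx(a1, abs=1e-12)

    def test_antisymmetry_reversed_convention(self, rng):
        db = "((((....))))...((....))"
        ct = ct_from_dotbracket(db)
        vals = rng.random(len(db))
        # distinct values so rank order is exactly reversed under negation
        a = roc_curve(ct, profile(vals)).auc
        b = roc_curve(ct, profile(-vals)).auc
        assert a + b == pytest.approx(1.0, abs=0.06)

    def test_degenerate_structure_flagged(self):
        ct = ct_from_dotbracket("....")
        curve = roc_curve(ct, profile([0.1, 0.2, 0.3, 0.4]))
        assert curve.degenerate
        assert np.isnan(curve.auc)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            roc_curve(ct_from_dotbracket("(...)"), profile([0.1]))


class TestTopFraction:
    def test_two_of_ten(self):
        vals = [0.1, 0.9, 0.2, 0.8, 0.3, 0.4, 0.5, 0.6, 0.65, 0.05]
        mask = top_fraction_mask(profile(vals), 0.2)
        assert mask.sum() == 2
        assert mask[1] and mask[3]

    def test_all_equal_deterministic(self):
        m1 = top_fraction_mask(profile([0.5] * 10), 0.2)
        m2 = top_fraction_mask(profile([0.5] * 10), 0.2)
        assert np.array_equal(m1, m2)
        assert m1.sum() == 2

    def test_perfect_profile_fully_single_stranded(self):
        db = "((((....))))"
        values = [1.0 if c == "." else 0.0 for c in db]
        mask = top_fraction_mask(profile(values), 4 / 12)
        assert single_stranded_share(mask, db) == 1.0

    def test_share_with_ct(self):
        ct = ct_from_dotbracket("((..))")
        mask = np.array([False, False, True, True, False, False])
        assert single_stranded_share(mask, ct) == 1.0

    def test_empty_mask_nan(self):
        assert np.isnan(single_stranded_share(np.zeros(4, dtype=bool), "...."))

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            top_fraction_mask(profile([0.1]), 0.0)


class TestReaders:
    def test_reactivity_reader_missing_conventions(self):
        buf = io.StringIO("1\t0.5\n2\tNA\n3\t-999\n5\t1.25\n")
        p = read_reactivity(buf)
        assert len(p) == 5
        assert p.values[0] == 0.5
        assert np.isnan(p.values[1]) and np.isnan(p.values[2]) and np.isnan(p.values[3])
        assert p.values[4] == 1.25

    def test_reactivity_empty_rejected(self):
        with pytest.raises(ValueError):
            read_reactivity(io.StringIO(""))

    def test_ct_reader(self):
        text = "4 toy\n1 G 0 2 4 1\n2 A 1 3 0 2\n3 A 2 4 0 3\n4 C 3 0 1 4\n"
        ct = read_ct(io.StringIO(text))
        assert ct.sequence == "GAAC"
        assert ct.partner == (4, 0, 0, 1)
        assert ct.paired_mask().tolist() == [True, False, False, True]

    def test_roc_table_writer(self):
        ct = ct_from_dotbracket("((....))")
        p = profile([0.0, 0.1, 0.9, 0.8, 0.85, 0.95, 0.2, 0.05])
        buf = io.StringIO()
        curve = write_roc_table(ct, p, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0].startswith("threshold")
        assert len(lines) == 103  # header + 101 thresholds + auc
        assert lines[-1].startswith("# auc")
        assert curve.auc == pytest.approx(1.0)
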