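"""Accuracy, chance level, success rate, confusion, subset building."""

import numpy as np
import pytest

import hdemg
from hdemg.metrics import MOVE_CLASS, SubsetSpec, build_subset
from hdemg.preprocess import CenterWindowDataset
from hdemg.simulate import CLASS_INDEX, CueSchedule, Segment


def _schedule(items):
    segs, t = [], 0.0
    for label, d in items:
        segs.append(Segment(label, t, t + d))
        t += d
    return CueSchedule(segments=tuple(segs), lead_in_rest_s=items[0][1])


class TestBinAccuracy:
    def test_identical_and_discordant(self):
        a = np.array([1, 2, 3])
        assert hdemg.bin_accuracy(a, a) == 1.0
        assert hdemg.bin_accuracy(a, a + 1) == 0.0

    def test_hand_count(self):
        pred = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0])
        true = np.array([0, 0, 1, 1, 2, 0, 1, 1, 2, 1])  # 7 matches
        assert hdemg.bin_accuracy(pred, true) == pytest.approx(0.7)

    def test_equals_one_minus_hamming(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 5, 200)
        true = rng.integers(0, 5, 200)
        hamming = np.count_nonzero(pred != true) / 200
        assert hdemg.bin_accuracy(pred, true) == pytest.approx(1 - hamming)

    def test_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            hdemg.bin_accuracy([1, 2], [1])
        with pytest.raises(ValueError):
            hdemg.bin_accuracy([], [])


class TestChanceLevel:
    def test_majority_fraction(self):
        assert hdemg.chance_level([0] * 6 + [1] * 4) == pytest.approx(0.6)

    def test_uniform_13_classes(self):
        assert hdemg.chance_level(list(range(13))) == pytest.approx(1 / 13)

    def test_matches_loop_count(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, 500)
        counts = {c: int(np.sum(labels == c)) for c in range(4)}
        assert hdemg.chance_level(labels) == pytest.approx(max(counts.values()) / 500)


class TestSuccessRate:
    def test_fully_correct_cue_succeeds(self):
        sched = _schedule([("Rest", 4.0), ("Hand Close", 4.0), ("Rest", 4.0)])
        pred = sched.labels_for_bins(120)
        rate, per = hdemg.success_rate(pred, sched)
        assert rate == 1.0
        assert per["Hand Close"] == (1, 1)

    @pytest.mark.parametrize("n_correct,ok", [(9, False), (10, True)])
    def test_one_second_rule_boundary(self, n_correct, ok):
        sched = _schedule([("Rest", 4.0), ("Hand Close", 4.0), ("Rest", 4.0)])
        hc = CLASS_INDEX["Hand Close"]
        pred = np.zeros(120, int)
        pred[41:41 + n_correct] = hc
        rate, _ = hdemg.success_rate(pred, sched)
        assert rate == (1.0 if ok else 0.0)

    def test_hand_scored_five_cue_toy(self):
        items = [("Rest", 4.0)]
        for m in ["Hand Close", "Hand Open", "Wrist Flexion", "Key Pinch", "Hand Close"]:
            items += [(m, 4.0), ("Rest", 4.0)]
        sched = _schedule(items)
        n = int(sched.duration_s / 0.1)
        pred = np.zeros(n, int)
        outcomes = [True, False, True, False, True]  # hand-chosen per cue
        for (seg, ok) in zip([s for s in sched.segments if s.label != "Rest"], outcomes):
            b0 = int(seg.onset_s / 0.1)
            run = 15 if ok else 8
            pred[b0 + 2: b0 + 2 + run] = CLASS_INDEX[seg.label]
        rate, per = hdemg.success_rate(pred, sched)
        assert rate == pytest.approx(3 / 5)
        assert per["Hand Close"] == (2, 2)
        assert per["Hand Open"] == (0, 1)

    def test_run_crossing_cue_edge_does_not_count(self):
        sched = _schedule([("Rest", 4.0), ("Hand Close", 1.5), ("Rest", 4.0)])
        hc = CLASS_INDEX["Hand Close"]
        pred = np.zeros(95, int)
        pred[35:55] = hc  # 20-bin run, but only 15 bins inside the cue
        rate, _ = hdemg.success_rate(pred, sched)
        assert rate == 1.0
        pred2 = np.zeros(95, int)
        pred2[35:48] = hc  # only 8 in-cue bins (40..47)
        rate2, _ = hdemg.success_rate(pred2, sched)
        assert rate2 == 0.0

    def test_monotone_under_corrections(self):
        rng = np.random.default_rng(2)
        sched = _schedule([("Rest", 4.0), ("Hand Close", 4.0), ("Rest", 4.0),
                           ("Hand Open", 4.0), ("Rest", 4.0)])
        true = sched.labels_for_bins(200)
        pred = rng.integers(0, 13, 200)
        rate, _ = hdemg.success_rate(pred, sched)
        # flip 40 wrong bins to correct: the rate may only improve
        wrong = np.flatnonzero(pred != true)
        fix = rng.choice(wrong, size=40, replace=False)
        pred3 = pred.copy()
        pred3[fix] = true[fix]
        rate3, _ = hdemg.success_rate(pred3, sched)
        assert rate3 >= rate


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        true = np.array([0, 0, 1, 1, 2])
        cm = hdemg.confusion(true, true, [0, 1, 2])
        assert np.all(cm == np.diag([2, 2, 1]))

    def test_total_equals_stream_length(self):
        rng = np.random.default_rng(3)
        pred, true = rng.integers(0, 3, 100), rng.integers(0, 3, 100)
        assert hdemg.confusion(pred, true, [0, 1, 2]).sum() == 100

    def test_hand_tally_three_class(self):
        true = [0, 0, 1, 1, 2, 2]
        pred = [0, 1, 1, 1, 0, 2]
        cm = hdemg.confusion(pred, true, [0, 1, 2])
        np.testing.assert_array_equal(cm, [[1, 1, 0], [0, 2, 0], [1, 0, 1]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="class set"):
            hdemg.confusion([0, 9], [0, 0], [0, 1])

    def test_report_invariant_to_class_permutation(self):
        rng = np.random.default_rng(4)
        pred, true = rng.integers(0, 3, 300), rng.integers(0, 3, 300)
        r1 = hdemg.evaluate_predictions(pred, true, class_indices=[0, 1, 2])
        r2 = hdemg.evaluate_predictions(pred, true, class_indices=[2, 0, 1])
        assert r1.bin_accuracy == r2.bin_accuracy
        assert r1.chance_level == r2.chance_level
        assert r1.confusion_matrix.sum() == r2.confusion_matrix.sum()
        for lbl in r1.per_class_accuracy:
            assert r1.per_class_accuracy[lbl] == r2.per_class_accuracy[lbl]


def _toy_dataset():
    """Alternating rest/movement schedule with 4 samples per segment."""
    movements = ["Hand Close", "Hand Open", "Wrist Flexion"]
    items = [("Rest", 4.0)]
    for _ in range(2):
        for m in movements:
            items += [(m, 4.0), ("Rest", 4.0)]
    sched = _schedule(items)
    X, y, bins, segs = [], [], [], []
    for si, seg in enumerate(sched.segments):
        b0 = int(seg.onset_s / 0.1)
        for j in range(4):
            X.append(np.full(8, si, float))
            y.append(CLASS_INDEX[seg.label])
            bins.append(b0 + 3 + j)
            segs.append(si)
    ds = CenterWindowDataset(
        X=np.array(X), y=np.array(y), bin_indices=np.array(bins),
        segment_ids=np.array(segs), width_s=0.7,
    )
    return ds, sched


class TestBuildSubset:
    def test_binary_mode_two_labels_half_rest(self):
        ds, sched = _toy_dataset()
        sub, classes = build_subset(ds, sched, SubsetSpec("binary_rest_move"))
        assert classes == ("Rest", MOVE_CLASS)
        vals = np.unique(sub.y)
        assert vals.size == 2
        rest_frac = np.mean(sub.y == CLASS_INDEX["Rest"])
        assert abs(rest_frac - 0.5) <= 1 / sub.y.size
        assert hdemg.chance_level(sub.y) == pytest.approx(0.5, abs=1 / sub.y.size)

    def test_fixed_three_retains_three_classes(self):
        ds, sched = _toy_dataset()
        sub, classes = build_subset(ds, sched, SubsetSpec("fixed_three"))
        assert classes == ("Rest", "Hand Close", "Hand Open")
        got = {c for c in np.unique(sub.y)}
        assert got == {CLASS_INDEX["Rest"], CLASS_INDEX["Hand Close"], CLASS_INDEX["Hand Open"]}

    def test_top_k_sorts_by_accuracy(self):
        ds, sched = _toy_dataset()
        acc = {"Hand Close": 0.9, "Hand Open": 0.7, "Wrist Flexion": 0.4}
        sub, classes = build_subset(ds, sched, SubsetSpec("top_k", k=2), acc)
        assert set(classes) == {"Rest", "Hand Close", "Hand Open"}

    def test_rest_drawn_from_preceding_cues(self):
        ds, sched = _toy_dataset()
        sub, _ = build_subset(ds, sched, SubsetSpec("top_k", k=1),
                              {"Hand Close": 0.9, "Hand Open": 0.1, "Wrist Flexion": 0.1})
        rest_rows = sub.segment_ids[sub.y == CLASS_INDEX["Rest"]]
        hc_segments = {si for si, s in enumerate(sched.segments) if s.label == "Hand Close"}
        assert set(rest_rows) <= {si - 1 for si in hc_segments}

    def test_k_too_large_rejected(self):
        ds, sched = _toy_dataset()
        with pytest.raises(ValueError, match="exceeds"):
            build_subset(ds, sched, SubsetSpec("top_k", k=9),
                         {"Hand Close": 0.9, "Hand Open": 0.1, "Wrist Flexion": 0.1})
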