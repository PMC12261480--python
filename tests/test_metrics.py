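"""Per-residue metric suite against brute-force oracles."""

import numpy as np
import pytest

from softdis.metrics import (
    ConfusionCounts,
    ScoreProfile,
    confusion,
    coverage_filter,
    f1,
    max_f1,
    mcc,
    metrics_report,
    pr_auc,
    profile_spearman,
    read_prediction_file,
    read_reference_labels,
    roc_auc,
    scores_to_profile,
)


def _profile(scores, labels, key="p"):
    return ScoreProfile(key=key, scores=np.asarray(scores, float), labels=np.asarray(labels))


def brute_force_auc(scores, labels):
    """Pairwise concordance with 0.5 for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_average_precision(scores, labels):
    """AP = sum_k (R_k - R_{k-1}) P_k over descending unique thresholds."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    s = np.asarray(scores)[order]
    y = np.asarray(labels)[order]
    n_pos = int(y.sum())
    ap, tp, fp = 0.0, 0, 0
    prev_recall = 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestConfusion:
    def test_hand_count(self):
        c = confusion(_profile([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0]), threshold=0.5)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_perfect_scores(self):
        c = confusion(_profile([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]))
        assert c.fp == 0 and c.fn == 0

    def test_threshold_boundary_counts_positive(self):
        c = confusion(_profile([0.5], [1]), threshold=0.5)
        assert c.tp == 1

    def test_masked_and_unscored_excluded(self):
        c = confusion(_profile([0.9, np.nan, 0.8], [1, 1, -1]))
        assert c.total == 1

    def test_no_evaluable_errors(self):
        with pytest.raises(ValueError):
            confusion(_profile([np.nan], [1]))

    def test_pooled_equals_sum_of_per_protein(self, rng):
        profiles = [
            _profile(rng.random(20), rng.integers(0, 2, 20), key=f"p{i}")
            for i in range(5)
        ]
        pooled = confusion(profiles)
        summed = ConfusionCounts()
        for p in profiles:
            summed = summed + confusion(p)
        assert pooled == summed


class TestMccF1:
    def test_mcc_formula(self):
        assert mcc(ConfusionCounts(tp=3, fp=1, fn=2, tn=4)) == pytest.approx(
            10 / np.sqrt(600)
        )

    def test_mcc_perfect_and_degenerate(self):
        assert mcc(ConfusionCounts(tp=5, tn=5)) == 1.0
        # all-positive predictor on mixed labels: a zero factor -> 0
        assert mcc(ConfusionCounts(tp=5, fp=5)) == 0.0

    def test_f1_formula(self):
        assert f1(ConfusionCounts(tp=3, fp=1, fn=2, tn=4)) == pytest.approx(6 / 9)
        assert f1(ConfusionCounts()) == 0.0
        assert f1(ConfusionCounts(tp=7)) == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(_profile([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_tie_symmetry(self):
        assert roc_auc(_profile([0.5, 0.5], [1, 0])) == 0.5

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            scores = np.round(rng.random(12), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, 12)
            if labels.sum() in (0, 12):
                labels[0] = 1 - labels[0]
            got = roc_auc(_profile(scores, labels))
            assert got == pytest.approx(brute_force_auc(scores, labels))

    def test_complement_identity(self, rng):
        scores = rng.random(30)  # tie-free almost surely
        labels = np.array([1] * 15 + [0] * 15)
        a = roc_auc(_profile(scores, labels))
        b = roc_auc(_profile(1 - scores, labels))
        assert a + b == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        transformed = scores**3 / (scores**3 + (1 - scores) ** 3)
        assert roc_auc(_profile(scores, labels)) == pytest.approx(
            roc_auc(_profile(transformed, labels))
        )

    def test_single_class_error_names_missing_class(self):
        with pytest.raises(ValueError, match="negative"):
            roc_auc(_profile([0.2, 0.4], [1, 1]))
        with pytest.raises(ValueError, match="positive"):
            roc_auc(_profile([0.2, 0.4], [0, 0]))


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc(_profile([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_all_equal_scores_gives_prevalence(self):
        # a single tie group: AP collapses to the positive prevalence
        labels = [1, 0, 0, 1, 0, 0, 0, 0, 1, 0]
        got = pr_auc(_profile([0.5] * 10, labels))
        assert got == pytest.approx(0.3)

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            scores = np.round(rng.random(15), 1)
            labels = rng.integers(0, 2, 15)
            if labels.sum() == 0:
                labels[0] = 1
            got = pr_auc(_profile(scores, labels))
            assert got == pytest.approx(
                brute_force_average_precision(scores, labels)
            )

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            pr_auc(_profile([0.2], [0]))


class TestMaxF1:
    def test_dominates_fixed_threshold(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        best, _ = max_f1(_profile(scores, labels))
        assert best >= f1(confusion(_profile(scores, labels), 0.5)) - 1e-12

    def test_exhaustive_grid_oracle(self, rng):
        scores = np.round(rng.random(20), 2)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        best, best_t = max_f1(_profile(scores, labels), step=0.01)
        # oracle: explicit scan over the same grid
        expected = []
        for k in range(101):
            t = k * 0.01
            pred = scores >= t
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            fn = int((~pred & (labels == 1)).sum())
            expected.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
        assert best == pytest.approx(max(expected))
        assert best_t == pytest.approx(0.01 * int(np.argmax(expected)))

    def test_separated_pair(self):
        best, t = max_f1(_profile([0.3, 0.7], [0, 1]))
        assert best == 1.0
        # the smallest grid threshold separating 0.3 from 0.7
        assert t == pytest.approx(0.31)

    def test_constant_scores_collapse_to_all_positive(self):
        labels = [1, 0, 1, 0, 0]
        best, _ = max_f1(_profile([0.4] * 5, labels))
        c = ConfusionCounts(tp=2, fp=3, fn=0, tn=0)
        assert best == pytest.approx(f1(c))


class TestCoverageFilter:
    def test_fully_scored_retained(self):
        profiles = [_profile([0.1, 0.9], [0, 1], key=f"p{i}") for i in range(3)]
        kept, frac = coverage_filter(profiles, 1.0)
        assert len(kept) == 3 and frac == 1.0

    def test_half_scored_dropped_at_full_coverage(self):
        full = _profile([0.1, 0.9], [0, 1], key="full")
        half = _profile([0.1, np.nan], [0, 1], key="half")
        kept, frac = coverage_filter([full, half], 1.0)
        assert [p.key for p in kept] == ["full"]
        assert frac == pytest.approx(0.5)

    def test_retained_fraction_recount(self, rng):
        profiles = []
        for i in range(6):
            n = int(rng.integers(5, 15))
            scores = rng.random(n)
            scores[rng.random(n) < 0.3] = np.nan
            profiles.append(_profile(scores, rng.integers(0, 2, n), key=f"p{i}"))
        kept, frac = coverage_filter(profiles, 0.6)
        total = sum(len(p) for p in profiles)
        retained = sum(len(p) for p in kept)
        assert frac == pytest.approx(retained / total)


class TestProfileSpearman:
    def test_identical_tracks(self):
        t = np.array([0.1, 0.5, 0.3, 0.9])
        assert profile_spearman(t, t) == pytest.approx(1.0)

    def test_rank_reversal(self):
        t = np.array([0.1, 0.5, 0.3, 0.9])
        assert profile_spearman(t, -t) == pytest.approx(-1.0)

    def test_matches_rank_formula(self, rng):
        a, b = rng.random(10), rng.random(10)
        # oracle: Spearman = Pearson on midranks
        def midrank(x):
            order = np.argsort(x)
            ranks = np.empty(len(x))
            ranks[order] = np.arange(1, len(x) + 1)
            for v in np.unique(x):
                sel = x == v
                ranks[sel] = ranks[sel].mean()
            return ranks

        ra, rb = midrank(a), midrank(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert profile_spearman(a, b) == pytest.approx(expected)

    def test_joint_mask_removal_and_length_checks(self):
        a = np.array([0.1, np.nan, 0.3, 0.9, 0.2])
        b = np.array([0.2, 0.5, np.nan, 0.8, 0.1])
        # surviving pairs (1,3,4): ranks a=[1,3,2], b=[2,3,1] -> rho = 0.5
        assert profile_spearman(a, b) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            profile_spearman(a, b[:4])
        with pytest.raises(ValueError):
            profile_spearman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestIO:
    def test_prediction_file_and_reference_labels(self, tmp_path):
        pred = tmp_path / "pred.caid"
        pred.write_text(">prot1\n1\tM\t0.91\t1\n2\tK\t0.15\t0\n4\tL\t0.30\n")
        scores = read_prediction_file(pred)
        assert scores == {1: 0.91, 2: 0.15, 4: 0.30}
        ref = tmp_path / "ref.fasta"
        ref.write_text(">prot1\n10-11\n")
        labels = read_reference_labels(ref)["prot1"]
        np.testing.assert_array_equal(labels, [1, 0, -1, 1, 1])
        profile = scores_to_profile("prot1", 5, scores, labels)
        c = confusion(profile)
        # evaluable: 1 (tp), 2 (tn), 4 (fn); 3 is masked, 5 unscored
        assert (c.tp, c.tn, c.fn, c.fp) == (1, 1, 1, 0)

    def test_out_of_range_index_errors(self):
        with pytest.raises(ValueError):
            scores_to_profile("p", 3, {4: 0.5}, np.array([0, 1, 0]))

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            _profile([1.2], [1])


def test_metrics_report_consistency(rng):
    profiles = [
        _profile(rng.random(30), rng.integers(0, 2, 30), key=f"p{i}") for i in range(4)
    ]
    rep = metrics_report(profiles)
    assert rep["n_residues"] == 120
    assert rep["tp"] + rep["fp"] + rep["fn"] + rep["tn"] == 120
    assert 0.0 <= rep["roc_auc"] <= 1.0
    assert rep["max_f1"] >= rep["f1"] - 1e-12
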