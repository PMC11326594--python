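"""Evaluation statistics: confusion diagnostics, AUC oracle, agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from folliscan.evaluate import (
    ConfusionMatrix,
    confusion,
    group_feature_stats,
    metrics,
    percent_difference,
    roc_auc,
    segmentation_agreement,
)


class TestConfusion:
    def test_perfect_predictions(self):
        y = ["PCOS"] * 10 + ["normal"] * 10
        cm = confusion(y, y)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 10)

    def test_all_predicted_positive(self):
        y_true = ["PCOS"] * 10 + ["normal"] * 10
        cm = confusion(y_true, ["PCOS"] * 20)
        assert cm.fp == 10 and cm.fn == 0

    def test_counts_conserve_n(self, rng):
        labels = np.array(["PCOS", "normal"])
        y_true = labels[rng.integers(0, 2, 50)]
        y_pred = labels[rng.integers(0, 2, 50)]
        assert confusion(y_true, y_pred).total == 50

    def test_unknown_label_and_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["PCOS"], ["cystic"])
        with pytest.raises(ValueError):
            confusion(["PCOS", "normal"], ["PCOS"])


class TestMetrics:
    def test_perfect_matrix(self):
        rep = metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=10))
        pct = rep.as_percent()
        assert pct["accuracy"] == 100.0
        assert pct["fdr"] == 0.0 and pct["fom"] == 0.0

    def test_undefined_ratios_reported_absent(self):
        rep = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=5))
        assert rep.precision is None and rep.recall is None
        assert rep.fdr is None
        assert rep.accuracy == 1.0

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(deadline=None, max_examples=300)
    def test_complementarity_identities(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        rep = metrics(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
        if tp + fp > 0:
            assert rep.precision + rep.fdr == pytest.approx(1.0)
        if tn + fn > 0:
            assert rep.npv + rep.fom == pytest.approx(1.0)


def _pair_count_auc(scores, labels):
    """Brute-force probability that a PCOS score outranks a normal score."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(str)
    pos, neg = s[y == "PCOS"], s[y == "normal"]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_and_inverted_and_tied(self):
        y = ["PCOS"] * 5 + ["normal"] * 5
        assert roc_auc(np.r_[np.ones(5), np.zeros(5)], y)[0] == 1.0
        assert roc_auc(np.r_[np.zeros(5), np.ones(5)], y)[0] == 0.0
        assert roc_auc(np.zeros(10), y)[0] == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(5):
            n = 60
            y = np.where(rng.random(n) < 0.5, "PCOS", "normal")
            if len(set(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # coarse scores force ties
            auc, _, _ = roc_auc(s, y)
            assert auc == pytest.approx(_pair_count_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["PCOS", "PCOS"])


class TestGroupStats:
    def test_published_percent_difference_examples(self):
        assert percent_difference(0.81, 0.60) == pytest.approx(35.0)
        assert percent_difference(31.35, 25.61) == pytest.approx(22.4, abs=0.05)

    def test_zero_denominator_guidance(self):
        with pytest.raises(ZeroDivisionError):
            percent_difference(1.0, 0.0)

    def test_identical_groups_are_indistinguishable(self, rng):
        vals = rng.random(10)
        cmp = group_feature_stats({"energy": vals}, {"energy": vals.copy()})
        row = cmp.row("energy")
        assert row.percent_difference == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_separated_groups_have_small_p(self, rng):
        a = rng.normal(10, 0.5, 30)
        b = rng.normal(5, 0.5, 30)
        row = group_feature_stats({"f": a}, {"f": b}).row("f")
        assert row.p_value < 1e-6
        assert row.percent_difference == pytest.approx(100.0, abs=15)


def _disk(r, size=60):
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= r**2


class TestAgreement:
    def test_identical_masks_have_zero_distance_and_unit_r(self):
        masks = [_disk(r) for r in (5, 9, 13, 17)]
        rep = segmentation_agreement(masks, [m.copy() for m in masks], pixel_spacing=0.2)
        assert rep.mean_distance_mm == 0.0
        assert rep.sd_distance_mm == 0.0
        assert rep.r == pytest.approx(1.0)

    def test_one_pixel_dilation_costs_about_one_pixel(self):
        gt = _disk(12)
        dilated = ndimage.binary_dilation(gt)
        rep = segmentation_agreement([dilated], [gt], pixel_spacing=0.2)
        assert rep.mean_distance_mm == pytest.approx(1.0 * 0.2, abs=0.08)

    def test_empty_masks_are_skipped_and_counted(self):
        rep = segmentation_agreement(
            [_disk(6), np.zeros((60, 60), bool)], [_disk(6), _disk(6)], pixel_spacing=0.2
        )
        assert rep.n_pairs == 1 and rep.n_skipped == 1

    def test_r_stays_in_unit_interval(self, rng):
        masks_a = [_disk(int(r)) for r in rng.integers(4, 20, 6)]
        masks_b = [_disk(int(r)) for r in rng.integers(4, 20, 6)]
        rep = segmentation_agreement(masks_a, masks_b, pixel_spacing=0.2)
        assert rep.r is None or -1.0 <= rep.r <= 1.0
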