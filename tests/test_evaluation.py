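"""Evaluation stack: OKS, AP/AR, ICC(2,1), deviation stats, t-tests."""

import math

import numpy as np
import pytest

from kneeqc.evaluation import (
    COCO_THRESHOLDS,
    OKSConfig,
    deviation_stats,
    icc_2_1,
    keypoint_ap_ar,
    oks,
    two_sample_t,
)
from kneeqc.geometry import LABELS, Keypoint, KeypointSet, Point2D, View


def _set(points, view=View.LAT):
    return KeypointSet.from_points(view, points)


def _nine_points(spread=60.0):
    return {lab: (10 + spread * i / 8, 15 + (spread / 2) * ((i * 3) % 9) / 8) for i, lab in enumerate(LABELS)}


class TestOKS:
    def test_exact_prediction_scores_one(self):
        gt = _set(_nine_points())
        assert oks(gt, gt) == pytest.approx(1.0)

    def test_characteristic_distance_gives_inverse_e(self):
        """A single keypoint displaced by d with d^2 = 2 s^2 k^2 scores e^-1."""
        gt = _set({"C": (10, 10), "A": (0, 0), "B": (40, 30)})  # A, B fix the scale box
        xs = [0, 40]
        ys = [0, 30]
        s2 = (max(xs) - min(xs)) * (max(ys) - min(ys))
        k_c = 2 * 0.029
        d = math.sqrt(2 * s2 * k_c**2)
        pred = _set({"C": (10 + d, 10), "A": (0, 0), "B": (40, 30)})
        expected = (math.exp(-1.0) + 2.0) / 3.0  # A and B are exact
        assert oks(pred, gt) == pytest.approx(expected, abs=1e-12)

    def test_default_k_for_head_keypoint(self):
        cfg = OKSConfig()
        assert cfg.k[LABELS.index("C")] == pytest.approx(0.058)

    def test_missing_prediction_contributes_zero(self):
        gt = _set({"A": (0, 0), "B": (40, 30)})
        pred = _set({"A": (0, 0)})
        assert oks(pred, gt) == pytest.approx(0.5)

    def test_translation_and_scale_invariance(self, rng):
        gt_pts = _nine_points()
        pred_pts = {lab: (x + rng.normal(0, 2), y + rng.normal(0, 2)) for lab, (x, y) in gt_pts.items()}
        base = oks(_set(pred_pts), _set(gt_pts))
        for _ in range(25):
            s, tx, ty = rng.uniform(0.2, 8), rng.uniform(-300, 300), rng.uniform(-300, 300)
            gt_t = _set({lab: (s * x + tx, s * y + ty) for lab, (x, y) in gt_pts.items()})
            pred_t = _set({lab: (s * x + tx, s * y + ty) for lab, (x, y) in pred_pts.items()})
            assert oks(pred_t, gt_t) == pytest.approx(base, abs=1e-12)

    def test_strictly_decreasing_in_single_error(self):
        gt = _set(_nine_points())
        prev = 1.0
        for d in (1, 2, 4, 8, 16):
            pts = _nine_points()
            pts["E"] = (pts["E"][0] + d, pts["E"][1])
            val = oks(_set(pts), gt)
            assert val < prev
            prev = val

    def test_degenerate_bbox_rejected(self):
        gt = _set({"A": (5, 5), "B": (5, 9)})  # zero-width box
        with pytest.raises(ValueError, match="degenerate"):
            oks(gt, gt)


def bruteforce_pr_metrics(oks_vals, confs, thresholds=COCO_THRESHOLDS):
    """Independent PR enumeration: rank by confidence, walk the list, take the
    101-point interpolated area under the precision envelope."""
    oks_vals = list(oks_vals)
    confs = list(confs)
    n = len(oks_vals)
    aps, ars = [], []
    for t in thresholds:
        ranked = sorted(range(n), key=lambda i: (-confs[i], i))
        pr = []
        tp = 0
        for rank, i in enumerate(ranked, start=1):
            tp += oks_vals[i] >= t
            pr.append((tp / n, tp / rank))  # (recall, precision)
        ap = 0.0
        for r in [i / 100 for i in range(101)]:
            candidates = [p for (rec, p) in pr if rec >= r - 1e-12]
            ap += max(candidates) if candidates else 0.0
        aps.append(ap / 101)
        ars.append(tp / n)
    return float(np.mean(aps)), float(np.mean(ars))


class TestAPAR:
    def _cases(self, oks_targets, confs):
        """Build (pred, conf, gt) cases whose OKS values hit given targets."""
        cases = []
        for target, conf in zip(oks_targets, confs):
            gt_pts = {"A": (0.0, 0.0), "B": (40.0, 30.0)}
            gt = _set(gt_pts)
            if target >= 1.0:
                pred = gt
            else:
                # displace A so that mean of (exp term, 1) equals the target
                k_a = 2 * 0.083
                d = math.sqrt(-2 * 1200 * k_a**2 * math.log(2 * target - 1))
                pred = _set({"A": (d, 0.0), "B": (40.0, 30.0)})
            cases.append((pred, conf, gt))
        return cases

    def test_perfect_predictions(self):
        cases = self._cases([1.0] * 5, [0.9] * 5)
        met = keypoint_ap_ar(cases)
        assert met.mAP == met.AP50 == met.AP75 == met.mAR == 1.0

    def test_threshold_bracketing(self):
        cases = self._cases([0.6] * 4, [0.5] * 4)
        met = keypoint_ap_ar(cases)
        assert met.AP50 == pytest.approx(1.0)
        assert met.AP75 == pytest.approx(0.0)

    def test_matches_bruteforce_enumeration(self, rng):
        """mAP/mAR equal an independent PR enumeration on all sets of size <= 6."""
        for n in range(1, 7):
            for _ in range(20):
                targets = rng.uniform(0.52, 0.99, size=n)
                confs = np.round(rng.uniform(0, 1, size=n), 2)  # ties likely
                cases = self._cases(targets, confs)
                met = keypoint_ap_ar(cases)
                exp_map, exp_mar = bruteforce_pr_metrics(
                    [oks(p, g) for p, _, g in cases], confs
                )
                assert met.mAP == pytest.approx(exp_map, abs=1e-12)
                assert met.mAR == pytest.approx(exp_mar, abs=1e-12)

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            keypoint_ap_ar([])


class TestICC:
    matrix = np.array([[7.0, 9.0], [5.0, 6.0], [8.0, 8.0], [4.0, 5.0], [6.0, 8.0], [9.0, 10.0]])

    def test_matches_explicit_anova_decomposition(self):
        """Estimate equals the mean-squares formula computed by raw loops."""
        x = self.matrix
        n, k = x.shape
        grand = x.mean()
        msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
        msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
        sse = sum(
            (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
            for i in range(n)
            for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        est, _ = icc_2_1(x)
        assert est == pytest.approx(expected, abs=1e-10)
        assert est == pytest.approx(0.7773279352226721, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = self.matrix
        df = pd.DataFrame(
            {
                "subj": np.repeat(range(len(x)), 2),
                "rater": ["a", "b"] * len(x),
                "score": x.ravel(),
            }
        )
        row = pg.intraclass_corr(df, "subj", "rater", "score").set_index("Type").loc["ICC(A,1)"]
        est, ci = icc_2_1(x)
        assert est == pytest.approx(float(row["ICC"]), abs=1e-9)
        assert ci[0] == pytest.approx(row["CI95"][0], abs=5e-3)
        assert ci[1] == pytest.approx(row["CI95"][1], abs=5e-3)

    def test_identical_raters_give_one(self):
        x = np.column_stack([self.matrix[:, 0], self.matrix[:, 0]])
        est, ci = icc_2_1(x)
        assert est == pytest.approx(1.0)
        assert ci[0] <= est <= ci[1] + 1e-12

    def test_bias_penalized_by_absolute_agreement(self):
        est0, _ = icc_2_1(self.matrix)
        shifted = np.column_stack([self.matrix[:, 0], self.matrix[:, 1] + 10.0])
        est1, _ = icc_2_1(shifted)
        assert est1 < est0

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            icc_2_1(np.full((6, 2), 3.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(self.matrix[:3])

    def test_recovers_population_icc(self):
        """Subject effect + rater bias + noise: estimate ~ analytic ICC."""
        sig_s2, sig_b2, sig_e2 = 4.0, 0.5, 0.5
        pop_icc = sig_s2 / (sig_s2 + sig_b2 + sig_e2)  # 0.8
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(20):
            subj = rng.normal(0, math.sqrt(sig_s2), size=500)
            bias = rng.normal(0, math.sqrt(sig_b2), size=2)
            x = subj[:, None] + bias[None, :] + rng.normal(0, math.sqrt(sig_e2), (500, 2))
            estimates.append(icc_2_1(x)[0])
        assert np.mean(estimates) == pytest.approx(pop_icc, abs=0.03)


class TestDeviationStats:
    def test_normalized_display_matches_printed_arithmetic(self):
        """Degrees / 180 rounded to 3 decimals: 1.049 -> 0.006, 3.730 -> 0.021."""
        assert round(1.049 / 180, 3) == 0.006  # layout of the reported table
        pairs = [(0.0, 1.049)]
        st = deviation_stats(pairs, normalization_range=180.0)
        assert st.mean == pytest.approx(1.049)
        assert st.normalized[0] == 0.006
        st2 = deviation_stats([(0.0, 3.730)], normalization_range=180.0)
        assert st2.normalized[2] == 0.021

    def test_identical_pairs_are_zero(self):
        st = deviation_stats([(3.0, 3.0), (7.0, 7.0)], normalization_range=180.0)
        assert (st.mean, st.sd, st.max) == (0.0, 0.0, 0.0)
        assert st.normalized == (0.0, 0.0, 0.0)

    def test_sample_sd_uses_n_minus_one(self):
        st = deviation_stats([(0.0, 1.0), (0.0, 3.0)])
        assert st.mean == 2.0
        assert st.sd == pytest.approx(math.sqrt(2.0))  # ddof=1
        assert st.max == 3.0
        assert st.normalized is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            deviation_stats([])


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_closed_form_pooled_variance(self):
        """x=(1,2,3), y=(4,5,6): t = -3/sqrt(2/3), p from t(4)."""
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346141747673, abs=1e-12)
        assert p == pytest.approx(0.021311641128756713, abs=1e-12)

    def test_antisymmetry(self):
        t1, p1 = two_sample_t([1, 2, 3], [4, 5, 7])
        t2, p2 = two_sample_t([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_constant_equal_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2.0], [2.0, 2.0])
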