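"""Evaluation statistics: Dice analytics, landmark MAD, the
absolute-agreement ICC against a brute-force ANOVA oracle and
pingouin's independent implementation, grading, success bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinemetrics.landmarks import LandmarkSet
from spinemetrics.metrics import (
    IccResult,
    RatingsMatrix,
    dice_f1,
    grade_reliability,
    icc_absolute_agreement,
    landmark_mad,
    success_report,
)


def brute_force_icc_a1(x: np.ndarray) -> float:
    """Independent oracle: explicit sums-of-squares ANOVA, ICC(A,1)."""
    n, k = x.shape
    grand = x.mean()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((30, 30)) > 0.5
        assert dice_f1(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = a.copy()
        a[:5] = True
        b[5:] = True
        assert dice_f1(a, b) == 0.0

    def test_constructed_half_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:5, 0:20] = True  # area 100
        b[2:7, 0:20] = True  # area 100, overlap rows 2-4 = 60 px
        # direct set counting: 2*60 / 200
        assert dice_f1(a, b) == pytest.approx(0.6)

    def test_both_empty_convention(self):
        z = np.zeros((5, 5), bool)
        assert dice_f1(z, z) == 1.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = r.random((12, 12)) > 0.6
        b = r.random((12, 12)) > 0.4
        assert dice_f1(a, b) == dice_f1(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_f1(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestLandmarkMad:
    def test_identical_sets_are_zero(self, default_geometry):
        ls = LandmarkSet.from_geometry(default_geometry)
        mad, sd, n = landmark_mad(ls, ls, view="frontal")
        assert mad == 0.0 and sd == 0.0 and n > 70

    def test_uniform_offset_gives_pythagorean_mad(self, default_geometry):
        true = LandmarkSet.from_geometry(default_geometry)
        pred = LandmarkSet.from_dict(true.to_dict())
        for lvl, corners in pred.vertebrae["frontal"].items():
            pred.vertebrae["frontal"][lvl] = {
                k: (x + 3.0, y + 4.0) for k, (x, y) in corners.items()
            }
        pred.sacral["frontal"] = {
            k: (x + 3.0, y + 4.0) for k, (x, y) in pred.sacral["frontal"].items()
        }
        pred.femoral["frontal"]["centers"] = [
            (x + 3.0, y + 4.0) for x, y in pred.femoral["frontal"]["centers"]
        ]
        pred.femoral["frontal"]["hip_axis_midpoint"] = tuple(
            np.add(pred.femoral["frontal"]["hip_axis_midpoint"], (3.0, 4.0))
        )
        mad, sd, _ = landmark_mad(pred, true, view="frontal")
        assert mad == pytest.approx(5.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_loop(self, default_geometry, rng):
        true = LandmarkSet.from_geometry(default_geometry)
        pred = LandmarkSet.from_dict(true.to_dict())
        ref = []
        for lvl, corners in pred.vertebrae["lateral"].items():
            out = {}
            for k, (x, y) in corners.items():
                dx, dy = rng.normal(0, 1, 2)
                out[k] = (x + dx, y + dy)
                ref.append(np.hypot(dx, dy))
            pred.vertebrae["lateral"][lvl] = out
        mad, sd, n = landmark_mad(pred, true, view="lateral", region="total")
        # sacral/femoral unperturbed -> extra zeros in the mean
        ref += [0.0] * (n - len(ref))
        assert mad == pytest.approx(np.mean(ref), rel=1e-9)

    def test_region_filters(self, default_geometry):
        ls = LandmarkSet.from_geometry(default_geometry)
        _, _, n_th = landmark_mad(ls, ls, view="lateral", region="thoracic")
        _, _, n_lu = landmark_mad(ls, ls, view="lateral", region="lumbar")
        assert n_th == 13 * 4 and n_lu == 5 * 4


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(8.0)[:, None], (1, 3))
        res = icc_absolute_agreement(RatingsMatrix(x))
        assert res.icc == pytest.approx(1.0)
        assert res.grade == "excellent"

    def test_offset_rater_below_consistency_form(self, rng):
        base = rng.normal(0, 3, size=(12, 1))
        x = np.hstack([base, base + 2.0])
        res = icc_absolute_agreement(RatingsMatrix(x))
        # consistency form ignores the systematic offset entirely
        n, k = x.shape
        grand = x.mean()
        msr = k * np.sum((x.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((x.mean(0) - grand) ** 2) / (k - 1)
        sse = np.sum((x - grand) ** 2) - (n - 1) * msr / k * k - (k - 1) * msc / n * n
        mse = (np.sum((x - grand) ** 2) - k * np.sum((x.mean(1) - grand) ** 2)
               - n * np.sum((x.mean(0) - grand) ** 2)) / ((n - 1) * (k - 1))
        icc_consistency = (msr - mse) / (msr + (k - 1) * mse)
        assert res.icc < 1.0
        assert res.icc < icc_consistency

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 31))
            k = int(rng.integers(2, 6))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = icc_absolute_agreement(RatingsMatrix(x))
            assert res.icc == pytest.approx(brute_force_icc_a1(x), abs=1e-8)
            assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_matches_pingouin_independent_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(5):
            n, k = 12, 3
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
            res = icc_absolute_agreement(RatingsMatrix(x))
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), k),
                    "raters": np.tile(np.arange(k), n),
                    "ratings": x.ravel(),
                }
            )
            out = pg.intraclass_corr(
                data=df, targets="targets", raters="raters", ratings="ratings"
            )
            row = out[out["Type"] == "ICC(A,1)"].iloc[0]
            assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
            # pingouin rounds its CI to 2 decimals
            assert res.ci95[0] == pytest.approx(row["CI95"][0], abs=0.01)
            assert res.ci95[1] == pytest.approx(row["CI95"][1], abs=0.01)

    def test_invariances(self, rng):
        x = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        base = icc_absolute_agreement(RatingsMatrix(x)).icc
        perm = rng.permutation(10)
        assert icc_absolute_agreement(RatingsMatrix(x[perm])).icc == pytest.approx(
            base, abs=1e-12
        )
        assert icc_absolute_agreement(
            RatingsMatrix(x + 7.5)
        ).icc == pytest.approx(base, abs=1e-9)

    def test_constant_matrix_degenerate(self):
        res = icc_absolute_agreement(RatingsMatrix(np.full((6, 3), 4.2)))
        assert res.degenerate and res.icc == 1.0

    def test_missing_cells_dropped_and_counted(self):
        x = np.arange(15.0).reshape(5, 3)
        x[2, 1] = np.nan
        m = RatingsMatrix(x)
        assert m.n_dropped == 1 and m.values.shape == (4, 3)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            RatingsMatrix(np.ones((1, 3)))


class TestGrades:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.95, "excellent"),
            (0.9, "excellent"),
            (0.75, "good"),
            (0.89, "good"),
            (0.5, "moderate"),
            (0.74, "moderate"),
            (0.49, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_scale(self, value, grade):
        assert grade_reliability(value) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade_reliability(1.5)


class TestSuccessReport:
    def _fake_result(self, contained=True, ok=True):
        class R:
            pass

        r = R()
        r.preprocess_contained = contained
        r.preprocess_success = {
            "frontal": {"neck": True, "spine": contained, "sacrum": True,
                        "femur": True},
            "lateral": {"neck": True, "spine": True, "sacrum": True,
                        "femur": True},
        }
        r.parameters = object() if ok else None
        r.reasonable = ok
        return r

    def test_all_pass_cohort(self):
        rep = success_report([self._fake_result() for _ in range(5)])
        assert rep["preprocess_correct"] == 5
        assert rep["reasonable_segmentation"] == 5
        assert rep["parameter_predictions"] == 5

    def test_planted_failures_counted(self):
        cohort = [self._fake_result() for _ in range(4)] + [
            self._fake_result(contained=False, ok=False)
        ]
        rep = success_report(cohort)
        assert rep["preprocess_correct"] == 4
        assert rep["reasonable_segmentation"] == 4
        assert rep["parameter_predictions"] == 4
        assert rep["roi_window_success"]["frontal"]["spine"] == 4
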