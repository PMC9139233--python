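"""Statistics suite: golden clinical-table values, oracle equivalences,
exact binomial CIs, Passing–Bablok regression, dilution error rules.

Golden rows embed the published count cells (TP/TN/FP/FN or raw counts) of
the clinical validation tables together with their printed derived values;
each derived value is recomputed from the counts and compared at the
precision it was printed with (half-up).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from mrdflow.evaluate import (
    REPORTED_POPULATIONS,
    class_metrics,
    confusion,
    dilution_errors,
    exact_binomial_ci,
    passing_bablok,
    pearson_r,
    population_of,
    roc_auc,
    status_table,
)

# --------------------------------------------------------------------------
# Golden per-class metric rows: full-cohort network test-split performance
# (population, TP, TN, FP, FN, printed {metric: value-string}).

F_DNN_ROWS = [
    ("CLL cells", 1_316_803, 24_331_391, 13_539, 9_865,
     {"accuracy": "0.9991", "sensitivity": "0.9926", "specificity": "0.9994",
      "PPV": "0.9898", "NPV": "0.9996", "F1": "0.9912"}),
    ("Polytypic B cells", 195_925, 25_464_627, 6_582, 4_464,
     {"accuracy": "0.9996", "sensitivity": "0.9777", "specificity": "0.9997",
      "PPV": "0.9675", "NPV": "0.9998", "F1": "0.9726"}),
    ("Hematogones", 93_642, 25_569_274, 5_298, 3_384,
     {"accuracy": "0.9997", "sensitivity": "0.9651", "specificity": "0.9998",
      "PPV": "0.9465", "NPV": "0.9999", "F1": "0.9557"}),
    ("Plasma cells", 11_033, 25_654_446, 2_914, 3_205,
     {"accuracy": "0.9998", "sensitivity": "0.7749", "specificity": "0.9999",
      "PPV": "0.7911", "NPV": "0.9999", "F1": "0.7829"}),
    ("T cells", 2_697_327, 22_909_067, 37_470, 27_734,
     {"accuracy": "0.9975", "sensitivity": "0.9898", "specificity": "0.9984",
      "PPV": "0.9863", "NPV": "0.9988", "F1": "0.9881"}),
    ("Aggregates", 1_739_028, 23_610_304, 149_637, 172_629,
     {"accuracy": "0.9874", "sensitivity": "0.9097", "specificity": "0.9937",
      "PPV": "0.9208", "NPV": "0.9927", "F1": "0.9152"}),
    ("Debris", 3_611_475, 21_611_955, 185_744, 262_424,
     {"accuracy": "0.9825", "sensitivity": "0.9323", "specificity": "0.9915",
      "PPV": "0.9511", "NPV": "0.988", "F1": "0.9416"}),
    ("Other cell categories", 15_297_918, 9_841_675, 307_263, 224_742,
     {"accuracy": "0.9793", "sensitivity": "0.9855", "specificity": "0.9697",
      "PPV": "0.9803", "NPV": "0.9777", "F1": "0.9829"}),
]

# Low-count network test-split performance.
L_DNN_ROWS = [
    ("CLL cells", 1_358, 18_210_402, 184, 322,
     {"accuracy": "1.0000", "sensitivity": "0.8083", "specificity": "1.0000",
      "PPV": "0.8807", "NPV": "1.0000", "F1": "0.8430"}),
    ("Polytypic B cells", 177_419, 18_027_561, 4_405, 2_881,
     {"accuracy": "0.9996", "sensitivity": "0.9840", "specificity": "0.9998",
      "PPV": "0.9758", "NPV": "0.9998", "F1": "0.9799"}),
    ("Hematogones", 70_908, 18_135_313, 3_494, 2_551,
     {"accuracy": "0.9997", "sensitivity": "0.9653", "specificity": "0.9998",
      "PPV": "0.9530", "NPV": "0.9999", "F1": "0.9591"}),
    ("Plasma cells", 10_749, 18_196_392, 2_426, 2_699,
     {"accuracy": "0.9997", "sensitivity": "0.7993", "specificity": "0.9999",
      "PPV": "0.8159", "NPV": "0.9999", "F1": "0.8075"}),
    ("T cells", 1_943_032, 16_226_465, 23_739, 19_030,
     {"accuracy": "0.9977", "sensitivity": "0.9903", "specificity": "0.9985",
      "PPV": "0.9879", "NPV": "0.9988", "F1": "0.9891"}),
    ("Aggregates", 1_213_909, 16_810_440, 82_813, 105_104,
     {"accuracy": "0.9897", "sensitivity": "0.9203", "specificity": "0.9951",
      "PPV": "0.9361", "NPV": "0.9938", "F1": "0.9281"}),
    ("Debris", 2_585_138, 15_324_944, 145_941, 156_243,
     {"accuracy": "0.9834", "sensitivity": "0.9430", "specificity": "0.9906",
      "PPV": "0.9466", "NPV": "0.9899", "F1": "0.9448"}),
    ("Other cell categories", 11_750_260, 6_094_852, 196_491, 170_663,
     {"accuracy": "0.9798", "sensitivity": "0.9857", "specificity": "0.9688",
      "PPV": "0.9836", "NPV": "0.9728", "F1": "0.9846"}),
]


def _printed_tolerance(printed: str) -> float:
    # One ulp of the printed precision: a few published cells are truncated
    # rather than half-up rounded (e.g. an F1 of 0.92816 printed as 0.9281).
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return 10.0 ** (-decimals)


@pytest.mark.parametrize(
    "row", F_DNN_ROWS + L_DNN_ROWS, ids=lambda r: r[0].replace(" ", "_")
)
def test_class_metrics_reproduce_printed_clinical_rows(row):
    """Derived ratios recomputed from printed count cells match every printed
    cell at its printed precision."""
    pop, tp, tn, fp, fn, printed = row
    out = class_metrics({"TP": tp, "TN": tn, "FP": fp, "FN": fn})
    for metric, text in printed.items():
        got = float(out[metric].iloc[0])
        assert got == pytest.approx(
            float(text), abs=_printed_tolerance(text)
        ), f"{pop} {metric}: computed {got:.6f}, printed {text}"


class TestClassMetricsEdge:
    def test_perfect_singleton_all_metrics_one(self):
        out = class_metrics({"TP": 1, "TN": 1, "FP": 0, "FN": 0})
        for m in ("accuracy", "sensitivity", "specificity", "PPV", "NPV", "F1"):
            assert out[m].iloc[0] == 1.0

    def test_undefined_ratios_are_nan_not_zero(self):
        out = class_metrics({"TP": 0, "TN": 10, "FP": 0, "FN": 0})
        assert math.isnan(out["sensitivity"].iloc[0])
        assert math.isnan(out["PPV"].iloc[0])
        assert out["specificity"].iloc[0] == 1.0


class TestConfusion:
    def test_hand_enumerated_toy(self):
        """truth (CLL, T, debris) vs predicted (CLL, CLL, debris)."""
        c = confusion(["CLL_cells", "T_cells", "debris"],
                      ["CLL_cells", "CLL_cells", "debris"])
        row = c.loc["CLL cells"]
        assert (row["TP"], row["FP"], row["FN"], row["TN"]) == (1, 1, 0, 1)

    def test_perfect_prediction_no_errors(self, small_case):
        c = confusion(small_case.truth, small_case.truth)
        assert (c["FP"] == 0).all() and (c["FN"] == 0).all()

    def test_row_sums_constant_across_populations(self, small_case, rng):
        pred = rng.permutation(small_case.truth)
        c = confusion(small_case.truth, pred)
        totals = c.sum(axis=1)
        assert (totals == small_case.n_events).all()

    def test_grouping_pools_seven_minor_classes(self):
        for cls in ("basophils_dendritic", "blasts", "erythroblasts",
                    "granulocytes", "monocytes", "NK_cells", "unknown"):
            assert population_of(cls) == "Other cell categories"
        assert population_of("CLL_cells") == "CLL cells"
        c = confusion(["granulocytes"], ["monocytes"])
        assert c.loc["Other cell categories", "TP"] == 1

    def test_grouping_off_keeps_fourteen_classes(self):
        c = confusion(["granulocytes"], ["monocytes"], grouping=False)
        assert len(c) == 14
        assert c.loc["granulocytes", "FN"] == 1


class TestExactBinomialCI:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (25, 25, 86.3, 100.0),  # validation sensitivity
            (8, 8, 63.1, 100.0),    # validation NPV
            (33, 34, 84.7, 99.9),   # validation accuracy
            (8, 9, 51.8, 99.7),     # validation specificity
            (25, 26, 80.4, 99.9),   # validation PPV
        ],
    )
    def test_reproduces_printed_validation_cis(self, k, n, lo, hi):
        got_lo, got_hi = exact_binomial_ci(k, n)
        assert 100 * got_lo == pytest.approx(lo, abs=0.1)
        assert 100 * got_hi == pytest.approx(hi, abs=0.1)

    def test_zero_successes_closed_form(self):
        lo, hi = exact_binomial_ci(0, 1)
        assert lo == 0.0
        # 1 - (alpha/2)^(1/n) equivalence for k=0
        assert hi == pytest.approx(0.975, abs=1e-9)

    def test_boundaries_pinned(self):
        assert exact_binomial_ci(0, 10)[0] == 0.0
        assert exact_binomial_ci(10, 10)[1] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)


class TestStatusTable:
    def test_reproduces_validation_2x2_metrics(self):
        """DNN vs expert MRD status for the 34-case validation cohort:
        TP=25, TN=8, FP=1, FN=0."""
        dnn = [True] * 25 + [True] + [False] * 8
        expert = [True] * 25 + [False] + [False] * 8
        out = status_table(dnn, expert)
        assert out["accuracy"]["value"] == pytest.approx(97.1, abs=0.05)
        assert out["sensitivity"]["value"] == pytest.approx(100.0)
        assert out["specificity"]["value"] == pytest.approx(88.9, abs=0.05)
        assert out["PPV"]["value"] == pytest.approx(96.2, abs=0.05)
        assert out["NPV"]["value"] == pytest.approx(100.0)
        assert out["accuracy"]["ci"] == pytest.approx((84.7, 99.9), abs=0.1)
        assert out["matrix"].loc["MRD_positive", "MRD_positive"] == 25
        assert out["matrix"].loc["MRD_negative", "MRD_negative"] == 8

    def test_all_correct_is_100(self):
        out = status_table([True, False], [True, False])
        assert out["accuracy"]["value"] == 100.0

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_accuracy_matches_enumeration(self, pairs):
        dnn = [d for d, _ in pairs]
        expert = [e for _, e in pairs]
        out = status_table(dnn, expert)
        brute = 100.0 * sum(d == e for d, e in pairs) / len(pairs)
        assert out["accuracy"]["value"] == pytest.approx(brute)


def _auc_pair_counting(scores, truth):
    """O(n^2) oracle: fraction of (pos, neg) pairs ranked correctly,
    ties counted half."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_are_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    @given(
        st.lists(st.integers(0, 10), min_size=2, max_size=50),
        st.data(),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_pair_counting_oracle(self, scores, data):
        n = len(scores)
        truth = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda t: any(t) and not all(t)
            )
        )
        got = roc_auc(np.array(scores, float), np.array(truth))
        assert got == pytest.approx(_auc_pair_counting(scores, truth))

    def test_agrees_with_sklearn_on_random_scores(self, rng):
        scores = rng.normal(size=200)
        truth = rng.random(200) < 0.3
        truth[0], truth[1] = True, False  # both classes present
        assert roc_auc(scores, truth) == pytest.approx(
            roc_auc_score(truth, scores)
        )


def _pb_slope_oracle(x, y):
    """Naive shifted-median slope over all pairs (the method's definition,
    with the same index clamp for mostly-negative-correlation inputs)."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            s = dy / dx if dx != 0 else math.copysign(math.inf, dy)
            if s == -1.0:
                continue
            slopes.append(s)
    slopes.sort()
    k = sum(s < -1 for s in slopes)
    n_s = len(slopes)
    if n_s == 0:
        raise IndexError("no valid slopes")
    if n_s % 2 == 1:
        return slopes[min((n_s + 1) // 2 + k, n_s) - 1]
    i1 = min(n_s // 2 + k, n_s - 1)
    return 0.5 * (slopes[i1 - 1] + slopes[i1])


class TestPassingBablok:
    def test_identity_line(self):
        x = np.arange(1.0, 11.0)
        fit = passing_bablok(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.slope_ci[0] <= 1.0 <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= 0.0 <= fit.intercept_ci[1]

    def test_affine_recovery(self):
        x = np.arange(1.0, 11.0)
        fit = passing_bablok(x, 2 * x + 3)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(3.0)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_slope_matches_exhaustive_oracle(self, data):
        n = data.draw(st.integers(3, 12))
        x = data.draw(
            st.lists(
                st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n
            ).filter(lambda v: len(set(v)) > 1)
        )
        y = data.draw(
            st.lists(
                st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n
            )
        )
        try:
            expected = _pb_slope_oracle(x, y)
        except IndexError:  # no valid slopes survive the exclusions
            with pytest.raises(ValueError):
                passing_bablok(x, y)
            return
        fit = passing_bablok(np.array(x), np.array(y))
        assert fit.slope == pytest.approx(expected, nan_ok=True)

    def test_swapping_methods_inverts_slope(self, rng):
        x = np.sort(rng.uniform(1, 100, 10))
        y = 1.7 * x + rng.normal(0, 0.5, 10)
        fwd = passing_bablok(x, y)
        rev = passing_bablok(y, x)
        assert fwd.slope == pytest.approx(1.0 / rev.slope, rel=0.05)

    def test_scale_invariance(self, rng):
        x = np.sort(rng.uniform(1, 100, 12))
        y = x * 1.3 + rng.normal(0, 1, 12)
        a = passing_bablok(x, y)
        b = passing_bablok(10 * x, 10 * y)
        assert a.slope == pytest.approx(b.slope)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            passing_bablok([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            passing_bablok([1.0, 2.0], [1.0, 2.0])

    def test_slope_within_own_ci(self, rng):
        x = np.sort(rng.uniform(0, 50, 15))
        y = 0.9 * x + rng.normal(0, 2, 15)
        fit = passing_bablok(x, y)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 8.0, 7.0])
        cx, cy = x - x.mean(), y - y.mean()
        expected = float(np.sum(cx * cy) /
                         np.sqrt(np.sum(cx**2) * np.sum(cy**2)))
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDilutionErrors:
    def test_reproduces_printed_dilution_rows(self):
        """Published dilution rows: proportionate error above 1000 expert
        events, absolute delta below."""
        rows = pd.DataFrame(
            {
                "expert_count": [1_132_442, 492, 725_221, 145_914, 1_139_331],
                "dnn_count": [1_096_836, 11, 715_315, 142_952, 1_067_634],
            }
        )
        out = dilution_errors(rows)
        assert list(out["error_type"]) == [
            "proportionate", "absolute", "proportionate", "proportionate",
            "proportionate",
        ]
        assert out["error"].iloc[0] == pytest.approx(-3.144, abs=5e-4)
        assert out["error"].iloc[1] == -481
        assert out["error"].iloc[2] == pytest.approx(-1.366, abs=5e-4)
        assert out["error"].iloc[3] == pytest.approx(-2.03, abs=5e-3)
        assert out["error"].iloc[4] == pytest.approx(-6.293, abs=5e-4)

    def test_equal_counts_zero_under_either_rule(self):
        rows = pd.DataFrame(
            {"expert_count": [10, 5000], "dnn_count": [10, 5000]}
        )
        out = dilution_errors(rows)
        assert (out["error"] == 0).all()

    def test_pct_wbc_error_is_absolute_difference(self):
        rows = pd.DataFrame(
            {
                "expert_count": [400],
                "dnn_count": [380],
                "expert_pct_wbc": [0.022],
                "dnn_pct_wbc": [0.023],
            }
        )
        out = dilution_errors(rows)
        assert out["abs_error_pct_wbc"].iloc[0] == pytest.approx(0.001)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dilution_errors(
                pd.DataFrame({"expert_count": [-1], "dnn_count": [0]})
            )

    def test_threshold_boundary_uses_proportionate_at_1000(self):
        rows = pd.DataFrame(
            {"expert_count": [999, 1000], "dnn_count": [999, 900]}
        )
        out = dilution_errors(rows)
        assert list(out["error_type"]) == ["absolute", "proportionate"]
        assert out["error"].iloc[1] == pytest.approx(-10.0)
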