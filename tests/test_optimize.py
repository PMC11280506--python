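"""Cut-point calibration: cost functions and two-stage grid search."""

import numpy as np
import pytest

from infant_pa import (
    cost_pap_primary,
    cost_pap_secondary,
    cost_tp_primary,
    cost_tp_secondary,
    fit_thresholds,
)

from conftest import make_epochs


def brute_tp_primary(values, labels, t):
    sed_sed = sum(1 for v, l in zip(values, labels) if l == "SED" and v < t)
    sed_act = sum(1 for v, l in zip(values, labels) if l == "SED" and v >= t)
    act_sed = sum(1 for v, l in zip(values, labels) if l != "SED" and v < t)
    act_act = sum(1 for v, l in zip(values, labels) if l != "SED" and v >= t)
    tp_sed = sed_sed / (sed_sed + sed_act) * 100
    tp_act = act_act / (act_sed + act_act) * 100
    return abs(tp_sed - tp_act)


def brute_pap_primary(values, labels, t):
    gold_sed = sum(1 for l in labels if l == "SED")
    gold_act = len(labels) - gold_sed
    pred_sed = sum(1 for v in values if v < t)
    pred_act = len(values) - pred_sed
    return (
        abs((gold_sed - pred_sed) / gold_sed) * 100
        + abs((gold_act - pred_act) / gold_act) * 100
    )


def brute_three_class(values, labels, t1, t2):
    """Full 3x3 confusion dict under (t1, t2)."""
    cells = {}
    for g in ("SED", "LIGHT", "MV"):
        for p in ("SED", "LIGHT", "MV"):
            cells[f"{g}_{p}"] = 0
    for v, g in zip(values, labels):
        p = "SED" if v < t1 else ("LIGHT" if v < t2 else "MV")
        cells[f"{g}_{p}"] += 1
    return cells


def random_epochs(rng, n=60):
    labels = rng.choice(["SED", "LIGHT", "MV"], size=n, p=[0.4, 0.2, 0.4])
    centers = {"SED": 0.5, "LIGHT": 1.8, "MV": 3.5}
    values = np.array([rng.normal(centers[l], 0.8) for l in labels])
    values = np.clip(values, 0.01, None)
    return values, list(labels)


class TestCostExtremes:
    def test_tp_primary_candidate_below_all(self):
        epochs = make_epochs([1.0, 2.0, 3.0, 4.0], ["SED", "SED", "MV", "LIGHT"])
        assert cost_tp_primary(epochs, "acceleration", "both", 0.5) == pytest.approx(100.0)

    def test_tp_primary_candidate_above_all(self):
        epochs = make_epochs([1.0, 2.0, 3.0, 4.0], ["SED", "SED", "MV", "LIGHT"])
        assert cost_tp_primary(epochs, "acceleration", "both", 9.0) == pytest.approx(100.0)

    def test_tp_primary_perfect_separation_zero_cost(self):
        epochs = make_epochs([1.0, 1.1, 3.0, 3.1], ["SED", "SED", "LIGHT", "MV"])
        assert cost_tp_primary(epochs, "acceleration", "both", 2.0) == pytest.approx(0.0)

    def test_tp_secondary_degenerate_band_maximal_tp_mv(self):
        epochs = make_epochs([0.5, 2.0, 3.0], ["SED", "LIGHT", "MV"])
        # candidate at t_primary: every active prediction is MV, TP_MV = 100
        cost = cost_tp_secondary(epochs, "acceleration", "both", 1.0, 1.0, 80.0)
        assert cost == pytest.approx(20.0)

    def test_tp_secondary_candidate_above_all(self):
        epochs = make_epochs([0.5, 2.0, 3.0], ["SED", "LIGHT", "MV"])
        cost = cost_tp_secondary(epochs, "acceleration", "both", 1.0, 9.0, 80.0)
        assert cost == pytest.approx(80.0)

    def test_pap_primary_matching_counts_zero_cost(self):
        epochs = make_epochs([0.2, 0.4, 2.0, 3.0, 3.5], ["SED", "SED", "LIGHT", "MV", "MV"])
        assert cost_pap_primary(epochs, "acceleration", "both", 1.0) == pytest.approx(0.0)

    def test_pap_secondary_matching_totals_zero_cost(self):
        epochs = make_epochs([0.2, 1.5, 2.0, 3.0], ["SED", "LIGHT", "LIGHT", "MV"])
        assert cost_pap_secondary(epochs, "acceleration", "both", 1.0, 2.5) == pytest.approx(0.0)

    def test_pap_secondary_all_predicted_mv(self):
        # candidate = t_primary: no light predictions, all active epochs MV
        epochs = make_epochs([0.2, 1.5, 2.0, 3.0], ["SED", "LIGHT", "LIGHT", "MV"])
        cost = cost_pap_secondary(epochs, "acceleration", "both", 1.0, 1.0)
        # oracle: gold light 2 pred 0 -> 100; gold MV 1 pred 3 -> 200
        assert cost == pytest.approx(100.0 + 200.0)


class TestCostsAgainstBruteForce:
    def test_primary_costs_match_oracle(self, rng):
        for _ in range(100):
            values, labels = random_epochs(rng, n=int(rng.integers(10, 50)))
            if "SED" not in labels or len(set(labels)) < 2:
                continue
            epochs = make_epochs(values, labels)
            t = float(rng.uniform(0, 5))
            assert cost_tp_primary(epochs, "acceleration", "both", t) == pytest.approx(
                brute_tp_primary(values, labels, t)
            )
            assert cost_pap_primary(epochs, "acceleration", "both", t) == pytest.approx(
                brute_pap_primary(values, labels, t)
            )

    def test_secondary_costs_match_confusion_oracle(self, rng):
        for _ in range(100):
            values, labels = random_epochs(rng, n=40)
            if len(set(labels)) < 3:
                continue
            epochs = make_epochs(values, labels)
            t1 = float(rng.uniform(0.2, 2.0))
            t2 = t1 + float(rng.uniform(0.0, 3.0))
            cells = brute_three_class(values, labels, t1, t2)
            mv_total = cells["MV_SED"] + cells["MV_LIGHT"] + cells["MV_MV"]
            tp_mv = cells["MV_MV"] / mv_total * 100
            tp_fixed = 77.0
            assert cost_tp_secondary(
                epochs, "acceleration", "both", t1, t2, tp_fixed
            ) == pytest.approx(abs(tp_mv - tp_fixed))
            gold_light = sum(1 for l in labels if l == "LIGHT")
            gold_mv = sum(1 for l in labels if l == "MV")
            pred_light = cells["SED_LIGHT"] + cells["LIGHT_LIGHT"] + cells["MV_LIGHT"]
            pred_mv = cells["SED_MV"] + cells["LIGHT_MV"] + cells["MV_MV"]
            expected = (
                abs((gold_light - pred_light) / gold_light) * 100
                + abs((gold_mv - pred_mv) / gold_mv) * 100
            )
            assert cost_pap_secondary(
                epochs, "acceleration", "both", t1, t2
            ) == pytest.approx(expected)


class TestFitThresholds:
    def test_grid_search_equals_exhaustive_costs(self, rng):
        values, labels = random_epochs(rng, n=80)
        epochs = make_epochs(values, labels)
        for method in ("TP", "PAP"):
            result = fit_thresholds(epochs, "acceleration", "both", method)
            # curve equals pointwise cost evaluation via the public cost fns
            for cand, cost in result.primary_curve[::37]:
                fn = cost_tp_primary if method == "TP" else cost_pap_primary
                assert cost == pytest.approx(fn(epochs, "acceleration", "both", cand))
            t1 = result.thresholds.t_sed_active
            assert result.primary_curve[:, 1].min() == pytest.approx(
                dict(zip(result.primary_curve[:, 0], result.primary_curve[:, 1]))[t1]
            )

    def test_primary_local_optimality_tp(self, rng):
        values, labels = random_epochs(rng, n=80)
        epochs = make_epochs(values, labels)
        result = fit_thresholds(epochs, "acceleration", "both", "TP")
        t1 = result.thresholds.t_sed_active
        step = 0.01
        c0 = cost_tp_primary(epochs, "acceleration", "both", t1)
        assert c0 <= cost_tp_primary(epochs, "acceleration", "both", t1 - step) + 1e-9
        assert c0 <= cost_tp_primary(epochs, "acceleration", "both", t1 + step) + 1e-9

    def test_two_separated_clusters_primary_recovery(self):
        values = [0.2, 0.3, 0.4, 2.0, 2.2, 2.4, 3.0, 3.3]
        labels = ["SED"] * 3 + ["LIGHT"] * 3 + ["MV"] * 2
        for method in ("TP", "PAP"):
            result = fit_thresholds(make_epochs(values, labels), "acceleration", "both", method)
            t1 = result.thresholds.t_sed_active
            assert 0.4 < t1 <= 2.0 + 0.01

    def test_three_separated_clusters_both_thresholds(self):
        values = [0.2, 0.3, 1.5, 1.6, 3.0, 3.2]
        labels = ["SED", "SED", "LIGHT", "LIGHT", "MV", "MV"]
        for method in ("TP", "PAP"):
            result = fit_thresholds(make_epochs(values, labels), "acceleration", "both", method)
            t1, t2 = result.thresholds.t_sed_active, result.thresholds.t_light_mv
            assert 0.3 < t1 <= 1.5 + 0.01
            assert 1.6 < t2 <= 3.0 + 0.01
            # PAP at the optimum matches gold proportions exactly
            if method == "PAP":
                assert cost_pap_primary(
                    make_epochs(values, labels), "acceleration", "both", t1
                ) == pytest.approx(0.0)

    def test_secondary_at_least_primary(self, rng):
        for seed in range(5):
            values, labels = random_epochs(np.random.default_rng(seed), n=60)
            epochs = make_epochs(values, labels)
            for method in ("TP", "PAP"):
                t = fit_thresholds(epochs, "acceleration", "both", method).thresholds
                assert t.t_light_mv >= t.t_sed_active

    def test_tp_fixed_frozen_from_primary(self, rng):
        values, labels = random_epochs(rng, n=80)
        epochs = make_epochs(values, labels)
        result = fit_thresholds(epochs, "acceleration", "both", "TP")
        t1 = result.thresholds.t_sed_active
        sed_vals = [v for v, l in zip(values, labels) if l == "SED"]
        expected = sum(1 for v in sed_vals if v < t1) / len(sed_vals) * 100
        assert result.tp_fixed == pytest.approx(expected)
        assert result.thresholds.tp_fixed == pytest.approx(expected)

    def test_single_class_rejected(self):
        epochs = make_epochs([1.0, 2.0, 3.0], ["SED", "SED", "SED"])
        with pytest.raises(ValueError, match="degenerate"):
            fit_thresholds(epochs, "acceleration", "both", "TP")
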