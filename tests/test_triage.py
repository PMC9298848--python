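import itertools

import numpy as np
import pandas as pd
import pytest

from fstriage.triage import (
    CATEGORIES,
    RelabeledTruth,
    TriageResult,
    TriageThresholds,
    TriageTree,
    relabel_ground_truth,
    triage_metrics,
    triple_classify,
)


class TestTripleClassify:
    @pytest.mark.parametrize(
        "prob,area,diam,perim,expected",
        [
            (0.9, 150.0, 10.0, 50.0, "common_malignant"),
            (0.1, 0.0, 0.0, 0.0, "common_benign"),
            (0.7, 50.0, 4.0, 20.0, "rare"),
            (0.1, 400.0, 10.0, 50.0, "rare"),  # benign branch, implausible area
            (0.9, 150.0, 10.0, 20.0, "rare"),  # malignant branch, short perimeter
            (0.9, 150.0, 4.0, 50.0, "rare"),  # malignant branch, small diameter
        ],
    )
    def test_default_topology_table(self, prob, area, diam, perim, expected):
        res = triple_classify(prob, (area, diam, perim))
        assert res.category == expected
        assert res.decision_path[0][0] == "probability"

    def test_validation(self):
        with pytest.raises(ValueError):
            triple_classify(0.5, (-1.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            triple_classify(1.5, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            TriageThresholds(prob_cut=1.0)
        with pytest.raises(ValueError):
            TriageThresholds(area_cut=-5.0)

    def test_partition_and_monotonicity_on_dense_grid(self):
        probs = np.linspace(0.0, 1.0, 21)
        areas = (0.0, 150.0, 299.9, 300.0, 450.0)
        diams = (0.0, 3.5, 6.9, 7.0, 14.0)
        perims = (0.0, 20.0, 34.9, 35.0, 70.0)
        for a, d, p in itertools.product(areas, diams, perims):
            prev_branch = None
            for prob in probs:
                res = triple_classify(prob, (a, d, p))
                assert res.category in CATEGORIES  # exactly one leaf, always
                branch = res.decision_path[0][1]
                # raising probability never moves malignant -> benign
                if prev_branch == "malignant":
                    assert branch == "malignant"
                prev_branch = branch

    def test_tree_estimator_matches_function(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "rf_prob": rng.random(30),
                "max_area_mm2": rng.uniform(0, 500, 30),
                "max_diameter_mm": rng.uniform(0, 15, 30),
                "max_perimeter_mm": rng.uniform(0, 80, 30),
            },
            index=[f"s{i}" for i in range(30)],
        )
        tree = TriageTree()
        cats = tree.predict(table)
        for (sid, row), cat in zip(table.iterrows(), cats):
            assert (
                triple_classify(
                    row["rf_prob"],
                    (row["max_area_mm2"], row["max_diameter_mm"], row["max_perimeter_mm"]),
                ).category
                == cat
            )

    def test_custom_thresholds_change_routing(self):
        res = triple_classify(0.7, (50.0, 4.0, 20.0), TriageThresholds(
            prob_cut=0.5, area_cut=300.0, diameter_cut=3.0, perimeter_cut=15.0))
        assert res.category == "common_malignant"


class TestRelabel:
    @pytest.mark.parametrize(
        "subtype,pred,label,expected",
        [
            ("TAL", "benign", "malignant", "rare"),
            ("TFCN", "malignant", "malignant", "rare"),
            ("PTC", "malignant", "malignant", "common_malignant"),
            ("PTC", "benign", "malignant", "rare"),
            ("NG", "malignant", "benign", "rare"),
            ("NG", "benign", "benign", "common_benign"),
            ("OtherTC", "malignant", "malignant", "common_malignant"),
            ("OtherBTL", "benign", "benign", "common_benign"),
        ],
    )
    def test_rules(self, subtype, pred, label, expected):
        assert relabel_ground_truth(subtype, pred, label) == expected

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError):
            relabel_ground_truth("FTC", "benign", "benign")
        with pytest.raises(ValueError):
            relabel_ground_truth("PTC", "positive", "malignant")

    def test_case_series_relabeling_reconstructed(self):
        # printed per-subtype binary outcomes of the real-world test series:
        # (subtype, n, binary_pred) with labels implied by the subtype
        rows = [
            ("PTC", 270, "malignant"), ("PTC", 13, "benign"),
            ("OtherTC", 5, "malignant"),
            ("TAL", 72, "benign"),
            ("TFCN", 45, "benign"),
            ("OtherBTL", 20, "benign"), ("OtherBTL", 5, "malignant"),
            ("NG", 325, "benign"), ("NG", 9, "malignant"),
        ]
        label = {"PTC": "malignant", "OtherTC": "malignant", "TAL": "malignant",
                 "TFCN": "malignant", "OtherBTL": "benign", "NG": "benign"}
        table = {}
        for subtype, n, pred in rows:
            cat = relabel_ground_truth(subtype, pred, label[subtype])
            table.setdefault(subtype, {c: 0 for c in CATEGORIES})
            table[subtype][cat] += n
        expected = {
            "PTC": (0, 270, 13),
            "OtherTC": (0, 5, 0),
            "TAL": (0, 0, 72),
            "TFCN": (0, 0, 45),
            "OtherBTL": (20, 0, 5),
            "NG": (325, 0, 9),
        }
        for subtype, (cb, cm, rare) in expected.items():
            assert table[subtype]["common_benign"] == cb
            assert table[subtype]["common_malignant"] == cm
            assert table[subtype]["rare"] == rare
        totals = {c: sum(t[c] for t in table.values()) for c in CATEGORIES}
        assert totals == {"common_benign": 345, "common_malignant": 275, "rare": 144}
        assert sum(totals.values()) == 764


def make_results_truth(n_rare, n_rare_flagged, n_flagged, n_total):
    """Synthetic id-aligned result/truth lists with the given marginals."""
    n_other_flagged = n_flagged - n_rare_flagged
    results, truth = [], []
    n_benign = (n_total - n_rare) // 2
    for i in range(n_total):
        sid = f"s{i}"
        if i < n_rare:
            true_cat = "rare"
            pred_cat = "rare" if i < n_rare_flagged else "common_benign"
        else:
            true_cat = "common_benign" if i < n_rare + n_benign else "common_malignant"
            pred_cat = "rare" if i - n_rare < n_other_flagged else true_cat
        results.append(
            TriageResult(sid, 0.5, 0.0, 0.0, 0.0, (("probability", "x"),), pred_cat)
        )
        truth.append(RelabeledTruth(sid, "PTC", "malignant", true_cat))
    return results, truth


class TestTriageMetrics:
    def test_case_series_counts_give_printed_rates(self):
        # 127 of 144 rare slides flagged, 255 flagged overall, 764 slides
        results, truth = make_results_truth(144, 127, 255, 764)
        m = triage_metrics(results, truth)
        assert m.rare_recall == pytest.approx(127 / 144)
        assert round(m.rare_recall, 3) == 0.882
        assert m.rare_precision == pytest.approx(127 / 255)
        assert round(m.rare_precision, 3) == 0.498
        assert m.workload_fraction == pytest.approx(255 / 764)
        assert round(m.workload_fraction, 3) == 0.334
        assert m.confusion.to_numpy().sum() == 764

    def test_empty_flagged_set_conventions(self):
        results, truth = make_results_truth(5, 0, 0, 20)
        m = triage_metrics(results, truth)
        assert m.rare_recall == 0.0
        assert m.rare_precision == 0.0
        assert m.workload_fraction == 0.0

    def test_id_mismatch_lists_difference(self):
        results, truth = make_results_truth(2, 1, 3, 10)
        with pytest.raises(ValueError, match="s9"):
            triage_metrics(results[:-1], truth)

    def test_json_round_trip(self, tmp_path):
        import json

        results, truth = make_results_truth(4, 3, 5, 20)
        m = triage_metrics(results, truth, thresholds=TriageThresholds())
        m.to_json(tmp_path / "m.json")
        loaded = json.loads((tmp_path / "m.json").read_text())
        assert loaded["rare_recall"] == pytest.approx(0.75)
        assert loaded["thresholds"]["area_cut"] == 300.0
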