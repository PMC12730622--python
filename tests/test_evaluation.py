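"""AUC/TSS metrics, thresholding rules and spatial cross-validation."""

import numpy as np
import pandas as pd
import pytest

import karstsdm as k
from karstsdm.evaluation import _candidate_thresholds

P_TOY = np.array([0.9, 0.8, 0.4])
B_TOY = np.array([0.7, 0.3, 0.2, 0.1])


def auc_brute_force(p, b):
    wins = sum(1.0 for pi in p for bi in b if pi > bi)
    ties = sum(1.0 for pi in p for bi in b if pi == bi)
    return (wins + 0.5 * ties) / (len(p) * len(b))


class TestAUC:
    def test_perfect_separation(self):
        assert k.auc([0.8, 0.9], [0.1, 0.2, 0.3]) == 1.0

    def test_identical_sets_all_ties(self):
        assert k.auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_enumerated_toy_example(self):
        assert k.auc(P_TOY, B_TOY) == pytest.approx(11.0 / 12.0)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.choice(np.linspace(0, 1, 11), size=rng.integers(1, 8))
            b = rng.choice(np.linspace(0, 1, 11), size=rng.integers(1, 12))
            assert k.auc(p, b) == pytest.approx(auc_brute_force(p, b), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        p, b = rng.random(20), rng.random(30)
        assert k.auc(np.exp(3 * p), np.exp(3 * b)) == pytest.approx(k.auc(p, b))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            k.auc([], [0.5])


class TestConfusion:
    def test_threshold_below_everything(self):
        sens, spec, tss = k.confusion_metrics(P_TOY, B_TOY, 0.0)
        assert (sens, spec, tss) == (1.0, 0.0, 0.0)

    def test_threshold_above_everything(self):
        sens, spec, tss = k.confusion_metrics(P_TOY, B_TOY, 2.0)
        assert (sens, spec, tss) == (0.0, 1.0, 0.0)

    def test_toy_counts(self):
        sens, spec, tss = k.confusion_metrics(P_TOY, B_TOY, 0.35)
        assert sens == 1.0 and spec == 0.75 and tss == pytest.approx(0.75)

    def test_tie_classified_positive(self):
        sens, _, _ = k.confusion_metrics([0.5], [0.1], 0.5)
        assert sens == 1.0


class TestYouden:
    def test_perfect_separation_reaches_tss_one(self):
        thr = k.youden_threshold([0.8, 0.9], [0.1, 0.2])
        assert k.confusion_metrics([0.8, 0.9], [0.1, 0.2], thr)[2] == 1.0

    def test_toy_optimum_in_gap(self):
        thr = k.youden_threshold(P_TOY, B_TOY)
        assert 0.3 < thr <= 0.4
        assert k.confusion_metrics(P_TOY, B_TOY, thr)[2] == pytest.approx(0.75)

    def test_matches_dense_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.beta(4, 2, size=rng.integers(2, 10))
            b = rng.beta(2, 4, size=rng.integers(2, 15))
            thr = k.youden_threshold(p, b)
            best = k.confusion_metrics(p, b, thr)[2]
            scan = max(
                k.confusion_metrics(p, b, t)[2] for t in np.linspace(-0.01, 1.01, 1000)
            )
            assert best == pytest.approx(scan, abs=1e-12)

    def test_youden_tss_dominates_all_candidates(self):
        rng = np.random.default_rng(4)
        p, b = rng.random(8), rng.random(12)
        thr = k.youden_threshold(p, b)
        best = k.confusion_metrics(p, b, thr)[2]
        for t in _candidate_thresholds(p, b):
            assert k.confusion_metrics(p, b, t)[2] <= best + 1e-12


class TestSpecSens:
    def test_mirrored_distributions_balance_near_half(self):
        p = np.array([0.6, 0.7, 0.8, 0.9])
        b = 1.0 - p
        thr = k.spec_sens_threshold(p, b)
        sens, spec, _ = k.confusion_metrics(p, b, thr)
        assert sens == spec
        assert 0.4 <= thr <= 0.6

    def test_two_point_case_returns_lowest_balancing_candidate(self):
        thr = k.spec_sens_threshold([0.9], [0.1])
        sens, spec, _ = k.confusion_metrics([0.9], [0.1], thr)
        assert sens == spec == 1.0
        assert 0.1 < thr <= 0.9

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.beta(4, 2, size=5)
            b = rng.beta(2, 4, size=9)
            thr = k.spec_sens_threshold(p, b)
            gap = abs(np.subtract(*k.confusion_metrics(p, b, thr)[:2]))
            scan = min(
                abs(np.subtract(*k.confusion_metrics(p, b, t)[:2]))
                for t in np.linspace(-0.01, 1.01, 1000)
            )
            assert gap <= scan + 1e-12


class TestThresholdSet:
    def test_presences_above_top10_full_coverage(self):
        rng = np.random.default_rng(6)
        masked = rng.random(5000)
        ts = k.threshold_set(masked, [0.95, 0.97, 0.99])
        assert ts.final_thr == ts.top10_thr
        assert ts.coverage == 1.0

    def test_uniform_map_top_decile_covers_ten_percent(self):
        rng = np.random.default_rng(7)
        masked = rng.random(100_000)
        ts = k.threshold_set(masked, [0.99], rule="top10-only")
        assert ts.positive_fraction == pytest.approx(0.10, abs=0.005)

    def test_strict_mtp_rule_always_full_coverage(self):
        rng = np.random.default_rng(8)
        masked = rng.random(1000)
        presence = rng.random(6)
        ts = k.threshold_set(masked, presence, rule="strict-mtp")
        assert ts.coverage == 1.0
        assert ts.mtp_thr <= ts.p10_thr

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            k.threshold_set(np.full(100, 0.4), [0.5])

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            k.threshold_set(np.random.default_rng(0).random(100), [0.5], rule="nope")


class TestAdaptiveK:
    @pytest.mark.parametrize("n,expected", [(6, 3), (4, 2), (25, 5), (2, 2), (3, 2), (10, 5)])
    def test_formula(self, n, expected):
        assert k.adaptive_k(n) == expected

    def test_below_two_rejected(self):
        with pytest.raises(ValueError):
            k.adaptive_k(1)


class TestSpatialFolds:
    def test_well_separated_clouds_recovered(self):
        rng = np.random.default_rng(9)
        clouds = [rng.normal(c, 50.0, size=(30, 2)) for c in ((0, 0), (1e5, 0), (0, 1e5))]
        coords = np.vstack(clouds)
        labels = k.spatial_folds(coords, 3, seed=0)
        for i in range(3):
            chunk = labels[30 * i : 30 * (i + 1)]
            assert len(set(chunk)) == 1

    def test_duplicate_coordinates_share_fold(self):
        coords = np.array([[0.0, 0.0]] * 5 + [[100.0, 0.0]] * 5 + [[0.0, 100.0]] * 5)
        labels = k.spatial_folds(coords, 3, seed=1)
        assert len(set(labels[:5])) == 1

    def test_seeded_and_better_than_random(self):
        rng = np.random.default_rng(10)
        coords = rng.random((60, 2)) * 1000.0
        a = k.spatial_folds(coords, 3, seed=4)
        b = k.spatial_folds(coords, 3, seed=4)
        np.testing.assert_array_equal(a, b)

        def wss(labels):
            return sum(
                np.sum((coords[labels == f] - coords[labels == f].mean(axis=0)) ** 2)
                for f in set(labels)
            )

        kmeans_wss = wss(a)
        for i in range(100):
            rand = np.random.default_rng(i).integers(0, 3, size=60)
            if all((rand == f).any() for f in range(3)):
                assert kmeans_wss <= wss(rand)

    def test_too_few_distinct_points(self):
        with pytest.raises(ValueError, match="distinct"):
            k.spatial_folds(np.zeros((10, 2)), 2, seed=0)


class TestSummarizeCV:
    def test_reported_fold_auc_summary(self):
        s = k.summarize_cv([0.886, 0.500, 0.602])
        assert round(s["mean"], 3) == 0.663
        assert round(s["sd"], 3) == 0.200
        assert s["median"] == pytest.approx(0.602)

    def test_reported_fold_tss_summary(self):
        s = k.summarize_cv([0.886, 0.000, 0.472])
        assert round(s["mean"], 3) == 0.453
        assert round(s["sd"], 3) == 0.443
        assert s["median"] == pytest.approx(0.472)

    def test_identical_values(self):
        s = k.summarize_cv([0.7, 0.7, 0.7])
        assert s["mean"] == pytest.approx(0.7)
        assert s["median"] == pytest.approx(0.7)
        assert s["sd"] == pytest.approx(0.0)

    def test_single_value_sd_undefined(self):
        s = k.summarize_cv([0.8])
        assert s["sd"] is None and s["mean"] == 0.8

    def test_no_defined_values_rejected(self):
        with pytest.raises(ValueError):
            k.summarize_cv([np.nan])


def toy_spatial_table():
    """6 presences in 3 well-separated clumps, plus local background."""
    rng = np.random.default_rng(11)
    rows = []
    for ci, centre in enumerate([(0.0, 0.0), (5e4, 0.0), (0.0, 5e4)]):
        for _ in range(2):
            rows.append((centre[0] + rng.normal(0, 100), centre[1] + rng.normal(0, 100), 1))
        for _ in range(40):
            rows.append((centre[0] + rng.normal(0, 500), centre[1] + rng.normal(0, 500), 0))
    df = pd.DataFrame(rows, columns=["x", "y", "label"])
    df["stratum"] = np.where(df["label"] == 1, "presence", "mask")
    df["p1"] = rng.normal(size=len(df)) + 2.0 * df["label"]
    df["p2"] = rng.normal(size=len(df))
    n_p = int(df["label"].sum())
    df["weight"] = np.where(df["label"] == 1, 0.5 / n_p, 0.5 / (len(df) - n_p))
    return k.TrainingTable(df[["x", "y", "stratum", "label", "weight", "p1", "p2"]], ["p1", "p2"])


class TestCrossValidate:
    def test_toy_partition_bookkeeping(self):
        table = toy_spatial_table()
        report = k.cross_validate(table, seed=0, lambda_=0.1)
        folds = report.folds
        assert len(folds) == 3  # adaptive_k(6)
        assert (folds["n_presence_test"] == 2).all()
        assert folds["n_presence_test"].sum() + folds["n_background_test"].sum() == len(table)
        assert (~folds["sparse"]).all()

    def test_informative_predictor_scores_high(self):
        table = toy_spatial_table()
        report = k.cross_validate(table, seed=0, lambda_=0.1)
        assert report.summary["auc"]["mean"] > 0.8

    def test_label_shuffle_destroys_signal(self):
        table = toy_spatial_table()
        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(10):
            df = table.data.copy()
            labels = rng.permutation(df["label"].to_numpy())
            df["label"] = labels
            n_p = labels.sum()
            df["weight"] = np.where(labels == 1, 0.5 / n_p, 0.5 / (len(df) - n_p))
            shuffled = k.TrainingTable(df, table.predictors)
            rep = k.cross_validate(shuffled, seed=0, lambda_=0.1)
            aucs.append(rep.summary["auc"]["mean"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_fold_csv_mirrors_report_columns(self, tmp_path):
        table = toy_spatial_table()
        report = k.cross_validate(table, seed=0, lambda_=0.1)
        report.to_csv(tmp_path / "cv.csv")
        back = pd.read_csv(tmp_path / "cv.csv")
        assert list(back.columns) == ["Fold", "AUC", "Thr_Spec_Sens", "TSS", "nP", "nB"]
        assert len(back) == 6  # 3 folds + mean/sd/median rows

    def test_undefined_folds_flagged_not_dropped(self):
        """A fold with a single training presence is recorded with a note."""
        table = toy_spatial_table()
        # keep only 2 presences total (one clump) -> adaptive_k = ... needs >=2
        df = table.data[(table.data["label"] == 0) | (table.data.index < 2)].copy()
        n_p = int(df["label"].sum())
        df["weight"] = np.where(df["label"] == 1, 0.5 / n_p, 0.5 / (len(df) - n_p))
        small = k.TrainingTable(df.reset_index(drop=True), table.predictors)
        report = k.cross_validate(small, seed=0)  # no fixed lambda
        folds = report.folds
        assert len(folds) == 2
        assert folds["note"].str.len().sum() > 0  # at least one fold annotated
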