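"""Feature assembly, exact Shapley attribution, rank statistics, pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sitmotif import ssa_pnn, study_pipeline as pipe
from sitmotif import synthetic_data as syn
from sitmotif.exceptions import ConfigError, FormatError


class TestLabel:
    @pytest.mark.parametrize("morning,evening,expected", [
        (5, 7, "exacerbated"),   # pain rose through the day
        (5, 5, "no_change"),
        (7, 3, "improved"),
        (0, 0, "no_change"),
    ])
    def test_sign_rule(self, morning, evening, expected):
        assert pipe.lbp_change_label(morning, evening) == expected

    def test_missing_score_is_unlabelable(self):
        assert pipe.lbp_change_label(None, 4) is None
        assert pipe.lbp_change_label(4, float("nan")) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            pipe.lbp_change_label(11, 4)


def tiny_inputs():
    day_features = pd.DataFrame([
        {"participant_id": "P01", "date": "d1", "sitting_hours": 5.0,
         "motif_rate_30min": 2.0},
        {"participant_id": "P01", "date": "d2", "sitting_hours": 0.0,
         "motif_rate_30min": 0.0},   # dropped: no sitting
        {"participant_id": "P02", "date": "d1", "sitting_hours": 4.0,
         "motif_rate_30min": 3.5},
    ])
    rows = []
    for pid, date, lbps in [("P01", "d1", [5, 5, 6, 7]),
                            ("P01", "d2", [5, 5, 5, 5]),
                            ("P02", "d1", [6, 4, 3, 2])]:
        for slot, lbp in zip(syn.TIME_SLOTS, lbps):
            rows.append({"participant_id": pid, "date": date, "time_slot": slot,
                         "lbp": lbp, "sleepiness": 6, "fullness": 3})
    questionnaire = pd.DataFrame(rows)
    metadata = pd.DataFrame([{"participant_id": "P01", "sex": 0, "weight_kg": 60.0},
                             {"participant_id": "P02", "sex": 1, "weight_kg": 70.0}])
    return day_features, questionnaire, metadata


class TestFeatureTable:
    def test_join_labels_and_schema(self):
        table = pipe.build_feature_table(*tiny_inputs())
        assert list(table.columns) == ["participant_id", "date",
                                       *pipe.FEATURE_COLUMNS, "label"]
        assert len(table) == 2  # zero-sitting day dropped
        assert table.set_index("participant_id")["label"].to_dict() == \
            {"P01": "exacerbated", "P02": "improved"}

    def test_missing_metadata_is_an_error(self):
        day_features, questionnaire, metadata = tiny_inputs()
        with pytest.raises(ConfigError, match="P02"):
            pipe.build_feature_table(day_features, questionnaire,
                                     metadata.iloc[:1])


class TestExactShapley:
    def test_additive_model_closed_form(self, rng):
        a = np.array([1.5, -2.0, 0.7, 0.0])
        background = rng.standard_normal((40, 4))
        x = rng.standard_normal(4)
        predict = lambda rows: (rows * a).sum(axis=1, keepdims=True)
        phi, base = pipe.exact_shapley(predict, x, background)
        want = a * (x - background.mean(axis=0))
        assert np.allclose(phi[:, 0], want, atol=1e-10)
        assert base[0] == pytest.approx(float(predict(background).mean()))

    def test_efficiency_axiom_on_pnn(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 2, 30)
        model = ssa_pnn.fit_pnn(X, y, 0.8, np.array([1.0, 0.5, 2.0]))
        predict = lambda rows: ssa_pnn.predict_proba(rows, model)
        for row in X[:5]:
            phi, base = pipe.exact_shapley(predict, row, X)
            f_x = predict(row[None, :])[0]
            assert np.allclose(phi.sum(axis=0), f_x - base, atol=1e-8)

    def test_null_player_has_zero_attribution(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.integers(0, 2, 25)
        model = ssa_pnn.fit_pnn(X, y, 0.8, np.array([1.0, 1.0, 0.0]))
        predict = lambda rows: ssa_pnn.predict_proba(rows, model)
        phi, _ = pipe.exact_shapley(predict, X[0], X)
        assert np.allclose(phi[2], 0.0, atol=1e-10)

    def test_empty_background_rejected(self):
        with pytest.raises(ConfigError):
            pipe.exact_shapley(lambda r: r.sum(1, keepdims=True),
                               np.zeros(2), np.zeros((0, 2)))

    def test_summary_ranks_dominant_feature_first(self, rng):
        background = rng.standard_normal((30, 3))
        predict = lambda rows: (rows * np.array([0.1, 5.0, 0.5])).sum(
            axis=1, keepdims=True)
        table = pipe.shapley_summary(predict, background[:10], background,
                                     feature_names=["a", "b", "c"])
        assert table.index[0] == "b"


class TestKruskalWallis:
    def test_all_equal_values(self):
        H, p = pipe.kruskal_wallis([[2, 2, 2], [2, 2], [2, 2, 2, 2]])
        assert H == 0.0 and p == 1.0

    def test_textbook_fixture(self):
        H, p = pipe.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert H == pytest.approx(7.2)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(50):
            groups = [rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
                      for _ in range(rng.integers(2, 5))]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            H, p = pipe.kruskal_wallis(groups)
            want = sps.kruskal(*groups)
            assert H == pytest.approx(want.statistic, abs=1e-10)
            assert p == pytest.approx(want.pvalue, abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=8), rng.normal(1, 1, 9), rng.normal(2, 1, 7)]
        H1, _ = pipe.kruskal_wallis(groups)
        H2, _ = pipe.kruskal_wallis([np.exp(g) for g in groups])
        assert H1 == pytest.approx(H2, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError):
            pipe.kruskal_wallis([[1, 2], []])


def oracle_dunn(groups):
    """Independent Dunn computation: explicit mid-ranks and tie counts."""
    from collections import Counter

    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    N = len(pooled)
    ties = Counter(pooled.tolist())
    tie_sum = sum(t ** 3 - t for t in ties.values())
    var = N * (N + 1) / 12 - tie_sum / (12 * (N - 1))
    out = []
    start = 0
    means, ns = [], []
    for g in groups:
        means.append(ranks[start:start + len(g)].mean())
        ns.append(len(g))
        start += len(g)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var * (1 / ns[i] + 1 / ns[j]))
            z = 0.0 if se == 0 else (means[i] - means[j]) / se
            out.append((z, min(1.0, 2 * sps.norm.sf(abs(z)))))
    return out


class TestDunn:
    def test_identical_groups(self):
        table = pipe.dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert table["z"].iloc[0] == pytest.approx(0.0)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_independent_computation(self, rng):
        for _ in range(50):
            groups = [rng.integers(0, 8, size=rng.integers(3, 10)).astype(float)
                      for _ in range(3)]
            table = pipe.dunn_posthoc(groups)
            want = oracle_dunn(groups)
            for (z, p), row in zip(want, table.itertuples()):
                assert row.z == pytest.approx(z, abs=1e-8)
                assert row.p == pytest.approx(p, abs=1e-8)

    def test_holm_adjustment_is_monotone(self, rng):
        groups = [rng.normal(size=10), rng.normal(2, 1, 10), rng.normal(4, 1, 10)]
        table = pipe.dunn_posthoc(groups, adjust="holm")
        assert (table["p_adjusted"] >= table["p"] - 1e-12).all()
        assert (table["p_adjusted"] <= 1.0).all()

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            pipe.dunn_posthoc([[1, 2, 3]])


class TestPipeline:
    def mini_config(self, seed, tmp_dir=None):
        return pipe.PipelineConfig(
            cohort=syn.CohortSpec(n_participants=12, days_per_participant=2,
                                  day_hours=1.0, seed=seed,
                                  category_probs=(0.4, 0.4, 0.2)),
            k_states=3, cv_reps=1, n_permutations=0, shap_background=15,
            seed=seed, out_dir=tmp_dir)

    def test_runs_end_to_end_and_is_deterministic(self):
        a = pipe.run_pipeline(self.mini_config(11))
        b = pipe.run_pipeline(self.mini_config(11))
        assert a["common_motif"] == b["common_motif"]
        assert a["cv_metrics"] == b["cv_metrics"]
        assert a["shap_ranking"] == b["shap_ranking"]
        assert a["kruskal_wallis"] == b["kruskal_wallis"]
        assert a["n_days"] <= 24
        assert set(a["group_motif_rates"]) <= set(pipe.LABELS)

    def test_report_written_with_artifacts(self, tmp_path):
        pipe.run_pipeline(self.mini_config(11, str(tmp_path)))
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "features.csv").exists()
        assert (tmp_path / "shap_summary.csv").exists()
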