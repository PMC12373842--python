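import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoscreen import (
    FeatureMatrix,
    b_score,
    b_score_wells,
    call_hits,
    control_separation,
    cumulative_variance,
    filter_dead_wells,
    fold_change,
    median_polish,
    normalize_colony_counts,
    pca_morphospace,
    pearson_matrix,
    score_residuals,
    top_percent_gate,
    zscore_features,
)
from morphoscreen.analytics import MAD_SCALE, plate_grid

from conftest import make_feature_table


class TestZScore:
    def test_closed_form_three_values(self):
        fm = make_feature_table({"P01": [1.0, 2.0, 3.0]})
        z = zscore_features(fm).data["median_colony_area"]
        assert np.allclose(z, [-1.224744871, 0.0, 1.224744871])

    def test_idempotent(self):
        fm = make_feature_table({"P01": [4.0, 8.0, 15.0, 16.0, 23.0, 42.0]})
        once = zscore_features(fm)
        twice = zscore_features(once)
        assert np.allclose(
            once.data["median_colony_area"], twice.data["median_colony_area"], atol=1e-12
        )

    def test_constant_column_dropped_with_warning(self, caplog):
        fm = make_feature_table(
            {"P01": [1.0, 2.0, 3.0]}, extra_features={"flat": {"P01": [7.0, 7.0, 7.0]}}
        )
        with caplog.at_level(logging.WARNING, logger="morphoscreen.analytics"):
            z = zscore_features(fm)
        assert "flat" not in z.features
        assert any("constant" in r.message for r in caplog.records)

    def test_all_constant_errors(self):
        fm = make_feature_table({"P01": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError):
            zscore_features(fm)


class TestPearson:
    def test_identical_and_negated_columns(self):
        vals = [1.0, 4.0, 2.0, 8.0]
        fm = make_feature_table(
            {"P01": vals},
            extra_features={
                "twin": {"P01": vals},
                "anti": {"P01": [-v for v in vals]},
            },
        )
        C = pearson_matrix(fm)
        assert C.loc["median_colony_area", "twin"] == pytest.approx(1.0)
        assert C.loc["median_colony_area", "anti"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)

    def test_matches_direct_formula(self, small_random_table):
        C = pearson_matrix(small_random_table)
        X = small_random_table.feature_values.to_numpy()
        for i, a in enumerate(small_random_table.features):
            for j, b in enumerate(small_random_table.features):
                x, y = X[:, i], X[:, j]
                cov = ((x - x.mean()) * (y - y.mean())).mean()
                r = cov / (x.std() * y.std())
                assert C.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_errors(self):
        fm = make_feature_table(
            {"P01": [1.0, 2.0, 3.0]}, extra_features={"flat": {"P01": [7.0, 7.0, 7.0]}}
        )
        with pytest.raises(ValueError):
            pearson_matrix(fm)


def _svd_oracle(X):
    """Independent PCA oracle: explicit standardization + SVD."""
    Z = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        Z[:, j] = (col - col.mean()) / col.std()  # population SD
    U, s, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    return Z, eig, Vt.T


class TestPCA:
    def test_perfectly_correlated_features(self):
        vals = [1.0, 2.0, 5.0, 7.0]
        fm = make_feature_table(
            {"P01": vals}, extra_features={"echo": {"P01": [2 * v + 1 for v in vals]}}
        )
        p = pca_morphospace(fm)
        assert p.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_data_splits_variance_evenly(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame(
            {
                "plate_id": "P01",
                "well": [f"A{i % 24 + 1:02d}" for i in range(n)],
                "role": "compound",
                "f1": rng.normal(size=n),
                "f2": rng.normal(size=n),
            }
        )
        df["well"] = [f"{chr(65 + i % 16)}{i % 24 + 1:02d}" for i in range(n)]
        df["plate_id"] = [f"P{i:04d}" for i in range(n)]  # unique keys
        p = pca_morphospace(FeatureMatrix(df))
        assert p.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_matches_svd_oracle(self, small_random_table):
        p = pca_morphospace(small_random_table)
        X = small_random_table.feature_values.to_numpy()
        _, eig, V = _svd_oracle(X)
        assert np.allclose(p.eigenvalues, eig, atol=1e-8)
        for j in range(V.shape[1]):
            load_oracle = V[:, j] * math.sqrt(eig[j])
            got = p.loadings.iloc[:, j].to_numpy()
            assert np.allclose(got, load_oracle, atol=1e-8) or np.allclose(
                got, -load_oracle, atol=1e-8
            )

    def test_loading_normalization_and_sign_convention(self, small_random_table):
        p = pca_morphospace(small_random_table)
        # per-component sum of squared loadings equals the eigenvalue
        assert np.allclose((p.loadings**2).sum(axis=0), p.eigenvalues, atol=1e-6)
        assert p.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        for j in range(p.loadings.shape[1]):
            col = p.loadings.iloc[:, j]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0

    def test_component_limit_enforced(self, small_random_table):
        with pytest.raises(ValueError):
            pca_morphospace(small_random_table, n_components=5)  # min(6-1, 4) = 4

    def test_cumulative_variance(self, small_random_table):
        p = pca_morphospace(small_random_table)
        assert cumulative_variance(p, len(p.eigenvalues)) == pytest.approx(1.0)
        partial = p.eigenvalues[:2].sum() / p.eigenvalues.sum()
        assert cumulative_variance(p, 2) == pytest.approx(partial)
        with pytest.raises(ValueError):
            cumulative_variance(p, 0)

    def test_rank_one_data(self):
        vals = [1.0, 3.0, 4.0, 10.0]
        fm = make_feature_table(
            {"P01": vals}, extra_features={"echo": {"P01": [3 * v for v in vals]}}
        )
        p = pca_morphospace(fm)
        assert cumulative_variance(p, 1) == pytest.approx(1.0, abs=1e-9)


class TestDeadWellFilter:
    @pytest.fixture
    def table(self):
        df = pd.DataFrame(
            {
                "plate_id": "P01",
                "well": ["A01", "A02", "A03", "A04", "A05", "A06"],
                "role": ["dmso", "dmso", "compound", "compound", "compound", "positive"],
                "median_colony_area": 1000.0,
                "pct_colonies_with_lumens": 0.1,
                "colony_count": [55, 65, 20, 40, 30, 5],
            }
        )
        return FeatureMatrix(df)

    def test_threshold_and_tie_rule(self, table):
        kept, dropped = filter_dead_wells(table, 0.5)  # DMSO median 60 -> cutoff 30
        assert dropped["well"].tolist() == ["A03"]  # 20 < 30 excluded
        wells = kept.data["well"].tolist()
        assert "A04" in wells  # 40 retained
        assert "A05" in wells  # exactly 30: ties retained
        assert "A06" in wells  # controls never excluded

    def test_plate_without_dmso_errors(self):
        df = pd.DataFrame(
            {
                "plate_id": "P01",
                "well": ["A01", "A02"],
                "role": ["compound", "compound"],
                "colony_count": [10, 20],
            }
        )
        with pytest.raises(ValueError):
            filter_dead_wells(FeatureMatrix(df), 0.5)


class TestFoldChange:
    def test_basic_ratio(self):
        fm = make_feature_table(
            {"P01": [90.0, 110.0, 200.0]},
            roles_by_plate={"P01": ["dmso", "dmso", "compound"]},
        )
        fc = fold_change(fm, "median_colony_area")
        assert fc.iloc[2] == pytest.approx(2.0)
        assert fc.iloc[0] == pytest.approx(0.9)

    def test_dmso_fold_changes_average_to_one(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(6, 0.3, 24).tolist()
        roles = ["dmso"] * 8 + ["compound"] * 16
        fm = make_feature_table({"P01": vals}, roles_by_plate={"P01": roles})
        fc = fold_change(fm, "median_colony_area")
        assert fc[fm.data["role"] == "dmso"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_per_plate_denominators(self):
        fm = make_feature_table(
            {"P01": [100.0, 300.0], "P02": [200.0, 300.0]},
            roles_by_plate={"P01": ["dmso", "compound"], "P02": ["dmso", "compound"]},
        )
        fc = fold_change(fm, "median_colony_area")
        assert fc.iloc[1] == pytest.approx(3.0)
        assert fc.iloc[3] == pytest.approx(1.5)

    def test_missing_dmso_errors(self):
        fm = make_feature_table({"P01": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fold_change(fm, "median_colony_area")


class TestMedianPolish:
    def test_pure_additive_matrix_has_zero_residuals(self):
        r = np.array([0.0, 1.0, 2.0])
        c = np.array([0.0, 1.0, 2.0, 3.0])
        M = 10.0 + r[:, None] + c[None, :]
        eff = median_polish(M)
        assert np.allclose(eff.residuals, 0.0, atol=1e-9)
        assert np.allclose(eff.reconstruct(), M, atol=1e-9)

    def test_single_spiked_cell(self):
        M = np.full((4, 4), 5.0)
        M[2, 2] = 15.0
        eff = median_polish(M)
        assert eff.residuals[2, 2] == pytest.approx(10.0)
        others = np.delete(eff.residuals.ravel(), 10)
        assert np.allclose(others, 0.0, atol=1e-9)
        assert eff.overall == pytest.approx(5.0)

    def test_constant_matrix(self):
        eff = median_polish(np.full((3, 5), 7.0))
        assert eff.overall == pytest.approx(7.0)
        assert np.allclose(eff.row_effects, 0.0)
        assert np.allclose(eff.col_effects, 0.0)
        assert np.allclose(eff.residuals, 0.0)

    def test_missing_cells_carry_no_residual(self):
        M = 10.0 + np.arange(3)[:, None] + np.arange(4)[None, :] * 2.0
        M[1, 2] = np.nan
        eff = median_polish(M)
        assert np.isnan(eff.residuals[1, 2])
        obs = ~np.isnan(M)
        assert np.allclose(eff.reconstruct()[obs], M[obs], atol=1e-9)

    def test_degenerate_matrices_rejected(self):
        with pytest.raises(ValueError):
            median_polish(np.full((3, 3), np.nan))
        with pytest.raises(ValueError):
            median_polish(np.array([[1.0, 2.0]]))


class TestBScore:
    def test_hand_computed_scaling(self):
        res = np.array([-2.0, -1.0, -1.0, 0.0, 0.0, 1.0, 1.0, 2.0])
        b = score_residuals(res)
        assert b[-1] == pytest.approx(2.0 / MAD_SCALE, abs=1e-3)
        assert b[-1] == pytest.approx(1.349, abs=1e-3)

    def test_composition_with_polish(self):
        rng = np.random.default_rng(12)
        M = rng.normal(50, 5, (8, 10))
        scores, eff = b_score(M)
        assert np.allclose(
            scores, score_residuals(eff.residuals), atol=1e-12, equal_nan=True
        )

    def test_additive_plate_with_one_spike(self):
        r = np.linspace(0, 30, 8)
        c = np.linspace(0, 11, 12)
        M = 100.0 + r[:, None] + c[None, :]
        M[3, 7] += 50.0
        scores, _ = b_score(M)
        # the MAD over an almost-all-zero residual plate is 0: only the
        # spiked well is nonzero, and it is unscorable rather than inflated
        nz = ~np.isnan(scores)
        assert nz.sum() == M.size - 1
        assert np.allclose(scores[nz], 0.0)
        assert np.isnan(scores[3, 7])

    def test_row_column_shift_invariance(self):
        rng = np.random.default_rng(4)
        M = rng.normal(200, 20, (16, 24))
        base, _ = b_score(M)
        shifted = M + 5.0 * (np.arange(16) == 3)[:, None]  # +5 to every well of row D
        pert, _ = b_score(shifted)
        assert np.nanmax(np.abs(pert - base)) < 1e-6

    def test_arbitrary_additive_perturbation_invariance(self):
        rng = np.random.default_rng(9)
        M = rng.normal(0, 1, (10, 14))
        r = rng.uniform(-30, 30, 10)
        c = rng.uniform(-30, 30, 14)
        base, _ = b_score(M)
        pert, _ = b_score(M + r[:, None] + c[None, :])
        assert np.nanmax(np.abs(pert - base)) < 1e-6

    def test_zero_mad_scores(self):
        M = np.full((3, 3), 4.0)
        scores, _ = b_score(M)
        assert np.allclose(scores, 0.0)


class TestTopPercentGate:
    def test_one_to_hundred(self):
        values = pd.Series(np.arange(1.0, 101.0))
        flags, thr = top_percent_gate(values, 5.0)
        # linear-interpolation 95th percentile of 1..100
        srt = np.sort(values.to_numpy())
        h = (len(srt) - 1) * 0.95
        expected = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
        assert thr == pytest.approx(expected) == pytest.approx(95.05)
        assert flags.sum() == 5
        assert set(values[flags]) == {96.0, 97.0, 98.0, 99.0, 100.0}

    def test_all_equal_flags_everything_with_warning(self, caplog):
        values = pd.Series([3.0] * 10)
        with caplog.at_level(logging.WARNING, logger="morphoscreen.analytics"):
            flags, thr = top_percent_gate(values, 5.0)
        assert flags.all()
        assert any("degenerate" in r.message for r in caplog.records)

    def test_two_values_fifty_percent(self):
        flags, thr = top_percent_gate(pd.Series([0.0, 10.0]), 50.0)
        assert thr == pytest.approx(5.0)
        assert flags.tolist() == [False, True]

    def test_population_restriction(self):
        values = pd.Series([1.0, 2.0, 3.0, 100.0])
        population = pd.Series([True, True, True, False])
        flags, thr = top_percent_gate(values, 50.0, population)
        assert thr == pytest.approx(2.0)
        assert flags.tolist() == [False, True, True, True]  # non-member still flagged

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            top_percent_gate(pd.Series(dtype=float), 5.0)


def _toy_hit_table():
    """20 wells on a 4x5 grid; wells 0 and 7 extreme on both metrics."""
    rng = np.random.default_rng(42)
    n = 20
    area = rng.normal(1000.0, 30.0, n)
    lumens = rng.normal(0.10, 0.01, n)
    area[[0, 7]] = [3000.0, 2800.0]
    lumens[[0, 7]] = [0.5, 0.45]
    rows = []
    for i in range(n):
        r, c = divmod(i, 5)
        rows.append(
            {
                "plate_id": "P01",
                "well": f"{chr(65 + r)}{c + 1:02d}",
                "role": "dmso" if i in (12, 18) else "compound",
                "compound_id": None if i in (12, 18) else f"X{i:03d}",
                "concentration_um": 1.0,
                "median_colony_area": area[i],
                "pct_colonies_with_lumens": lumens[i],
                "colony_count": 60,
            }
        )
    return FeatureMatrix(pd.DataFrame(rows)), [0, 7]


class TestCallHits:
    def test_planted_extremes_are_the_only_hits(self):
        fm, planted = _toy_hit_table()
        ht = call_hits(fm, percent=15.0, n_rows=4, n_cols=5)
        hits = ht.table.index[ht.table["is_hit"]].tolist()
        assert hits == planted

    def test_single_metric_extreme_is_not_a_hit(self):
        fm, _ = _toy_hit_table()
        df = fm.data.copy()
        # well 3: extreme area only
        df.loc[3, "median_colony_area"] = 5000.0
        ht = call_hits(FeatureMatrix(df), percent=15.0, n_rows=4, n_cols=5)
        row = ht.table.loc[3]
        assert row["gate_fold_change_area"]
        assert not row["is_hit"]

    def test_well_and_plate_order_invariance(self):
        fm, planted = _toy_hit_table()
        ht1 = call_hits(fm, percent=15.0, n_rows=4, n_cols=5)
        shuffled = FeatureMatrix(
            fm.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        ht2 = call_hits(shuffled, percent=15.0, n_rows=4, n_cols=5)
        key = lambda t: set(
            zip(t.table.loc[t.table["is_hit"], "plate_id"], t.table.loc[t.table["is_hit"], "well"])
        )
        assert key(ht1) == key(ht2)
        assert ht1.thresholds == pytest.approx(ht2.thresholds)

    def test_compound_rollup_counts_wells(self):
        fm, planted = _toy_hit_table()
        ht = call_hits(fm, percent=15.0, n_rows=4, n_cols=5)
        assert set(ht.compound_rollup["compound_id"]) == {"X000", "X007"}
        assert (ht.compound_rollup["n_hit_wells"] == 1).all()

    def test_dead_wells_cannot_be_hits(self):
        fm, planted = _toy_hit_table()
        df = fm.data.copy()
        df.loc[planted, "colony_count"] = 5  # extremes are cytotoxic artifacts
        ht = call_hits(FeatureMatrix(df), percent=15.0, dead_fraction=0.5, n_rows=4, n_cols=5)
        assert ht.table.loc[planted, "excluded_dead"].all()
        assert not ht.table.loc[planted, "is_hit"].any()


class TestControlSeparation:
    def test_disjoint_samples_separate(self):
        rng = np.random.default_rng(1)
        dmso_area = rng.normal(1000, 50, 14)
        pos_area = 3 * dmso_area
        vals = np.concatenate([dmso_area, pos_area])
        roles = ["dmso"] * 14 + ["positive"] * 14
        fm = make_feature_table(
            {"P01": vals.tolist()},
            roles_by_plate={"P01": roles},
            extra_features={
                "pct_colonies_with_lumens": {"P01": ([0.1] * 14 + [0.5] * 14)}
            },
        )
        # perturb the constant-ish lumen columns to avoid ties
        df = fm.data.copy()
        df["pct_colonies_with_lumens"] += rng.normal(0, 0.005, 28)
        sep = control_separation(FeatureMatrix(df))
        assert sep.passed
        for metric, d in sep.metrics.items():
            assert d["p_value"] < 1e-4
            assert d["positive_median"] > d["dmso_median"]
        # exact rank-sum z for fully disjoint 14 vs 14
        z = (14 * 14 / 2) / math.sqrt(14 * 14 * 29 / 12)
        assert sep.metrics["median_colony_area"]["statistic"] == pytest.approx(z)

    def test_identical_distributions_fail_qc(self):
        vals = list(np.linspace(900, 1100, 14)) * 2
        roles = ["dmso"] * 14 + ["positive"] * 14
        fm = make_feature_table(
            {"P01": vals},
            roles_by_plate={"P01": roles},
            extra_features={"pct_colonies_with_lumens": {"P01": [0.1] * 28}},
        )
        sep = control_separation(fm)
        assert not sep.passed
        assert sep.metrics["median_colony_area"]["p_value"] > 0.9

    def test_medians_match_direct_computation(self):
        vals = [10.0, 20.0, 30.0, 100.0, 200.0, 300.0]
        roles = ["dmso"] * 3 + ["positive"] * 3
        fm = make_feature_table(
            {"P01": vals},
            roles_by_plate={"P01": roles},
            extra_features={"pct_colonies_with_lumens": {"P01": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]}},
        )
        sep = control_separation(fm)
        assert sep.metrics["median_colony_area"]["dmso_median"] == 20.0
        assert sep.metrics["median_colony_area"]["positive_median"] == 200.0

    def test_missing_role_errors(self):
        fm = make_feature_table({"P01": [1.0, 2.0]})
        with pytest.raises(ValueError):
            control_separation(fm)


class TestNormalizeColonyCounts:
    def test_half(self):
        out = normalize_colony_counts([8, 10, 12], [20, 20, 20])
        assert out["mean"] == pytest.approx(0.5)

    def test_identity(self):
        out = normalize_colony_counts([20, 20, 20], [20, 20, 20])
        assert out["mean"] == pytest.approx(1.0)
        assert out["sem"] == pytest.approx(0.0)

    def test_small_fraction(self):
        out = normalize_colony_counts([1, 1, 1], [20, 19, 21])
        assert out["mean"] == pytest.approx(0.05, abs=1e-12)

    def test_zero_control_errors(self):
        with pytest.raises(ValueError):
            normalize_colony_counts([1.0], [0.0, 0.0])
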