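import numpy as np
import pandas as pd
import pytest

from vpdgrowth import drivers as drv
from vpdgrowth.growth_model import GrowthModelFit


def make_table(n=80, seed=0, signal="mat", species_levels=("PIMA", "PIGL", "PIBA")):
    """Synthetic sensitivity table with a known generative signal."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "site_id": [f"S{i}" for i in range(n)],
        "species": rng.choice(species_levels, n),
        "which_covariate": rng.choice(["vpd_t", "vpd_t1"], n),
        "elevation": rng.uniform(100, 1500, n),
        "mat": rng.uniform(-3, 6, n),
        "map": rng.uniform(300, 1200, n),
        "summer_smi": rng.uniform(30, 90, n),
        "mean_age": rng.uniform(40, 200, n),
        "mean_ba": rng.uniform(100, 900, n),
    })
    noise = 0.3 * rng.standard_normal(n)
    if signal == "mat":
        df["t_value"] = -1.0 * df["mat"] + noise
    elif signal == "age":
        df["t_value"] = 0.03 * df["mean_age"] + noise
    elif signal == "none":
        df["t_value"] = rng.standard_normal(n)
    return df


class TestAssemble:
    def _fit(self, sid, spp, t1, p1, t2, p2, converged=True):
        return GrowthModelFit(converged=converged, site_id=sid, species=spp,
                              t_beta1=t1, p_beta1=p1, t_beta2=t2, p_beta2=p2)

    def _frames(self, sites):
        ss = pd.DataFrame([{"site_id": s, "species": "PIMA", "mean_age": 80.0,
                            "mean_ba": 400.0} for s in sites])
        cl = pd.DataFrame([{"site_id": s, "elevation": 300.0, "mat": 1.0,
                            "map": 700.0, "summer_smi": 60.0} for s in sites])
        return ss, cl

    def test_counts_significant_only(self):
        fits = [self._fit(f"S{i}", "PIMA", -1.0, 0.5, -3.0, 0.01) for i in range(10)]
        fits += [self._fit(f"S{i}", "PIMA", 0.0, 0.9, 0.1, 0.9) for i in range(10, 16)]
        ss, cl = self._frames([f"S{i}" for i in range(16)])
        out = drv.assemble_sensitivity_table(fits, ss, cl)
        assert len(out) == 10
        assert set(out["which_covariate"]) == {"vpd_t1"}

    def test_nonconverged_skipped(self):
        fits = [self._fit("S0", "PIMA", -5.0, 0.001, -5.0, 0.001, converged=False)]
        ss, cl = self._frames(["S0"])
        assert drv.assemble_sensitivity_table(fits, ss, cl).empty

    def test_empty_table_refused_downstream(self):
        fits = [self._fit("S0", "PIMA", 0.1, 0.9, 0.1, 0.9)]
        ss, cl = self._frames(["S0"])
        table = drv.assemble_sensitivity_table(fits, ss, cl)
        with pytest.raises(drv.DriverError, match="empty"):
            drv.fit_forest(table)

    def test_missing_predictor_dropped(self):
        fits = [self._fit("S0", "PIMA", -3.0, 0.01, 0.0, 0.9),
                self._fit("S1", "PIMA", -3.0, 0.01, 0.0, 0.9)]
        ss, cl = self._frames(["S0", "S1"])
        cl.loc[cl["site_id"] == "S1", "mat"] = np.nan
        with pytest.warns(UserWarning, match="missing predictors"):
            out = drv.assemble_sensitivity_table(fits, ss, cl)
        assert len(out) == 1


class TestForest:
    def test_determinism(self):
        table = make_table(60, seed=1)
        a = drv.fit_forest(table, n_trees=50, seed=9)
        b = drv.fit_forest(table, n_trees=50, seed=9)
        assert np.allclose(a.model.predict(a.X), b.model.predict(b.X))
        ra = drv.importance_report(a, seed=3)
        rb = drv.importance_report(b, seed=3)
        pd.testing.assert_frame_equal(ra, rb)

    def test_single_deep_tree_interpolates(self):
        table = make_table(5, seed=2)
        f = drv.fit_forest(table, n_trees=1, seed=0, min_samples_leaf=1,
                           bootstrap=False)
        np.testing.assert_allclose(f.model.predict(f.X), f.y)

    def test_constant_response_rejected(self):
        table = make_table(40, seed=3)
        table["t_value"] = 1.0
        with pytest.raises(drv.DriverError, match="constant"):
            drv.fit_forest(table)

    def test_small_table_warns(self):
        with pytest.warns(UserWarning, match="noisy"):
            drv.fit_forest(make_table(10, seed=4), n_trees=20)

    def test_oob_mse_beats_variance_with_signal(self):
        table = make_table(150, seed=5, signal="mat")
        f = drv.fit_forest(table, n_trees=100, seed=0)
        preds = np.zeros(len(f.y))
        counts = np.zeros(len(f.y))
        for est, oob in zip(f.model.estimators_, f.oob_indices):
            preds[oob] += est.predict(f.X[oob])
            counts[oob] += 1
        ok = counts > 0
        oob_mse = np.mean((preds[ok] / counts[ok] - f.y[ok]) ** 2)
        assert oob_mse < np.var(f.y)


class TestImportance:
    def test_null_predictor_near_zero(self):
        table = make_table(150, seed=6, signal="mat")
        f = drv.fit_forest(table, n_trees=100, seed=0)
        imp = drv.permutation_importance(f, seed=0)
        assert imp["mat"] > 10 * abs(imp["mean_ba"])

    def test_mat_signal_recovered(self):
        wins = 0
        for s in range(5):
            table = make_table(120, seed=100 + s, signal="mat")
            f = drv.fit_forest(table, n_trees=100, seed=s)
            imp = drv.permutation_importance(f, seed=s)
            if max(imp, key=imp.get) == "mat":
                wins += 1
        assert wins >= 4

    def test_duplicated_predictor_masks(self):
        table = make_table(150, seed=7, signal="mat")
        # duplicate the informative column into an unused slot
        table2 = table.copy()
        table2["map"] = table2["mat"] + 1e-9  # map now clones the signal
        f1 = drv.fit_forest(table, n_trees=100, seed=0)
        f2 = drv.fit_forest(table2, n_trees=100, seed=0)
        i1 = drv.permutation_importance(f1, seed=0)
        i2 = drv.permutation_importance(f2, seed=0)
        assert i2["mat"] < i1["mat"]  # importance split between the clones


class TestMinimalDepth:
    def test_root_counts_sum_to_n_trees(self):
        f = drv.fit_forest(make_table(100, seed=8), n_trees=60, seed=1)
        md = drv.minimal_depth_stats(f)
        assert md["root_node_count"].sum() == 60
        assert (md["avg_min_depth"] >= 0).all()

    def test_single_informative_predictor_is_root(self):
        table = make_table(120, seed=9, signal="mat")
        table["t_value"] = -1.0 * table["mat"]  # noise-free
        f = drv.fit_forest(table, n_trees=50, seed=0, mtry=99)
        md = drv.minimal_depth_stats(f).set_index("variable")
        assert md.loc["mat", "root_node_count"] == 50
        assert md.loc["mat", "avg_min_depth"] == 0.0

    def test_dominant_predictor_lowest_depth(self):
        table = make_table(150, seed=10, signal="age")
        f = drv.fit_forest(table, n_trees=100, seed=0)
        md = drv.minimal_depth_stats(f).set_index("variable")
        assert md["avg_min_depth"].idxmin() == "mean_age"


class TestPartialDependence:
    def test_constant_model_flat(self):
        table = make_table(60, seed=11)
        table["t_value"] = np.where(np.arange(60) % 2, 1.0, 1.0001)
        f = drv.fit_forest(table, n_trees=20, seed=0)
        pd_curve = drv.partial_dependence(f, "mat")
        assert np.ptp(pd_curve["pd"].to_numpy()) < 1e-3

    def test_monotone_signal(self):
        table = make_table(200, seed=12, signal="age")
        f = drv.fit_forest(table, n_trees=100, seed=0)
        curve = drv.partial_dependence(f, "mean_age", n_grid=15)
        inner = curve[curve["in_95pct_coverage"]]["pd"].to_numpy()
        # non-decreasing up to small edge noise
        assert np.min(np.diff(inner)) > -0.1 * np.ptp(inner)
        assert np.corrcoef(np.arange(len(inner)), inner)[0, 1] > 0.9

    def test_species_levels_invariant_to_order(self):
        table = make_table(100, seed=13)
        f = drv.fit_forest(table, n_trees=30, seed=0)
        out = drv.partial_dependence(f, "species")
        assert set(out["level"]) == set(table["species"].unique())

    def test_unknown_variable(self):
        f = drv.fit_forest(make_table(60, seed=14), n_trees=10, seed=0)
        with pytest.raises(drv.DriverError):
            drv.partial_dependence(f, "nope")

    def test_extrapolation_warns(self):
        f = drv.fit_forest(make_table(60, seed=15), n_trees=10, seed=0)
        with pytest.warns(UserWarning, match="beyond observed"):
            out = drv.partial_dependence(f, "mat", grid=[-50.0, 0.0])
        assert out["extrapolated"].iloc[0]


class TestTriMetricDominance:
    def test_informative_predictor_dominates_all_three(self):
        table = make_table(200, seed=16, signal="mat")
        f = drv.fit_forest(table, n_trees=200, seed=0)
        rep = drv.importance_report(f, seed=0).set_index("variable")
        assert rep["mse_increase"].idxmax() == "mat"
        assert rep["avg_min_depth"].idxmin() == "mat"
        assert rep["root_node_count"].idxmax() == "mat"
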