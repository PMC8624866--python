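"""Evaluation metrics, LOOCV, and the NN-informed hybrid pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwmap import (
    HybridConfig,
    InterpolatorSpec,
    PSOConfig,
    SampleSet,
    augment_with_nn,
    hybrid_interpolate,
    idw_predict,
    loocv,
    mae,
    make_grid,
    mse,
    pearson_r,
    predict_grid,
    run_method_comparison,
    select_governing,
)
from gwmap.metrics import CVRow
from gwmap.synthetic import FieldSpec, make_survey

finite_vec = st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=3,
                      max_size=12)


class TestMetrics:
    def test_mae_forced_arithmetic(self):
        assert mae([1, 2, 3], [2, 2, 5]) == pytest.approx(1.0)
        assert mae([1.0, 1.0], [1.0, 1.0]) == 0.0

    def test_mse_forced_arithmetic(self):
        assert mse([0, 0, 0], [1, 0, 2]) == pytest.approx(5 / 3)

    def test_pearson_toy_direct_formula(self):
        assert pearson_r([1, 2, 3, 4], [2, 4, 5, 9]) == pytest.approx(
            11 / np.sqrt(130), abs=1e-12)
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_length_mismatch_and_constant(self):
        with pytest.raises(ValueError):
            mae([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3], strict=False))

    @given(finite_vec, st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance_and_jensen(self, xs, rnd):
        obs = np.array(xs)
        pred = obs + 1.0
        perm = list(range(len(xs)))
        rnd.shuffle(perm)
        assert mae(pred[perm], obs[perm]) == pytest.approx(mae(pred, obs))
        assert mse(pred, obs) >= mae(pred, obs) ** 2 - 1e-9

    def test_direct_formula_oracles_random_vectors(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert mae(a, b) == pytest.approx(np.sum(np.abs(a - b)) / 50, abs=1e-12)
        assert mse(a, b) == pytest.approx(np.sum((a - b) ** 2) / 50, abs=1e-12)
        am, bm = a - a.mean(), b - b.mean()
        r_direct = np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))
        assert pearson_r(a, b) == pytest.approx(r_direct, abs=1e-12)


class TestSelectGoverning:
    def test_single_row(self):
        row = CVRow("idw", False, 0.5, 0.9, 10)
        assert select_governing([row]) is row

    def test_mae_primary(self):
        rows = [CVRow("ok", True, 0.002, 0.94, 36),
                CVRow("ebk", True, 0.005, 0.99, 36)]
        assert select_governing(rows).method == "ok"

    def test_tie_broken_by_r(self):
        rows = [CVRow("a", False, 0.1, 0.90, 5),
                CVRow("b", False, 0.1, 0.95, 5)]
        assert select_governing(rows).method == "b"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_governing([])


class TestLOOCV:
    def test_matches_brute_force_refit(self, toy_survey):
        spec = InterpolatorSpec("idw", {"p": 2.0, "k": 15})
        row = loocv(spec, toy_survey, "Cd")
        xy = toy_survey.coords()
        z = toy_survey.values("Cd")
        preds = []
        for i in range(len(toy_survey)):  # independent naive refit loop
            rest = SampleSet(toy_survey.data.drop(index=i))
            preds.append(idw_predict(rest, "Cd", xy[i:i + 1], p=2.0, k=15)[0])
        assert row.mae == pytest.approx(mae(preds, z), abs=1e-10)
        assert row.r == pytest.approx(pearson_r(preds, z), abs=1e-10)

    def test_manual_fold_arithmetic_on_linear_field(self):
        # 4 stations on a plane z = x/1000; hold out the interior point and
        # the exact-plane methods must return its true value
        xy = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0],
                       [1000.0, 1000.0], [500.0, 500.0]])
        z = xy[:, 0] / 1000.0
        df = pd.DataFrame({"station_id": [f"S{i}" for i in range(5)],
                           "lon": 121.0, "lat": 13.0, "season": "dry",
                           "x": xy[:, 0], "y": xy[:, 1], "Cd": z})
        s = SampleSet(df)
        row = loocv(InterpolatorSpec("gpi", {"degree": 1}), s, "Cd")
        assert row.mae == pytest.approx(0.0, abs=1e-8)

    def test_deterministic_repeat(self, toy_survey):
        a = loocv(InterpolatorSpec("rbf"), toy_survey, "Cd")
        b = loocv(InterpolatorSpec("rbf"), toy_survey, "Cd")
        assert a.mae == b.mae and a.r == b.r

    def test_constant_field_zero_mae(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 1000, (8, 2))
        df = pd.DataFrame({"station_id": [f"S{i}" for i in range(8)],
                           "lon": 121.0, "lat": 13.0, "season": "dry",
                           "x": xy[:, 0], "y": xy[:, 1], "Cd": 2.5})
        row = loocv(InterpolatorSpec("idw"), SampleSet(df), "Cd")
        assert row.mae == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(row.r)  # constant predictions: R undefined

    def test_too_few_stations(self, toy_survey):
        small = SampleSet(toy_survey.data.iloc[:4])
        with pytest.raises(ValueError):
            loocv(InterpolatorSpec("idw"), small, "Cd")


def _hybrid_cfg(aux, target="Cd", n_aux=30, pso_iters=20, particles=4,
                hidden=4, seed=0):
    n_cells = len(aux["latent"])
    aux_df = pd.DataFrame({k: v for k, v in aux.items() if k != "latent"})
    return HybridConfig(
        target=target, covariates=("x", "y", "temp", "pH", "EC", "TDS"),
        aux_sites=aux_df, n_aux=n_aux, n_hidden=hidden, partition_seed=seed,
        pso=PSOConfig(n_particles=particles, n_iterations=pso_iters, seed=seed),
        lm_kwargs={"max_iter": 40},
    )


@pytest.fixture(scope="module")
def hybrid_setup():
    sv, truth, aux = make_survey(FieldSpec(seed=11))
    cells = truth.cell_centers()
    aux = dict(aux)
    aux["x"], aux["y"] = cells[:, 0], cells[:, 1]
    return sv, truth, aux


class TestAugment:
    def test_zero_aux_is_identity(self, hybrid_setup):
        sv, _, aux = hybrid_setup
        cfg = _hybrid_cfg(aux, n_aux=0)
        out = augment_with_nn(sv, cfg)
        assert out.data.equals(sv.data)

    def test_deterministic(self, hybrid_setup):
        sv, _, aux = hybrid_setup
        cfg = _hybrid_cfg(aux)
        a = augment_with_nn(sv, cfg)
        b = augment_with_nn(sv, cfg)
        assert a.data.equals(b.data)

    def test_pseudo_flagged_and_located(self, hybrid_setup):
        sv, _, aux = hybrid_setup
        out = augment_with_nn(sv, _hybrid_cfg(aux))
        pseudo = out.data[out.data["is_pseudo"]]
        assert len(pseudo) == 30
        assert pseudo["Cd"].notna().all()
        assert len(out.measured()) == len(sv)

    def test_informative_covariates_recover_field(self):
        """Noise-free identity link: network predictions at auxiliary sites
        track the true latent field (MAE < 5% of range)."""
        spec = FieldSpec(link_coefficients={"temp": 1.0},
                         covariate_noise_sd=0.0, noise_sd=0.0, seed=21)
        sv, truth, aux = make_survey(spec)
        cells = truth.cell_centers()
        aux = {"latent": aux["latent"], "temp": aux["temp"],
               "x": cells[:, 0], "y": cells[:, 1]}
        aux_df = pd.DataFrame({k: aux[k] for k in ("x", "y", "temp")})
        cfg = HybridConfig(target="Cd", covariates=("temp",),
                           aux_sites=aux_df, n_aux=50, n_hidden=4,
                           pso=PSOConfig(n_particles=6, n_iterations=50, seed=0),
                           lm_kwargs={"max_iter": 80})
        out = augment_with_nn(sv, cfg)
        pseudo = out.data[out.data["is_pseudo"]]
        idx = np.linspace(0, len(aux_df) - 1, 50).round().astype(int)
        true_vals = aux["latent"][idx]
        rng_span = true_vals.max() - true_vals.min()
        assert mae(pseudo["Cd"].to_numpy(), true_vals) < 0.05 * rng_span

    def test_missing_covariate_sites_skipped(self, hybrid_setup):
        sv, _, aux = hybrid_setup
        cfg = _hybrid_cfg(aux)
        cfg.aux_sites = cfg.aux_sites.copy()
        cfg.aux_sites.loc[0, "temp"] = np.nan
        with pytest.warns(UserWarning, match="skipped"):
            out = augment_with_nn(sv, cfg)
        assert out.data["is_pseudo"].sum() == 30  # still capped at n_aux

    def test_target_in_covariates_rejected(self):
        with pytest.raises(ValueError):
            HybridConfig(target="Cd", covariates=("x", "Cd"))


class TestHybridInterpolate:
    def test_zero_aux_bit_identical_to_plain(self, hybrid_setup):
        sv, truth, aux = hybrid_setup
        grid = make_grid(sv, cellsize=4000.0, padding=500.0)
        spec = InterpolatorSpec("idw")
        cfg = _hybrid_cfg(aux, n_aux=0)
        a = hybrid_interpolate(spec, sv, cfg, grid)
        b = predict_grid(spec, sv, "Cd", grid)
        assert np.array_equal(a.values, b.values)

    def test_pseudo_points_change_surface(self, hybrid_setup):
        sv, truth, aux = hybrid_setup
        grid = make_grid(sv, cellsize=4000.0, padding=500.0)
        spec = InterpolatorSpec("idw")
        a = hybrid_interpolate(spec, sv, _hybrid_cfg(aux), grid)
        b = predict_grid(spec, sv, "Cd", grid)
        assert not np.allclose(a.values, b.values)

    def test_lambda_pseudo_downweights_lpi(self, hybrid_setup):
        sv, truth, aux = hybrid_setup
        grid = make_grid(sv, cellsize=6000.0, padding=500.0)
        spec = InterpolatorSpec("lpi", {"degree": 1, "bandwidth": 8000.0})
        full = _hybrid_cfg(aux)
        soft = _hybrid_cfg(aux)
        soft.lambda_pseudo = 1e-6
        a = hybrid_interpolate(spec, sv, full, grid)
        b = hybrid_interpolate(spec, sv, soft, grid)
        plain = predict_grid(spec, sv, "Cd", grid)
        # near-zero pseudo weight recovers (approximately) the plain surface
        assert np.nanmax(np.abs(b.values - plain.values)) < \
            np.nanmax(np.abs(a.values - plain.values))


class TestNoFreeLunch:
    def test_uninformative_covariates_still_run(self):
        """Zero link coefficients: covariates are pure noise; the pipeline
        must still complete (hybrids are not required to win here)."""
        spec = FieldSpec(link_coefficients={"temp": 0.0, "pH": 0.0},
                         seed=31)
        sv, truth, aux = make_survey(spec)
        cells = truth.cell_centers()
        aux_df = pd.DataFrame({"x": cells[:, 0], "y": cells[:, 1],
                               "temp": aux["temp"], "pH": aux["pH"]})
        cfg = HybridConfig(target="Cd", covariates=("temp", "pH"),
                           aux_sites=aux_df, n_aux=20, n_hidden=2,
                           pso=PSOConfig(n_particles=3, n_iterations=10,
                                         seed=0),
                           lm_kwargs={"max_iter": 10})
        row = loocv(InterpolatorSpec("idw"), sv, "Cd", hybrid=cfg, seed=0)
        assert np.isfinite(row.mae) and row.mae >= 0


class TestMethodComparison:
    def test_single_method_single_row(self, toy_survey):
        rep = run_method_comparison(toy_survey, "Cd", ["idw"], hybrid=(False,))
        assert len(rep.rows) == 1
        assert rep.governing.method == "idw"

    def test_table_layout_and_determinism(self, hybrid_setup):
        sv, _, aux = hybrid_setup
        cfg = _hybrid_cfg(aux, n_aux=10, pso_iters=5, particles=3)
        a = run_method_comparison(sv, "Cd", ["idw", "gpi"], hybrid_cfg=cfg,
                                  hybrid=(False, True), seed=1)
        b = run_method_comparison(sv, "Cd", ["idw", "gpi"], hybrid_cfg=cfg,
                                  hybrid=(False, True), seed=1)
        recs = a.to_records()
        assert len(recs) == 4
        assert {r["method"] for r in recs} == {"IDW", "IDW+NN-PSO", "GPI",
                                               "GPI+NN-PSO"}
        assert all(set(r) >= {"parameter", "season", "method", "MAE", "R"}
                   for r in recs)
        assert [r.mae for r in a.rows] == [r.mae for r in b.rows]

    def test_pseudo_never_held_out(self, hybrid_setup):
        sv, _, aux = hybrid_setup
        cfg = _hybrid_cfg(aux, n_aux=10, pso_iters=5, particles=3)
        row = loocv(InterpolatorSpec("idw"), sv, "Cd", hybrid=cfg, seed=0)
        assert row.n_folds == len(sv.measured())
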