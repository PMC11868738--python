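"""Use-availability design construction, collinearity screen and GLMM fit."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

from nestpattern.geometry import PointSet, SpatialFeatureSet
from nestpattern.glmm import (
    GlmmConfig,
    PREDICTORS,
    UseAvailabilityGLMM,
    build_design,
    collinearity_report,
    standardize,
)
from nestpattern.simulate import SimulatedPattern, SimulationConfig, simulate_ensemble


@pytest.fixture(scope="module")
def toy_features():
    """100x10 rectangle with shore at y=0, edge at y=10, one lek."""
    return SpatialFeatureSet(
        region=Polygon([(0, 0), (100, 0), (100, 10), (0, 10)]),
        shore=LineString([(0, 0), (100, 0)]),
        edge=LineString([(0, 10), (100, 10)]),
        lek_coords=[(0.0, 0.0)],
        lek_active_years=[{2018}],
    )


def _pattern(coords, year=2018, rid=1):
    return SimulatedPattern(rid, year, PointSet(coords), 0)


def test_build_design_row_count_and_hand_computed_predictors(toy_features):
    observed = {2018: PointSet([(0, 2), (3, 6)])}
    ens = [_pattern([(10, 2), (10, 6)], rid=1), _pattern([(50, 5), (54, 8)], rid=2)]
    design = build_design(observed, ens, toy_features)
    assert len(design) == 3  # 1 observed + 2 simulated
    obs = design[design.source == "observed"].iloc[0]
    assert obs["d_nests"] == pytest.approx(5.0)            # both nests 5 m apart
    assert obs["d_shore"] == pytest.approx((2 + 6) / 2)
    assert obs["d_edge"] == pytest.approx((8 + 4) / 2)
    assert obs["d_leks"] == pytest.approx((2 + np.hypot(3, 6)) / 2)


def test_build_design_observed_equal_to_replicate_gives_identical_rows(toy_features):
    coords = [(10, 2), (20, 7), (40, 3)]
    design = build_design({2018: PointSet(coords)}, [_pattern(coords)], toy_features)
    a, b = design[list(PREDICTORS)].to_numpy()
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_build_design_nest_level_rows(toy_features):
    observed = {2018: PointSet([(0, 2), (3, 6), (9, 9)])}
    ens = [_pattern([(10, 2), (10, 6)], rid=1)]
    design = build_design(observed, ens, toy_features, unit="nest")
    assert len(design) == 5  # 3 observed nests + 2 simulated points
    first = design.iloc[0]
    assert first["d_nests"] == pytest.approx(5.0)  # its own nearest neighbour


def test_build_design_year_mismatch_errors(toy_features):
    with pytest.raises(ValueError, match="year mismatch"):
        build_design({2019: PointSet([(0, 1), (1, 1)])}, [_pattern([(0, 1), (1, 1)])],
                     toy_features)


def test_standardize_convention_and_zero_variance():
    df = pd.DataFrame({"d_nests": [0.0, 10.0], "year": [1, 1]})
    out, scaling = standardize(df, ["d_nests"])
    np.testing.assert_allclose(out["d_nests"], [-np.sqrt(0.5), np.sqrt(0.5)])
    assert scaling["d_nests"] == (5.0, pytest.approx(np.sqrt(50.0)))
    # an already-standardised column is unchanged
    again, _ = standardize(out, ["d_nests"])
    np.testing.assert_allclose(again["d_nests"], out["d_nests"], atol=1e-12)
    with pytest.raises(ValueError, match="d_nests"):
        standardize(pd.DataFrame({"d_nests": [1.0, 1.0]}), ["d_nests"])


def test_standardized_columns_have_mean_zero_sd_one(rng):
    df = pd.DataFrame({c: rng.normal(5, 3, 50) for c in PREDICTORS})
    out, _ = standardize(df)
    for c in PREDICTORS:
        assert out[c].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[c].std(ddof=1) == pytest.approx(1.0, rel=1e-12)


def test_collinearity_perfect_orthogonal_and_constructed(rng):
    n = 200
    x1 = rng.normal(size=n)
    df = pd.DataFrame({"a": x1, "b": 2 * x1})
    rep = collinearity_report(df, columns=["a", "b"])
    assert rep.correlation.loc["a", "b"] == pytest.approx(1.0)
    x2 = rng.normal(size=n)
    rep2 = collinearity_report(pd.DataFrame({"a": x1, "b": x2}), columns=["a", "b"])
    assert abs(rep2.correlation.loc["a", "b"]) < 0.2
    assert (rep2.vif < 1.1).all()
    # x3 = x1 + noise: VIF must match the closed form 1/(1-R^2)
    x3 = x1 + 0.5 * rng.normal(size=n)
    df3 = pd.DataFrame({"a": x1, "b": x2, "c": x3})
    rep3 = collinearity_report(df3, columns=["a", "b", "c"])
    X = df3[["a", "b"]].to_numpy()
    X = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(X, x3, rcond=None)
    resid = x3 - X @ beta
    r2 = 1 - resid.var() / x3.var()
    assert rep3.vif["c"] == pytest.approx(1 / (1 - r2), rel=1e-6)


def test_vif_matches_statsmodels_reference(rng):
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = rng.normal(size=(120, 3))
    X[:, 2] += 0.8 * X[:, 0]
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    rep = collinearity_report(df, columns=["a", "b", "c"])
    Xc = np.column_stack([np.ones(len(df)), X])
    ref = [variance_inflation_factor(Xc, i + 1) for i in range(3)]
    np.testing.assert_allclose(rep.vif.to_numpy(), ref, rtol=1e-8)


def test_collinearity_errors():
    with pytest.raises(ValueError):
        collinearity_report(pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}),
                            columns=["a", "b"])
    with pytest.raises(ValueError, match="constant"):
        collinearity_report(pd.DataFrame({"a": [1.0] * 5, "b": np.arange(5.0)}),
                            columns=["a", "b"])


def _balanced_design(rng, n_per_year=40, years=(2018, 2019)):
    rows = []
    for year in years:
        for i in range(n_per_year):
            rows.append({"year": year, "source": "observed" if i % 2 == 0 else "simulated",
                         "replicate_id": i,
                         **{c: rng.normal() for c in PREDICTORS}})
    return pd.DataFrame(rows)


def test_intercept_only_balanced_labels_centre_at_zero(rng):
    design = _balanced_design(rng)
    cfg = GlmmConfig(chains=2, warmup=500, draws=500, seed=3)
    res = UseAvailabilityGLMM(design, predictors=(), config=cfg).fit()
    assert abs(res.params["intercept"]) < 3 * res.summary().loc["intercept", "sd"]


def test_posterior_agrees_across_seeds(rng):
    design = _balanced_design(rng)
    fits = []
    for seed in (1, 2):
        cfg = GlmmConfig(chains=2, warmup=600, draws=600, seed=seed)
        fits.append(UseAvailabilityGLMM(design, config=cfg).fit())
    a, b = fits
    for name in a.params.index:
        sd = max(a.summary().loc[name, "sd"], 1e-6)
        assert abs(a.params[name] - b.params[name]) < 3 * sd


def test_fit_invariant_to_affine_rescaling_of_raw_units(rng):
    design = _balanced_design(rng, n_per_year=60)
    scaled = design.copy()
    scaled[list(PREDICTORS)] = scaled[list(PREDICTORS)] * 1000.0 + 77.0
    cfg = GlmmConfig(chains=2, warmup=600, draws=600, seed=5)
    res_a = UseAvailabilityGLMM(design, config=cfg).fit()
    res_b = UseAvailabilityGLMM(scaled, config=cfg).fit()
    for name in res_a.params.index:
        sd = max(res_a.summary().loc[name, "sd"], 1e-6)
        assert abs(res_a.params[name] - res_b.params[name]) < 3 * sd


def test_single_year_degrades_with_warning(rng):
    design = _balanced_design(rng, years=(2018,))
    with pytest.warns(UserWarning, match="fixed intercept"):
        UseAvailabilityGLMM(design)


def test_summary_reports_required_columns(small_landscape, rng):
    from nestpattern.simulate import simulate_csr

    counts = {2018: 12, 2019: 15}
    nests = {y: simulate_csr(small_landscape.region, n, seed=y) for y, n in counts.items()}
    ens = simulate_ensemble(small_landscape.region, counts, SimulationConfig(30, 2))
    cfg = GlmmConfig(chains=2, warmup=400, draws=400, seed=9)
    res = UseAvailabilityGLMM.from_patterns(nests, ens, small_landscape, config=cfg).fit()
    tab = res.summary()
    assert list(tab.index) == ["intercept", "beta_nests", "beta_leks", "beta_edge",
                               "beta_shore", "sigma_year"]
    for col in ("mean", "sd", "cri_2.5%", "cri_97.5%", "ess", "rhat"):
        assert col in tab.columns
    assert (tab["cri_2.5%"] <= tab["cri_97.5%"]).all()
    assert (tab["ess"] > 0).all()
    assert isinstance(res.converged, bool)
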