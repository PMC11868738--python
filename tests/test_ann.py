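"""ANN statistics, the pseudo p-value formula and Stouffer combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from shapely.geometry import LineString, Polygon

from nestpattern.ann import (
    AnnRandomizationTest,
    ann,
    ann_to_feature,
    combine_pseudo_p,
    pseudo_p,
    run_ann_test,
)
from nestpattern.geometry import PointSet
from nestpattern.simulate import SimulatedPattern, SimulationConfig, simulate_csr, simulate_ensemble

UNIT_SQUARE = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


def _patterns(coords_list, year=2018):
    return [SimulatedPattern(i, year, PointSet(c), 0) for i, c in enumerate(coords_list)]


def test_ann_known_values(rng):
    assert ann(PointSet([(0, 0), (10, 0)])) == pytest.approx(10.0)
    assert ann(PointSet([(0, 0), (1, 0), (3, 0)])) == pytest.approx(4.0 / 3.0)
    coords = rng.uniform(0, 100, (100, 2))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert ann(PointSet(coords)) == pytest.approx(d.min(axis=1).mean(), rel=1e-9)


def test_ann_to_feature_lines_points_and_oracle(rng):
    line = LineString([(-100, 0), (100, 0)])
    pts = PointSet([(0, 1), (5, 2), (-3, 3)])
    assert ann_to_feature(pts, line) == pytest.approx(2.0)
    leks = PointSet([(1, 1), (4, 4)])
    assert ann_to_feature(PointSet([(1, 1), (4, 4)]), leks) == pytest.approx(0.0)
    random_pts = rng.uniform(0, 50, (30, 2))
    targets = rng.uniform(0, 50, (4, 2))
    oracle = np.linalg.norm(random_pts[:, None] - targets[None, :], axis=-1).min(axis=1).mean()
    assert ann_to_feature(PointSet(random_pts), PointSet(targets)) == pytest.approx(oracle, rel=1e-9)


@pytest.mark.parametrize(
    "n_greater,n_total,expected",
    [
        (1000, 1000, 1 / 1001),
        (0, 1000, 1 / 1001),
        (500, 1000, 501 / 1001),
    ],
)
def test_pseudo_p_formula_values(n_greater, n_total, expected):
    assert pseudo_p(n_greater, n_total) == pytest.approx(expected, rel=1e-12)


def test_pseudo_p_rejects_out_of_range():
    with pytest.raises(ValueError):
        pseudo_p(-1, 10)
    with pytest.raises(ValueError):
        pseudo_p(11, 10)
    with pytest.raises(ValueError):
        pseudo_p(0, 0)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(n_total=st.integers(1, 5000), n_greater=st.integers(0, 5000))
def test_pseudo_p_symmetry_and_bounds(n_total, n_greater):
    n_greater = min(n_greater, n_total)
    p = pseudo_p(n_greater, n_total)
    # folded symmetry and attainable range
    assert p == pytest.approx(pseudo_p(n_total - n_greater, n_total), rel=1e-12)
    assert 1 / (n_total + 1) <= p <= 1.0
    if n_greater in (0, n_total):
        assert p == pytest.approx(1 / (n_total + 1), rel=1e-12)
    else:
        assert p > 1 / (n_total + 1)


def test_stouffer_combination_known_values():
    assert combine_pseudo_p([0.3]).combined_p == pytest.approx(0.3, rel=1e-9)
    assert combine_pseudo_p([0.5] * 5).combined_p == pytest.approx(0.5, rel=1e-9)
    res = combine_pseudo_p([0.05] * 5)
    z = 5 * stats.norm.isf(0.05) / np.sqrt(5)
    assert res.combined_p == pytest.approx(stats.norm.sf(z), rel=1e-6)
    assert res.combined_p == pytest.approx(1.17e-4, rel=0.01)


def test_stouffer_matches_reference_implementation(rng):
    for _ in range(5):
        p = rng.uniform(0.001, 0.999, size=rng.integers(2, 8))
        ours = combine_pseudo_p(p).combined_p
        _, ref = stats.combine_pvalues(p, method="stouffer")
        assert ours == pytest.approx(ref, rel=1e-9)


def test_stouffer_monotone_and_domain_errors():
    base = combine_pseudo_p([0.2, 0.3, 0.4]).combined_p
    assert combine_pseudo_p([0.1, 0.3, 0.4]).combined_p < base
    for bad in ([0.0, 0.5], [0.5, 1.0], []):
        with pytest.raises(ValueError):
            combine_pseudo_p(bad)


def test_run_ann_test_observed_below_all_simulations(rng):
    # clustered observed: all simulated ANNs exceed it
    observed = PointSet(rng.uniform(0, 0.01, (5, 2)))
    ens = _patterns([rng.uniform(0, 1, (5, 2)) for _ in range(1000)])
    res = run_ann_test(observed, ens, feature=None, year=2018)
    assert res.n_greater == 1000
    assert res.pseudo_p == pytest.approx(1 / 1001, rel=1e-12)
    assert res.direction == -1


def test_run_ann_test_corner_cluster_qualitative(rng):
    observed = PointSet(0.05 * rng.uniform(0, 1, (5, 2)))
    ens = _patterns([simulate_csr(UNIT_SQUARE, 5, seed=s).coords for s in range(200)])
    res = run_ann_test(observed, ens)
    assert res.n_greater >= 190  # near n_total


def test_run_ann_test_empty_ensemble_errors():
    with pytest.raises(ValueError):
        run_ann_test(PointSet([(0, 0), (1, 1)]), [])


def test_observed_rank_uniform_under_exchangeability():
    # observed drawn from the same CSR generator: n_greater/n should be
    # uniform; check with a KS test over independent repetitions
    n_rep = 150
    n_sims = 40
    ranks = []
    for r in range(n_rep):
        ens = _patterns([simulate_csr(UNIT_SQUARE, 10, seed=10_000 + r * 100 + s).coords
                         for s in range(n_sims)])
        observed = PointSet(simulate_csr(UNIT_SQUARE, 10, seed=999_000 + r).coords)
        res = run_ann_test(observed, ens)
        ranks.append(res.n_greater / n_sims)
    assert stats.kstest(ranks, "uniform").pvalue > 0.005


def test_model_reports_all_years_and_features(small_landscape):
    counts = {2018: 10, 2019: 12}
    nests = {y: simulate_csr(small_landscape.region, n, seed=y) for y, n in counts.items()}
    results = AnnRandomizationTest(nests, small_landscape, n_replicates=20, seed=3).fit()
    assert set(results.tests) == {(y, f) for y in counts for f in ("nests", "leks", "edge", "shore")}
    tab = results.summary()
    assert len(tab) == 8
    assert ((tab["pseudo_p"] >= 1 / 21) & (tab["pseudo_p"] <= 1.0)).all()
    comb = results.combined_summary()
    assert set(comb["method"]) == {"stouffer", "stouffer_directional"}


def test_lek_feature_uses_only_active_leks(small_landscape):
    # year 2018 has 3 active leks of 4; distances must ignore the inactive one
    nests = {2018: simulate_csr(small_landscape.region, 8, seed=1)}
    model = AnnRandomizationTest(nests, small_landscape, n_replicates=5, seed=2)
    active = small_landscape.leks_active_in(2018)
    assert len(active) == 3
    res = model.fit()
    expected = ann_to_feature(nests[2018], active)
    assert res.tests[(2018, "leks")].observed_ann == pytest.approx(expected, rel=1e-12)
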