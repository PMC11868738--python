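"""Synthetic landscapes and nest datasets with known spatial structure.

The generator emulates the geometry of a coastal-meadow study site: a
suitable breeding band bounded below by a shoreline polyline and above by a
roughly parallel meadow-edge polyline, with a handful of lek centres inside
the band, some active every year and some intermittent. Yearly nest counts
default to the five study seasons (64, 56, 28, 54, 44 nests; 6, 8, 4, 4, 6
active leks, 2018-2022).

Nest point processes:

* inhomogeneous Poisson (conditioned on n) with log-linear intensity
  ``log lambda(s) = beta_lek * d_lek(s) + beta_edge * d_edge(s) +
  beta_shore * d_shore(s)`` sampled by thinning; all betas 0 gives CSR;
* Thomas clustering on top: parents drawn from the same intensity,
  offspring displaced by an isotropic Gaussian (sigma metres), escapes
  resampled so the per-year count is exact.

Ground truth (the betas, clustering settings, seeds) is serialised next to
the data so end-to-end tests can score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .geometry import PointSet, SpatialFeatureSet, distances_to_polyline, min_distances_to_points
from .suitability import RasterGrid

__all__ = [
    "LandscapeConfig",
    "ThomasConfig",
    "NestProcessConfig",
    "SyntheticDataset",
    "DEFAULT_NESTS_BY_YEAR",
    "DEFAULT_LEKS_BY_YEAR",
    "make_landscape",
    "sample_nests",
    "generate_dataset",
    "generate_case_control_design",
    "make_toy_rasters",
]

#: per-season nest counts of the five field seasons used as defaults
DEFAULT_NESTS_BY_YEAR = {2018: 64, 2019: 56, 2020: 28, 2021: 54, 2022: 44}
#: per-season active-lek counts of the five field seasons
DEFAULT_LEKS_BY_YEAR = {2018: 6, 2019: 8, 2020: 4, 2021: 4, 2022: 6}


@dataclass
class LandscapeConfig:
    """Geometry of the synthetic suitable band.

    The shore runs near ``y = 0`` and the meadow edge near ``y = height``,
    both gently wavy so distances to them are nontrivial; the suitable
    region is the band between the two polylines.
    """

    width: float = 3000.0
    height: float = 1000.0
    wiggle: float = 40.0          # polyline amplitude, m; must stay << height
    #: relative long-wavelength variation of the band width along x; the two
    #: boundaries are parallel only in parts of the site, which keeps mean
    #: edge and shore distances from being perfectly anti-correlated
    width_variation: float = 0.45
    n_vertices: int = 25
    n_leks: int = 8
    years: tuple = (2018, 2019, 2020, 2021, 2022)
    leks_by_year: dict = field(default_factory=lambda: dict(DEFAULT_LEKS_BY_YEAR))
    seed: int = 0


@dataclass
class ThomasConfig:
    """Thomas cluster settings: CSR/intensity-drawn parents, Gaussian offspring."""

    n_parents: int = 8
    sigma: float = 30.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_parents < 1:
            raise ValueError("n_parents must be >= 1")


@dataclass
class NestProcessConfig:
    """Ground-truth nest process: per-metre log-intensity slopes and clustering.

    Negative ``beta_lek`` attracts nests toward leks; positive
    ``beta_edge``/``beta_shore`` push nests away from those boundaries.
    Defaults are CSR (all zero, no clustering).
    """

    n_nests_by_year: dict = field(default_factory=lambda: dict(DEFAULT_NESTS_BY_YEAR))
    beta_lek: float = 0.0
    beta_edge: float = 0.0
    beta_shore: float = 0.0
    clustering: ThomasConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for year, n in self.n_nests_by_year.items():
            if n < 2:
                raise ValueError(f"need >= 2 nests per year; year {year!r} has {n}")


@dataclass
class SyntheticDataset:
    """A generated landscape plus yearly nest point sets and their ground truth."""

    features: SpatialFeatureSet
    nests_by_year: dict
    truth: dict


def _wavy_line(rng, width: float, y0: float, wiggle: float, n_vertices: int) -> LineString:
    x = np.linspace(0.0, width, n_vertices)
    phase = rng.uniform(0, 2 * np.pi)
    y = y0 + wiggle * np.sin(2 * np.pi * x / width * rng.uniform(1.0, 2.5) + phase)
    y += rng.normal(0, wiggle * 0.15, n_vertices)
    return LineString(np.column_stack([x, y]))


def make_landscape(config: LandscapeConfig) -> SpatialFeatureSet:
    """Build the suitable band, its bounding polylines and the lek centres.

    Two leks are active in every year; the remaining leks are assigned to
    years so that each year's active-lek count matches ``leks_by_year``.
    """
    if config.height <= 4 * config.wiggle:
        raise ValueError("band height too small relative to wiggle amplitude")
    rng = np.random.default_rng(config.seed)
    shore = _wavy_line(rng, config.width, 0.0, config.wiggle, config.n_vertices)
    # band width varies slowly along x: boundaries parallel only in parts
    x = np.linspace(0.0, config.width, config.n_vertices)
    profile = config.height * (1.0 + config.width_variation
                               * np.sin(2 * np.pi * x / config.width + rng.uniform(0, 2 * np.pi)))
    edge_xy = np.asarray(_wavy_line(rng, config.width, 0.0, config.wiggle,
                                    config.n_vertices).coords)
    edge_xy[:, 1] += profile
    edge = LineString(edge_xy)
    shore_xy = np.asarray(shore.coords)
    region = Polygon(np.vstack([shore_xy, edge_xy[::-1]]))
    if not region.is_valid or region.area <= 0:
        raise ValueError("degenerate landscape geometry")

    # lek centres uniform in the interior, kept off the boundaries
    from .simulate import simulate_csr

    margin = 3 * config.wiggle
    inner = region.buffer(-margin)
    if inner.is_empty:
        raise ValueError("band too thin for lek placement margin")
    lek_coords = simulate_csr(inner, config.n_leks, rng).coords

    years = list(config.years)
    counts = {y: int(config.leks_by_year.get(y, max(2, config.n_leks // 2))) for y in years}
    if max(counts.values()) > config.n_leks:
        raise ValueError("leks_by_year requests more active leks than exist")
    active: list[set] = [set() for _ in range(config.n_leks)]
    for y in years:
        # persistent leks 0 and 1 are always active; fill the rest at random
        chosen = {0, 1} if counts[y] >= 2 else {0}
        pool = [i for i in range(config.n_leks) if i not in chosen]
        extra = rng.choice(pool, size=counts[y] - len(chosen), replace=False)
        chosen.update(int(i) for i in extra)
        for i in chosen:
            active[i].add(y)
    return SpatialFeatureSet(region=region, shore=shore, edge=edge,
                             lek_coords=lek_coords, lek_active_years=active)


def _log_intensity(coords: np.ndarray, landscape: SpatialFeatureSet,
                   config: NestProcessConfig, year) -> np.ndarray:
    pts = PointSet(coords)
    out = np.zeros(coords.shape[0])
    if config.beta_lek != 0.0:
        out += config.beta_lek * min_distances_to_points(pts, landscape.leks_active_in(year))
    if config.beta_edge != 0.0:
        out += config.beta_edge * distances_to_polyline(pts, landscape.edge)
    if config.beta_shore != 0.0:
        out += config.beta_shore * distances_to_polyline(pts, landscape.shore)
    return out


def _thin_sample(landscape: SpatialFeatureSet, config: NestProcessConfig, year,
                 n: int, rng, max_batches: int = 400) -> np.ndarray:
    """Exactly-n draw from the log-linear intensity by thinning CSR proposals."""
    from .simulate import simulate_csr

    if config.beta_lek == config.beta_edge == config.beta_shore == 0.0:
        return simulate_csr(landscape.region, n, rng, label=str(year)).coords
    # estimate the in-region intensity max on a probe sample, with headroom
    probe = simulate_csr(landscape.region, 4096, rng).coords
    log_max = _log_intensity(probe, landscape, config, year).max() + 0.5
    out = np.empty((0, 2))
    accepted = total = 0
    for _ in range(max_batches):
        need = n - out.shape[0]
        if need <= 0:
            break
        batch = max(64, need * 8)
        cand = simulate_csr(landscape.region, batch, rng).coords
        logw = _log_intensity(cand, landscape, config, year) - log_max
        keep = np.log(rng.uniform(size=batch)) < logw
        accepted += int(keep.sum())
        total += batch
        out = np.vstack([out, cand[keep]])
    if out.shape[0] < n:
        raise RuntimeError(
            f"thinning acceptance too low ({accepted}/{total}); reduce |beta|")
    return out[:n]


def sample_nests(landscape: SpatialFeatureSet, config: NestProcessConfig, year,
                 rng=None) -> PointSet:
    """One year's nest point set under the configured ground-truth process."""
    if rng is None or isinstance(rng, (int, np.integer, np.random.SeedSequence)):
        rng = np.random.default_rng(rng if rng is not None else config.seed)
    n = int(config.n_nests_by_year[year])
    if config.clustering is None:
        return PointSet(_thin_sample(landscape, config, year, n, rng), label=str(year))
    tc = config.clustering
    parents = _thin_sample(landscape, config, year, tc.n_parents, rng)
    import shapely

    coords = np.empty((0, 2))
    while coords.shape[0] < n:
        need = n - coords.shape[0]
        idx = rng.integers(0, tc.n_parents, need)
        cand = parents[idx] + rng.normal(0.0, tc.sigma, (need, 2))
        keep = shapely.intersects_xy(landscape.region, cand[:, 0], cand[:, 1])
        coords = np.vstack([coords, cand[keep]])  # escapes resampled, exact n kept
    return PointSet(coords[:n], label=str(year))


def generate_dataset(landscape_config: LandscapeConfig | None = None,
                     process_config: NestProcessConfig | None = None,
                     outdir=None) -> SyntheticDataset:
    """Landscape + yearly nests + ground truth; optionally written to disk.

    Files (when ``outdir`` is given) use the pipeline's input dialects:
    ``nests.csv`` (id, year, x, y, laying_date), ``leks.csv`` (id, x, y,
    active_years semicolon-separated), ``features.geojson`` (region, shore,
    edge) and ``truth.json``.
    """
    lc = landscape_config or LandscapeConfig()
    pc = process_config or NestProcessConfig()
    landscape = make_landscape(lc)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(pc.seed), spawn_key=(7,)))
    nests = {y: sample_nests(landscape, pc, y, rng) for y in lc.years
             if y in pc.n_nests_by_year}
    truth = {
        "landscape": asdict(lc) | {"years": list(lc.years)},
        "process": {
            "n_nests_by_year": {str(k): int(v) for k, v in pc.n_nests_by_year.items()},
            "beta_lek": pc.beta_lek, "beta_edge": pc.beta_edge, "beta_shore": pc.beta_shore,
            "clustering": asdict(pc.clustering) if pc.clustering else None,
            "seed": int(pc.seed),
        },
    }
    ds = SyntheticDataset(features=landscape, nests_by_year=nests, truth=truth)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    from . import io as npio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    i = 0
    for year, pts in ds.nests_by_year.items():
        for x, y in pts.coords:
            rows.append({"id": f"nest{i:04d}", "year": year, "x": x, "y": y,
                         "laying_date": ""})
            i += 1
    pd.DataFrame(rows).to_csv(outdir / "nests.csv", index=False, float_format="%.6f")
    lek_rows = []
    for j in range(ds.features.n_leks):
        lek_rows.append({
            "id": ds.features.lek_ids[j],
            "x": ds.features.lek_coords[j, 0],
            "y": ds.features.lek_coords[j, 1],
            "active_years": ";".join(str(y) for y in sorted(ds.features.lek_active_years[j])),
        })
    pd.DataFrame(lek_rows).to_csv(outdir / "leks.csv", index=False, float_format="%.6f")
    npio.write_features_geojson(ds.features, outdir / "features.geojson")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=2, sort_keys=True)


def generate_case_control_design(n_replicates: int = 200, beta: dict | None = None,
                                 landscape_config: LandscapeConfig | None = None,
                                 counts_by_year: dict | None = None,
                                 seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Distribution-level design with known logistic ground truth.

    Per year, ``n_replicates + 1`` CSR candidate distributions are generated
    and their four distance summaries computed; after pooled z-scoring, one
    candidate per year is picked to be the "observed" row with conditional
    probability proportional to ``exp(sum_j beta_j * z_j)``. A
    use-availability logistic fit on such data recovers ``beta`` (the
    intercept absorbs the 1-per-stratum sampling), which makes the design a
    parameter-recovery oracle for the GLMM.

    Returns the (standardised-predictor) design table and the truth dict.
    """
    from .glmm import PREDICTORS, standardize
    from .simulate import SimulationConfig, simulate_ensemble
    from .glmm import build_design

    beta = dict(beta or {"d_nests": -2.0})
    lc = landscape_config or LandscapeConfig(seed=seed)
    landscape = make_landscape(lc)
    counts = dict(counts_by_year or DEFAULT_NESTS_BY_YEAR)
    config = SimulationConfig(n_replicates=n_replicates + 1, seed=seed)
    ensemble = simulate_ensemble(landscape.region, counts, config)
    # treat replicate 0 of each year as a placeholder "observed" so
    # build_design produces rows for every candidate
    observed = {y: next(p.points for p in ensemble if p.year_label == y and p.replicate_id == 0)
                for y in counts}
    design = build_design(observed, [p for p in ensemble if p.replicate_id > 0],
                          landscape)
    design, scaling = standardize(design, PREDICTORS)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(11,)))
    design = design.copy()
    design["source"] = "simulated"
    for year in counts:
        idx = design.index[design["year"] == year]
        eta = np.zeros(len(idx))
        for col, b in beta.items():
            eta += b * design.loc[idx, col].to_numpy()
        w = np.exp(eta - eta.max())
        pick = rng.choice(idx, p=w / w.sum())
        design.loc[pick, "source"] = "observed"
    truth = {"beta": beta, "seed": int(seed), "n_replicates": int(n_replicates),
             "scaling": {k: (float(m), float(s)) for k, (m, s) in scaling.items()}}
    return design, truth


def make_toy_rasters(landscape: SpatialFeatureSet, years, n_dates: int = 3,
                     cell_size: float = 10.0, seed: int = 0,
                     noise_sd: float = 0.03) -> dict:
    """Tiny two-index raster stack for exercising the suitability pipeline.

    Synthetic stand-in for satellite index grids: each index varies smoothly
    across the band (distinct inside vs. outside the suitable region) with
    per-date noise; no attempt at radiometric realism.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = landscape.region.bounds
    pad = 2 * cell_size
    xmin, ymin, xmax, ymax = xmin - pad, ymin - pad, xmax + pad, ymax + pad
    nx = int(np.ceil((xmax - xmin) / cell_size))
    ny = int(np.ceil((ymax - ymin) / cell_size))
    xc = xmin + (np.arange(nx) + 0.5) * cell_size
    yc = ymax - (np.arange(ny) + 0.5) * cell_size
    xx, yy = np.meshgrid(xc, yc)
    import shapely

    inside = shapely.intersects_xy(landscape.region, xx.ravel(), yy.ravel()).reshape(ny, nx)
    base = {
        # greenness-like: mid values inside the band, high outside
        "ndvi": np.where(inside, 0.55, 0.9) + 0.05 * np.sin(xx / 400.0),
        # backscatter-like (dB): band near -18, outside much brighter
        "sar": np.where(inside, -18.0, -8.0) + 0.5 * np.cos(yy / 300.0),
    }
    out: dict = {}
    for name, vals in base.items():
        scale = noise_sd if name == "ndvi" else noise_sd * 20
        out[name] = {
            y: [RasterGrid(vals + rng.normal(0, scale, vals.shape), xmin, ymax, cell_size)
                for _ in range(n_dates)]
            for y in years
        }
    return out
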