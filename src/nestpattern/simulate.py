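"""Seeded complete-spatial-randomness (CSR) null distributions of nests.

The null model conditions on the observed per-year nest count and places
that many points i.i.d. uniform over the suitable breeding area, by
rejection sampling from the region's axis-aligned bounding box. No minimum
inter-point spacing is imposed.

Per-replicate seeds derive deterministically from a master seed together
with the year label and the replicate index (a counter-based substream via
``numpy.random.SeedSequence``), so an ensemble is reproducible and each
replicate is independent of the order in which it is generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import shapely

from .geometry import PointSet, ensure_region

__all__ = ["SimulationConfig", "SimulatedPattern", "simulate_csr", "simulate_ensemble", "replicate_seed"]


@dataclass
class SimulationConfig:
    """Ensemble settings: number of CSR replicates per year and master seed."""

    n_replicates: int = 1000
    seed: int = 0
    max_rejection_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimulatedPattern:
    """One seeded CSR replicate of n points inside the region."""

    replicate_id: int
    year_label: object
    points: PointSet
    seed_used: int


def replicate_seed(master_seed: int, year, replicate: int) -> np.random.SeedSequence:
    """Substream seed for (master, year, replicate); stable across runs."""
    year_key = zlib.crc32(str(year).encode("utf8"))
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(year_key, int(replicate)))


def simulate_csr(region, n_points: int, seed, max_rejection_iterations: int = 1000,
                 label: str = "") -> PointSet:
    """Draw ``n_points`` i.i.d. uniform points in ``region``.

    Rejection sampling from the bounding box; raises if the acceptance rate
    is so low that the iteration budget is exhausted (pathologically thin
    regions).
    """
    region = ensure_region(region)
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = region.bounds
    accept_rate = region.area / ((xmax - xmin) * (ymax - ymin))
    # draw in batches sized so one round usually suffices
    out = np.empty((0, 2))
    for _ in range(max_rejection_iterations):
        need = n_points - out.shape[0]
        if need <= 0:
            break
        batch = min(max(32, int(need / max(accept_rate, 1e-12) * 1.5)), 500_000)
        x = rng.uniform(xmin, xmax, batch)
        y = rng.uniform(ymin, ymax, batch)
        keep = shapely.intersects_xy(region, x, y)
        out = np.vstack([out, np.column_stack([x[keep], y[keep]])])
    if out.shape[0] < n_points:
        raise RuntimeError(
            f"rejection sampling exhausted after {max_rejection_iterations} iterations "
            f"(bounding-box acceptance rate {accept_rate:.2e})"
        )
    return PointSet(out[:n_points], label=label)


def simulate_ensemble(region, counts_by_year: dict, config: SimulationConfig) -> list[SimulatedPattern]:
    """CSR ensemble: ``config.n_replicates`` patterns per year at the observed counts."""
    region = ensure_region(region)
    patterns: list[SimulatedPattern] = []
    for year, n in counts_by_year.items():
        for r in range(config.n_replicates):
            ss = replicate_seed(config.seed, year, r)
            pts = simulate_csr(region, int(n), ss, config.max_rejection_iterations,
                               label=f"sim:{year}:{r}")
            patterns.append(SimulatedPattern(replicate_id=r, year_label=year, points=pts,
                                             seed_used=int(ss.entropy)))
    return patterns
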