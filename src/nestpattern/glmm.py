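"""Bayesian use-availability binomial GLMM for nest distributions.

The design contrasts each year's observed nest distribution ("use") with
its CSR replicates ("availability"): one row per distribution, with four
distance summaries as predictors — the within-distribution ANN (``d_nests``)
and the mean distances of the distribution's points to active leks, meadow
edge and shoreline. The response is whether the row is observed (1) or
simulated (0); ``year`` enters as a random intercept:

    logit P(observed) = alpha + u_year + X beta,   u_year ~ Normal(0, sigma_year)

Predictors are z-scored pooled across all rows (n-1 SD), so the betas are
per-SD effects. Priors are weakly informative on that scale: Normal(0, 5)
for the intercept and betas, half-Normal(2.5) for sigma_year. An effect is
flagged "clear" when its 95% equal-tailed credible interval excludes 0,
and convergence requires every split-R-hat below 1.10.

Sampling uses an affine-invariant ensemble MCMC (emcee) with a non-centred
year offset and log-sigma transform; several independent ensembles are run
and every walker is treated as a chain for rank-normalised R-hat / ESS
(computed with arviz). The extreme 1:N class imbalance per year is inherent
to the use-availability design and is left unweighted.

A ``unit="nest"`` switch builds nest-level rows instead (each point one row
carrying its own distances); the distribution level is the default because
the distance summaries are defined per distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .geometry import PointSet, SpatialFeatureSet, distances_to_polyline, \
    min_distances_to_points, nearest_neighbor_distances
from .ann import ann
from .simulate import SimulatedPattern

__all__ = [
    "PREDICTORS",
    "GlmmConfig",
    "build_design",
    "standardize",
    "CollinearityReport",
    "collinearity_report",
    "UseAvailabilityGLMM",
    "GLMMResults",
]

#: distance-summary predictors, in reporting order
PREDICTORS = ("d_nests", "d_leks", "d_edge", "d_shore")


@dataclass
class GlmmConfig:
    """Sampler and prior settings for the use-availability GLMM."""

    prior_beta_scale: float = 5.0
    prior_sigma_scale: float = 2.5
    chains: int = 4
    warmup: int = 2000
    draws: int = 2000
    walkers: int = 32
    seed: int = 0
    rhat_threshold: float = 1.10

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for R-hat")
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws must be >= 1 and warmup >= 0")


def _distance_summaries(points: PointSet, features: SpatialFeatureSet, year) -> dict:
    return {
        "d_nests": ann(points),
        "d_leks": float(np.mean(min_distances_to_points(points, features.leks_active_in(year)))),
        "d_edge": float(np.mean(distances_to_polyline(points, features.edge))),
        "d_shore": float(np.mean(distances_to_polyline(points, features.shore))),
    }


def _nest_rows(points: PointSet, features: SpatialFeatureSet, year) -> pd.DataFrame:
    return pd.DataFrame({
        "d_nests": nearest_neighbor_distances(points),
        "d_leks": min_distances_to_points(points, features.leks_active_in(year)),
        "d_edge": distances_to_polyline(points, features.edge),
        "d_shore": distances_to_polyline(points, features.shore),
    })


def build_design(observed_by_year: dict, ensemble: list[SimulatedPattern],
                 features: SpatialFeatureSet, unit: str = "distribution") -> pd.DataFrame:
    """Stack observed and simulated distance summaries into the model table.

    One row per distribution (default) or per nest (``unit="nest"``), with
    columns year, source, replicate_id and the four predictors. Lek
    distances use only the leks active in the row's year.
    """
    if unit not in ("distribution", "nest"):
        raise ValueError("unit must be 'distribution' or 'nest'")
    ens_years = {p.year_label for p in ensemble}
    if set(observed_by_year) != ens_years:
        raise ValueError(f"year mismatch: observed {sorted(map(str, observed_by_year))} "
                         f"vs ensemble {sorted(map(str, ens_years))}")
    frames = []

    def add(points, year, source, replicate_id):
        if unit == "distribution":
            row = {"year": year, "source": source, "replicate_id": replicate_id}
            row.update(_distance_summaries(points, features, year))
            frames.append(pd.DataFrame([row]))
        else:
            df = _nest_rows(points, features, year)
            df.insert(0, "replicate_id", replicate_id)
            df.insert(0, "source", source)
            df.insert(0, "year", year)
            frames.append(df)

    for year, pts in observed_by_year.items():
        add(pts, year, "observed", 0)
    for p in ensemble:
        add(p.points, p.year_label, "simulated", p.replicate_id)
    return pd.concat(frames, ignore_index=True)


def standardize(table: pd.DataFrame, columns=PREDICTORS):
    """Z-score predictors pooled across all rows (n-1 SD).

    Returns the transformed copy and ``{column: (mean, sd)}`` so raw-scale
    effects can be recovered.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    out = table.copy()
    scaling = {}
    for col in columns:
        mu = float(out[col].mean())
        sd = float(out[col].std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"predictor {col!r} has zero variance")
        out[col] = (out[col] - mu) / sd
        scaling[col] = (mu, sd)
    return out, scaling


@dataclass
class CollinearityReport:
    """Pairwise Pearson screen and variance inflation factors."""

    correlation: pd.DataFrame
    p_values: pd.DataFrame
    per_year: dict
    vif: pd.Series

    def max_vif(self) -> float:
        return float(self.vif.max())


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others + const."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
        out[j] = 1.0 / max(1.0 - r2, 1e-12)
    return out


def collinearity_report(table: pd.DataFrame, columns=PREDICTORS) -> CollinearityReport:
    """Pearson r (with two-sided p) between predictor pairs, overall and per
    year, plus VIFs."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    cols = list(columns)
    for c in cols:
        if table[c].nunique() <= 1:
            raise ValueError(f"predictor {c!r} is constant")
    k = len(cols)
    r = np.eye(k)
    pv = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = pearsonr(table[cols[i]], table[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    per_year = {}
    if "year" in table.columns:
        for year, grp in table.groupby("year"):
            if len(grp) < 3:
                continue
            ry = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    ry[i, j] = ry[j, i] = pearsonr(grp[cols[i]], grp[cols[j]]).statistic
            per_year[year] = pd.DataFrame(ry, index=cols, columns=cols)
    vif = pd.Series(_vif(table[cols].to_numpy(float)), index=cols, name="vif")
    return CollinearityReport(
        correlation=pd.DataFrame(r, index=cols, columns=cols),
        p_values=pd.DataFrame(pv, index=cols, columns=cols),
        per_year=per_year,
        vif=vif,
    )


def _log_prob_batch(theta, X, y, year_idx, n_years, beta_scale, sigma_scale):
    """Vectorised log posterior; theta has shape (walkers, ndim).

    Layout: [alpha, beta_1..beta_p, z_1..z_J (non-centred offsets), log sigma].
    """
    p = X.shape[1]
    alpha = theta[:, 0]
    beta = theta[:, 1:1 + p]
    z = theta[:, 1 + p:1 + p + n_years]
    t = theta[:, -1]
    sigma = np.exp(np.clip(t, -30, 30))
    eta = alpha[:, None] + beta @ X.T + (sigma[:, None] * z)[:, year_idx]
    # Bernoulli log-likelihood with logit link
    ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=1)
    lp = -0.5 * (alpha / beta_scale) ** 2
    lp += -0.5 * np.sum((beta / beta_scale) ** 2, axis=1)
    lp += -0.5 * np.sum(z ** 2, axis=1)
    # half-Normal(sigma_scale) on sigma plus log-Jacobian of sigma = exp(t)
    lp += -0.5 * (sigma / sigma_scale) ** 2 + t
    return ll + lp


class UseAvailabilityGLMM:
    """Binomial use-availability GLMM with a year random intercept.

    Parameters
    ----------
    design
        Table from :func:`build_design` (or equivalent) containing
        ``year``, ``source`` and the predictor columns.
    predictors
        Predictor columns; default the four distance summaries.
    standardize_predictors
        Z-score predictors pooled across rows before fitting (default; the
        reported betas are then per-SD effects).
    config
        :class:`GlmmConfig`; priors, chains, iterations, seed.
    """

    def __init__(self, design: pd.DataFrame, predictors=PREDICTORS,
                 standardize_predictors: bool = True,
                 config: GlmmConfig | None = None):
        self.config = config or GlmmConfig()
        self.predictors = list(predictors)
        missing = [c for c in self.predictors + ["year", "source"] if c not in design.columns]
        if missing:
            raise ValueError(f"design lacks columns {missing}")
        if standardize_predictors:
            design, self.scaling = standardize(design, self.predictors)
        else:
            self.scaling = {c: (0.0, 1.0) for c in self.predictors}
        self.design = design.reset_index(drop=True)
        self.years = sorted(self.design["year"].unique(), key=str)
        self._single_year = len(self.years) < 2
        if self._single_year:
            import warnings

            warnings.warn("fewer than 2 years: random intercept degraded to fixed intercept",
                          stacklevel=2)

    @classmethod
    def from_patterns(cls, observed_by_year: dict, ensemble, features: SpatialFeatureSet,
                      unit: str = "distribution", **kwargs) -> "UseAvailabilityGLMM":
        return cls(build_design(observed_by_year, ensemble, features, unit=unit), **kwargs)

    # parameter vector layout helpers -------------------------------------
    @property
    def param_names(self) -> list:
        return (["intercept"] + [f"beta_{p[2:]}" for p in self.predictors]
                + [f"u_{y}" for y in self.years] + ["sigma_year"])

    def fit(self, progress: bool = False) -> "GLMMResults":
        import emcee

        cfg = self.config
        X = self.design[self.predictors].to_numpy(float)
        y = (self.design["source"] == "observed").to_numpy(float)
        year_idx = self.design["year"].map({y_: i for i, y_ in enumerate(self.years)}).to_numpy()
        n_years = len(self.years)
        p = X.shape[1]
        ndim = 1 + p + n_years + 1
        nwalkers = max(cfg.walkers, 2 * ndim + 2)

        base_rate = max(y.mean(), 1.0 / (len(y) + 1))
        alpha0 = np.log(base_rate / (1 - base_rate))

        chains = []
        accept = []
        for c in range(cfg.chains):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=int(cfg.seed),
                                                               spawn_key=(101, c)))
            p0 = np.zeros((nwalkers, ndim))
            p0[:, 0] = alpha0
            p0[:, -1] = np.log(0.5)
            p0 += 0.1 * rng.standard_normal(p0.shape)
            # differential-evolution moves handle the correlated, funnel-ish
            # posterior far better than the default stretch move
            sampler = emcee.EnsembleSampler(
                nwalkers, ndim, _log_prob_batch,
                args=(X, y, year_idx, n_years, cfg.prior_beta_scale, cfg.prior_sigma_scale),
                vectorize=True,
                moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
            )
            seed_c = np.random.SeedSequence(entropy=int(cfg.seed),
                                            spawn_key=(102, c)).generate_state(1)[0]
            sampler.random_state = np.random.RandomState(int(seed_c)).get_state()
            sampler.run_mcmc(p0, cfg.warmup + cfg.draws, progress=progress)
            # (draws, walkers, ndim) -> (walkers, draws, ndim)
            chains.append(np.moveaxis(sampler.get_chain(discard=cfg.warmup), 0, 1))
            accept.append(float(sampler.acceptance_fraction.mean()))
        raw = np.concatenate(chains, axis=0)  # (chains*walkers, draws, ndim)
        return GLMMResults(self, raw, acceptance=float(np.mean(accept)))


class GLMMResults:
    """Posterior summaries and diagnostics for the use-availability GLMM."""

    def __init__(self, model: UseAvailabilityGLMM, raw_chains: np.ndarray,
                 acceptance: float = np.nan):
        self.model = model
        self.acceptance = acceptance
        p = len(model.predictors)
        J = len(model.years)
        sigma = np.exp(raw_chains[:, :, -1])
        u = sigma[:, :, None] * raw_chains[:, :, 1 + p:1 + p + J]
        # reported parameters: intercept, betas, sigma_year (+ year offsets)
        self._samples = {
            "intercept": raw_chains[:, :, 0],
            **{f"beta_{pred[2:]}": raw_chains[:, :, 1 + j]
               for j, pred in enumerate(model.predictors)},
            "sigma_year": sigma,
            **{f"u_{yv}": u[:, :, j] for j, yv in enumerate(model.years)},
        }
        self._main = (["intercept"]
                      + [f"beta_{pred[2:]}" for pred in model.predictors]
                      + ["sigma_year"])
        self._diag = self._diagnostics()

    def _diagnostics(self) -> pd.DataFrame:
        import arviz as az

        idata = az.from_dict(posterior={k: v for k, v in self._samples.items()})
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rows = {}
        for name, s in self._samples.items():
            flat = s.reshape(-1)
            lo, hi = np.quantile(flat, [0.025, 0.975])
            rows[name] = {
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "cri_2.5%": float(lo),
                "cri_97.5%": float(hi),
                "ess": float(ess[name].values),
                "rhat": float(rhat[name].values),
            }
        return pd.DataFrame(rows).T

    # -- public surface ----------------------------------------------------
    def posterior(self, name: str) -> np.ndarray:
        """(chains, draws) posterior sample array for one parameter."""
        return self._samples[name]

    @property
    def params(self) -> pd.Series:
        return self._diag.loc[self._main, "mean"]

    @property
    def rhat(self) -> pd.Series:
        return self._diag.loc[self._main, "rhat"]

    @property
    def ess(self) -> pd.Series:
        return self._diag.loc[self._main, "ess"]

    def cri(self, name: str) -> tuple:
        row = self._diag.loc[name]
        return (float(row["cri_2.5%"]), float(row["cri_97.5%"]))

    @property
    def converged(self) -> bool:
        return bool((self.rhat < self.model.config.rhat_threshold).all())

    def clear_effects(self) -> pd.Series:
        """True where the 95% CrI excludes 0 (betas only)."""
        names = [n for n in self._main if n.startswith("beta_")]
        out = {}
        for n in names:
            lo, hi = self.cri(n)
            out[n] = bool(lo > 0 or hi < 0)
        return pd.Series(out, name="clear")

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, 95% equal-tailed CrI, ESS and R-hat per
        parameter (intercept, four distance effects, sigma_year)."""
        tab = self._diag.loc[self._main].copy()
        tab["clear"] = [self.clear_effects().get(n, np.nan) for n in tab.index]
        return tab

    def to_records(self) -> list:
        tab = self.summary().reset_index(names="parameter")
        return tab.to_dict(orient="records")

    def plot_effects(self, path=None):
        from .plotting import plot_glmm_effects

        return plot_glmm_effects(self, path=path)
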