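"""Bayesian geostatistical trend model for log-transformed mean daily clicks.

Model.  For year t and site i with data, the log response
``Y_ti = log(W_ti + 1)`` is

    Y_ti | mu_t, Z_ti ~ Normal(mu_t + Z_ti, sigma2_eps / n_ti)

so site-years backed by more sampling days are observed more precisely.
The site deviations in year t form a spatially autocorrelated Gaussian
field,

    Z_t ~ MVN(0, sigma2_z * R(rho)),   R_ij = exp(-3 h_ij / rho),

with h_ij the Euclidean inter-site distance in km and rho a range
parameter (correlation drops to ~0.05 at distance rho).  One surface is
fitted per year; the smoothness (rho) and variances are shared across
years, which is how sparsely sampled years borrow strength from the grid.

Inference is Metropolis-within-Gibbs: mu_t and the full Z_t vector have
conjugate Gaussian full conditionals (Z at unsampled sites is drawn from
its conditional given the sampled sites, so derived quantities average
over the whole grid every year); sigma2_eps and sigma2_z have conjugate
inverse-gamma updates; log rho is updated by random-walk Metropolis with
step size adapted during burn-in only.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .io import MonitoringDataset, SiteGrid


def log_transform(w):
    """Log response Y = log(W + 1); strictly increasing, Y=0 at W=0."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("W must be nonnegative")
    return np.log1p(w)


def correlation_matrix(grid_or_distances, rho: float) -> np.ndarray:
    """Exponential spatial correlation matrix R with R_ij = exp(-3 h_ij / rho)."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if isinstance(grid_or_distances, SiteGrid):
        h = grid_or_distances.distance_matrix()
    else:
        h = np.asarray(grid_or_distances, dtype=float)
    off = h.copy()
    np.fill_diagonal(off, np.inf)
    if h.shape[0] > 1 and np.min(off) == 0.0:
        warnings.warn("duplicated site coordinates: correlation matrix is singular "
                      "in the pure-spatial limit")
    r = np.exp(-3.0 * h / rho)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse priors for the trend model; every scale is overridable.

    mu_t ~ Normal(mu_mean, mu_var); variances ~ InvGamma(shape, rate) with
    tiny shape/rate (vague); rho ~ Uniform(rho_lower, rho_upper), the upper
    bound defaulting to 4x the maximum inter-site distance.
    """

    mu_mean: float = 0.0
    mu_var: float = 1000.0
    eps_shape: float = 0.001
    eps_rate: float = 0.001
    z_shape: float = 0.001
    z_rate: float = 0.001
    rho_lower: float = 0.01
    rho_upper: float | None = None  # None -> 4 * max inter-site distance

    def resolve_rho_upper(self, grid: SiteGrid) -> float:
        if self.rho_upper is not None:
            return self.rho_upper
        # degenerate (single-site / zero-extent) grids get a token range
        return max(4.0 * float(np.max(grid.distance_matrix())), self.rho_lower + 1.0)

    def widened(self, factor: float) -> "PriorSpec":
        """All prior scales multiplied by ``factor`` (vaguer everywhere)."""
        if factor <= 0:
            raise ValueError("widen factor must be > 0")
        return replace(
            self,
            mu_var=self.mu_var * factor**2,
            eps_shape=self.eps_shape / factor,
            eps_rate=self.eps_rate / factor,
            z_shape=self.z_shape / factor,
            z_rate=self.z_rate / factor,
            rho_upper=None if self.rho_upper is None else self.rho_upper * factor,
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  Defaults mirror the monitoring study's single-chain
    run: 7500 burn-in iterations, every 100th sample kept, 10 000 retained
    draws.  Reduced settings (smaller thin / n_keep) are appropriate for
    tests and quick exploration."""

    n_burn: int = 7500
    n_keep: int = 10_000
    thin: int = 100
    seed: int = 0
    jitter: float = 1e-10
    rho_step: float = 0.3  # initial sd of the log-rho random walk
    adapt_target: float = 0.44

    def __post_init__(self):
        if self.n_burn < 0 or self.n_keep <= 0 or self.thin < 1:
            raise ValueError("invalid MCMC configuration")


@dataclass(frozen=True)
class GeostatParams:
    """One state of the model: per-year means, spatial field, variances, range."""

    mu: np.ndarray        # (n_years,)
    Z: np.ndarray         # (n_years, n_sites)
    sigma2_eps: float
    sigma2_z: float
    rho: float

    def validate(self):
        if self.sigma2_eps <= 0 or self.sigma2_z <= 0 or self.rho <= 0:
            raise ValueError("variance and range parameters must be positive")
        if self.Z.shape[0] != self.mu.shape[0]:
            raise ValueError("Z must have one row per year")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus the provenance needed to reproduce them."""

    years: list
    site_ids: list
    mu: np.ndarray         # (n_keep, n_years)
    Z: np.ndarray          # (n_keep, n_years, n_sites)
    sigma2_eps: np.ndarray
    sigma2_z: np.ndarray
    rho: np.ndarray
    config: MCMCConfig
    data_fingerprint: str
    rho_accept_rate: float = float("nan")
    warnings: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def scalar_chains(self) -> dict:
        """Monitored scalar chains for convergence diagnostics."""
        chains = {f"mu[{y}]": self.mu[:, t] for t, y in enumerate(self.years)}
        chains["sigma2_eps"] = self.sigma2_eps
        chains["sigma2_z"] = self.sigma2_z
        chains["rho"] = self.rho
        return chains

    def to_frame(self) -> pd.DataFrame:
        cols = {f"mu[{y}]": self.mu[:, t] for t, y in enumerate(self.years)}
        for t, y in enumerate(self.years):
            for i, s in enumerate(self.site_ids):
                cols[f"Z[{y},{s}]"] = self.Z[:, t, i]
        cols["sigma2_eps"] = self.sigma2_eps
        cols["sigma2_z"] = self.sigma2_z
        cols["rho"] = self.rho
        return pd.DataFrame(cols)

    def write_csv(self, path, meta_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if meta_path is not None:
            meta = {
                "seed": self.config.seed,
                "n_burn": self.config.n_burn,
                "n_keep": self.config.n_keep,
                "thin": self.config.thin,
                "data_fingerprint": self.data_fingerprint,
                "rho_accept_rate": self.rho_accept_rate,
                "warnings": self.warnings,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: MCMCConfig | None = None) -> "PosteriorDraws":
        mu_cols = [c for c in frame.columns if c.startswith("mu[")]
        years = [int(c[3:-1]) for c in mu_cols]
        z_cols = [c for c in frame.columns if c.startswith("Z[")]
        site_ids = []
        for c in z_cols:
            y, s = c[2:-1].split(",", 1)
            if int(y) == years[0] and s not in site_ids:
                site_ids.append(s)
        n = len(frame)
        z = np.empty((n, len(years), len(site_ids)))
        for t, y in enumerate(years):
            for i, s in enumerate(site_ids):
                z[:, t, i] = frame[f"Z[{y},{s}]"].to_numpy()
        return cls(
            years=years,
            site_ids=site_ids,
            mu=frame[mu_cols].to_numpy(),
            Z=z,
            sigma2_eps=frame["sigma2_eps"].to_numpy(),
            sigma2_z=frame["sigma2_z"].to_numpy(),
            rho=frame["rho"].to_numpy(),
            config=config or MCMCConfig(),
            data_fingerprint="",
        )


def _fingerprint(ymat: np.ndarray, nmat: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.nan_to_num(ymat).tobytes())
    h.update(nmat.tobytes())
    return h.hexdigest()[:16]


def log_posterior(
    params: GeostatParams,
    dataset: MonitoringDataset,
    priors: PriorSpec | None = None,
) -> float:
    """Unnormalized log posterior density of one parameter state.

    Sum of the Gaussian observation log-likelihood over observed site-years,
    the per-year MVN log-density of Z_t, and the log-priors.  Used for
    testing and for external samplers; the Gibbs sampler itself works from
    full conditionals.
    """
    priors = priors or PriorSpec()
    params.validate()
    ymat, nmat = dataset.response_matrices()
    obs = nmat > 0
    mean = params.mu[:, None] + params.Z
    var = params.sigma2_eps / np.where(obs, nmat, 1.0)
    ll = -0.5 * np.sum(
        (np.log(2 * np.pi * var) + (ymat - mean) ** 2 / var)[obs]
    )
    r = correlation_matrix(dataset.grid, params.rho)
    r[np.diag_indices_from(r)] += 1e-10
    try:
        cho = linalg.cho_factor(r, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("spatial covariance not positive definite") from exc
    logdet_r = 2.0 * np.sum(np.log(np.diag(cho[0])))
    s = r.shape[0]
    for t in range(params.Z.shape[0]):
        quad = params.Z[t] @ linalg.cho_solve(cho, params.Z[t])
        ll += -0.5 * (s * np.log(2 * np.pi * params.sigma2_z) + logdet_r
                      + quad / params.sigma2_z)
    # priors
    ll += np.sum(-0.5 * (np.log(2 * np.pi * priors.mu_var)
                         + (params.mu - priors.mu_mean) ** 2 / priors.mu_var))
    for val, a, b in [
        (params.sigma2_eps, priors.eps_shape, priors.eps_rate),
        (params.sigma2_z, priors.z_shape, priors.z_rate),
    ]:
        ll += -(a + 1.0) * np.log(val) - b / val  # inverse-gamma kernel
    upper = priors.resolve_rho_upper(dataset.grid)
    if not (priors.rho_lower <= params.rho <= upper):
        return -np.inf
    return float(ll)


def fit(
    dataset: MonitoringDataset,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    fixed: dict | None = None,
    check_convergence: bool = True,
) -> PosteriorDraws:
    """Fit the geostatistical trend model by Metropolis-within-Gibbs MCMC.

    Parameters
    ----------
    fixed
        Optional dict pinning any of ``sigma2_eps``, ``sigma2_z``, ``rho``
        to known values (their updates are skipped) — used for sampler
        validation against closed-form Gaussian posteriors.
    check_convergence
        Run a quick Geweke check on the monitored scalar chains and record
        failures in ``PosteriorDraws.warnings`` (never silently ignored).
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    fixed = fixed or {}
    rng = np.random.default_rng(config.seed)

    ymat, nmat = dataset.response_matrices()
    n_years, n_sites = ymat.shape
    if n_years < 2 and "allow_single_year" not in fixed:
        # single-year fits are permitted for toy checks but warn loudly
        warnings.warn("fitting with a single year: no trend is identifiable")
    obs = nmat > 0
    y0 = np.nan_to_num(ymat)
    dist = dataset.grid.distance_matrix()
    rho_upper = priors.resolve_rho_upper(dataset.grid)

    # starting values: year means of observed Y, flat field, moments of residuals
    mu = np.array([ymat[t, obs[t]].mean() if obs[t].any() else 0.0
                   for t in range(n_years)])
    z = np.zeros((n_years, n_sites))
    resid = (ymat - mu[:, None])[obs]
    s2 = float(np.var(resid)) if resid.size > 1 else 1.0
    sig2_eps = float(fixed.get("sigma2_eps", max(s2 / 2, 1e-3)))
    sig2_z = float(fixed.get("sigma2_z", max(s2 / 2, 1e-3)))
    off = dist[np.triu_indices(n_sites, k=1)]
    rho = float(fixed.get("rho", np.median(off) if off.size else 1.0))
    if "rho" not in fixed:
        rho = min(max(rho, priors.rho_lower), rho_upper)

    def chol_r(rho_val):
        r = np.exp(-3.0 * dist / rho_val)
        r[np.diag_indices_from(r)] += config.jitter
        low = linalg.cholesky(r, lower=True)
        return r, low

    r_jit, low_r = chol_r(rho)
    logdet_r = 2.0 * np.sum(np.log(np.diag(low_r)))

    n_total = config.n_burn + config.n_keep * config.thin
    keep_mu = np.empty((config.n_keep, n_years))
    keep_z = np.empty((config.n_keep, n_years, n_sites))
    keep_eps = np.empty(config.n_keep)
    keep_zvar = np.empty(config.n_keep)
    keep_rho = np.empty(config.n_keep)

    rho_step = config.rho_step
    rho_acc = 0
    rho_try = 0
    kept = 0
    eye = np.eye(n_sites)

    r_full = np.exp(-3.0 * dist / rho)

    for it in range(n_total):
        # --- (mu_t, Z_t) jointly per year: mu_t from its marginal with the
        # spatial field integrated out, then Z_t from its full conditional.
        # Blocking the two removes the severe autocorrelation of the
        # weakly identified mu-vs-Z direction.
        rinv = linalg.cho_solve((low_r, True), eye)
        for t in range(n_years):
            o = obs[t]
            if o.any():
                sig = sig2_z * r_full[np.ix_(o, o)] + np.diag(sig2_eps / nmat[t, o])
                cs = linalg.cho_factor(sig, lower=True)
                ones = np.ones(o.sum())
                si_y = linalg.cho_solve(cs, y0[t, o])
                si_1 = linalg.cho_solve(cs, ones)
                prec = 1.0 / priors.mu_var + ones @ si_1
                num = priors.mu_mean / priors.mu_var + ones @ si_y
            else:
                prec = 1.0 / priors.mu_var
                num = priors.mu_mean / priors.mu_var
            mu[t] = num / prec + rng.standard_normal() / np.sqrt(prec)

            # Z_t | mu_t: unsampled sites follow their conditional spatial
            # prior given the sampled sites automatically (D=0 there)
            d = nmat[t] / sig2_eps
            q = rinv / sig2_z + np.diag(d)
            lq = linalg.cholesky(q, lower=True)
            r_vec = d * (y0[t] - mu[t])
            m = linalg.cho_solve((lq, True), r_vec)
            z[t] = m + linalg.solve_triangular(
                lq.T, rng.standard_normal(n_sites), lower=False
            )

        # --- sigma2_eps: conjugate inverse gamma
        if "sigma2_eps" not in fixed:
            res = (ymat - mu[:, None] - z)[obs]
            shape = priors.eps_shape + 0.5 * res.size
            rate = priors.eps_rate + 0.5 * float(np.sum(nmat[obs] * res**2))
            sig2_eps = rate / rng.gamma(shape)

        # --- sigma2_z: conjugate inverse gamma given R(rho)
        v = linalg.cho_solve((low_r, True), z.T)  # (n_sites, n_years)
        quad_all = float(np.sum(z.T * v))
        if "sigma2_z" not in fixed:
            shape = priors.z_shape + 0.5 * n_years * n_sites
            rate = priors.z_rate + 0.5 * quad_all
            sig2_z = rate / rng.gamma(shape)

        # --- rho: random-walk Metropolis on log scale (uniform prior on rho)
        if "rho" not in fixed:
            rho_try += 1
            prop = rho * np.exp(rho_step * rng.standard_normal())
            if priors.rho_lower <= prop <= rho_upper:
                try:
                    r_p, low_p = chol_r(prop)
                except linalg.LinAlgError:
                    low_p = None
                if low_p is not None:
                    logdet_p = 2.0 * np.sum(np.log(np.diag(low_p)))
                    vp = linalg.cho_solve((low_p, True), z.T)
                    quad_p = float(np.sum(z.T * vp))
                    log_accept = (
                        -0.5 * n_years * (logdet_p - logdet_r)
                        - 0.5 * (quad_p - quad_all) / sig2_z
                        + np.log(prop) - np.log(rho)  # log-scale proposal Jacobian
                    )
                    if np.log(rng.uniform()) < log_accept:
                        rho, low_r, logdet_r = prop, low_p, logdet_p
                        r_full = np.exp(-3.0 * dist / rho)
                        rho_acc += 1
            if it < config.n_burn and rho_try % 50 == 0:
                # Robbins-Monro style step adaptation, burn-in only
                rate = rho_acc / rho_try
                rho_step *= np.exp(0.5 * (rate - config.adapt_target))
                rho_step = float(np.clip(rho_step, 1e-3, 5.0))

        if it >= config.n_burn and (it - config.n_burn + 1) % config.thin == 0:
            keep_mu[kept] = mu
            keep_z[kept] = z
            keep_eps[kept] = sig2_eps
            keep_zvar[kept] = sig2_z
            keep_rho[kept] = rho
            kept += 1

    draws = PosteriorDraws(
        years=dataset.years,
        site_ids=list(dataset.grid.site_ids),
        mu=keep_mu,
        Z=keep_z,
        sigma2_eps=keep_eps,
        sigma2_z=keep_zvar,
        rho=keep_rho,
        config=config,
        data_fingerprint=_fingerprint(ymat, nmat),
        rho_accept_rate=(rho_acc / rho_try) if rho_try else float("nan"),
    )
    if check_convergence:
        from .diagnostics import geweke

        for name, chain in draws.scalar_chains().items():
            if np.std(chain) == 0:  # pinned parameter: nothing to diagnose
                continue
            zscore = geweke(chain)
            if abs(zscore) > 4.0:
                draws.warnings.append(
                    f"Geweke |z|={abs(zscore):.1f} for {name}: chain may not have converged"
                )
    return draws


def rerun_with_wider_priors(
    dataset: MonitoringDataset,
    priors: PriorSpec,
    config: MCMCConfig,
    widen_factor: float,
    baseline: PosteriorDraws | None = None,
) -> dict:
    """Prior-sensitivity check: refit with all prior scales widened.

    Reports the maximum absolute difference in posterior-mean lambda across
    consecutive year pairs between the baseline and widened fits, alongside
    the per-pair values.
    """
    from .trend import compute_B, compute_lambda

    if baseline is None:
        baseline = fit(dataset, priors, config, check_convergence=False)
    widened = fit(dataset, priors.widened(widen_factor), config, check_convergence=False)

    def lam_means(draws):
        b = compute_B(draws)
        years = draws.years
        return {
            (years[t], years[t + 1]): compute_lambda(b, years, years[t], years[t + 1]).mean
            for t in range(len(years) - 1)
        }

    base_l, wide_l = lam_means(baseline), lam_means(widened)
    diffs = {pair: abs(base_l[pair] - wide_l[pair]) for pair in base_l}
    return {
        "widen_factor": widen_factor,
        "lambda_baseline": base_l,
        "lambda_widened": wide_l,
        "max_abs_diff_lambda": max(diffs.values()) if diffs else float("nan"),
        "per_pair_abs_diff": diffs,
    }
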