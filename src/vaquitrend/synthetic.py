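"""Synthetic monitoring-data generator with known ground truth.

Emulates the statistical structure the trend analysis assumes: a fixed
near-systematic grid of sites; per-year log-scale means mu_t following a
multiplicative decline; spatially autocorrelated site deviations Z_t drawn
from MVN(0, sigma2_z * R(rho)) with the exponential correlogram; observation
noise with variance sigma2_eps / n_ti, so site-years with fewer sampled
days are noisier; and realistic missing-effort patterns (whole sites
missing in early years, short within-season gaps).

The generated site surface on the click scale is max(exp(mu_t + Z_ti)-1, 0):
a synthetic site cannot have a negative click rate, so the truncated field
is the true acoustic landscape of the simulated world, and the realized
activity index B_t and change ratios lambda reported in the truth object
are computed from it.  The truncation fraction is logged per realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .io import DEFAULT_CORE_WINDOW, MonitoringDataset, SiteGrid

#: Pre-update posterior-mean annual change ratios from the vaquita
#: monitoring study, 2011-2012 through 2017-2018; product ~0.022
#: (a ~98% total decline over seven years).
STUDY_LAMBDA_PATH = (0.67, 1.18, 0.49, 0.65, 0.41, 0.51, 0.42)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters: the study conditions plus ground truth."""

    n_sites: int = 46
    extent_km: tuple = (36.0, 30.0)
    years: tuple = tuple(range(2011, 2019))
    initial_mean_clicks: float = 4.37   # grid-average clicks/day in the first year
    lambda_path: tuple = STUDY_LAMBDA_PATH
    sigma2_eps: float = 0.2
    sigma2_z: float = 0.35
    rho: float = 12.0
    n_days: int = 62
    missing_year_prob: tuple = (0.25, 0.25, 0.25, 0.04, 0.04, 0.04, 0.04, 0.04)
    day_dropout_prob: float = 0.05
    daily_dispersion: float = 1.0       # negative-binomial shape for daily counts
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_eps < 0 or self.sigma2_z < 0 or self.rho <= 0:
            raise ValueError("variances must be nonnegative and rho positive")
        if any(l <= 0 for l in self.lambda_path):
            raise ValueError("lambda values must be positive")
        if len(self.missing_year_prob) != len(self.years):
            raise ValueError("one missing-year probability per year")
        if not all(0 <= p <= 1 for p in self.missing_year_prob):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.lambda_path) != len(self.years) - 1:
            raise ValueError("lambda_path must have one entry per year transition")

    @property
    def mu(self) -> np.ndarray:
        """Log-scale year means: B path declines by lambda_path on the click
        scale, mu_t = log(1 + B_t)."""
        b = [self.initial_mean_clicks]
        for lam in self.lambda_path:
            b.append(b[-1] * lam)
        return np.log1p(np.array(b))


@dataclass
class SyntheticRealization:
    """Ground truth realized in one simulated dataset."""

    truth: SyntheticTruth
    Z: np.ndarray               # (n_years, n_sites) spatial deviations
    Y: np.ndarray               # latent Gaussian responses (NaN where unsampled)
    surface: np.ndarray         # true click-scale site surface, truncated at 0
    n_days_sampled: np.ndarray  # (n_years, n_sites) effort
    truncated_fraction: float   # fraction of site-years with exp(mu+Z)-1 < 0

    @property
    def B_true(self) -> np.ndarray:
        """Realized activity index per year from the true site surface."""
        return self.surface.mean(axis=1)

    @property
    def lambda_true(self) -> np.ndarray:
        """Realized consecutive-year change ratios of the true surface."""
        b = self.B_true
        return b[1:] / b[:-1]


def simulate_grid(truth: SyntheticTruth) -> SiteGrid:
    """Near-systematic grid of n_sites within the stated extent, with a
    small seeded jitter so no two sites coincide (unless extent is zero)."""
    if truth.n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(truth.seed)
    ncol = int(np.ceil(np.sqrt(truth.n_sites)))
    nrow = int(np.ceil(truth.n_sites / ncol))
    ex, ey = truth.extent_km
    xs = np.linspace(0.0, ex, ncol)
    ys = np.linspace(0.0, ey, nrow)
    pts = np.array([(x, y) for y in ys for x in xs])[: truth.n_sites]
    jitter_scale = 0.05 * max(ex / max(ncol - 1, 1), ey / max(nrow - 1, 1))
    pts = pts + rng.normal(scale=jitter_scale, size=pts.shape)
    if ex == 0 and ey == 0:
        import warnings

        warnings.warn("zero spatial extent: duplicate coordinates are degenerate")
        pts = np.zeros_like(pts)
    ids = tuple(range(1, truth.n_sites + 1))
    return SiteGrid(site_ids=ids, coords_km=pts)


def _sample_effort(truth: SyntheticTruth, rng) -> np.ndarray:
    """Sampled days per (year, site): whole-site missing years plus
    binomial within-season dropout."""
    n_years, n_sites = len(truth.years), truth.n_sites
    n = np.zeros((n_years, n_sites), dtype=int)
    for t in range(n_years):
        present = rng.uniform(size=n_sites) >= truth.missing_year_prob[t]
        days = rng.binomial(truth.n_days, 1.0 - truth.day_dropout_prob, size=n_sites)
        n[t] = np.where(present, days, 0)
    return n


def simulate_dataset(
    truth: SyntheticTruth, daily: bool = False
) -> tuple[MonitoringDataset, SyntheticRealization] | tuple[MonitoringDataset, SyntheticRealization, pd.DataFrame]:
    """Draw one monitoring dataset from the generative model.

    Returns ``(dataset, realization)``, plus a daily-record frame (same
    schema ``load_daily_records`` produces) when ``daily=True``; daily
    counts are negative-binomial with the site-year's W as mean, and the
    dataset is then the exact annualization of those counts.
    """
    rng = np.random.default_rng(truth.seed)
    grid = simulate_grid(truth)
    dist = grid.distance_matrix()
    n_years, n_sites = len(truth.years), truth.n_sites
    mu = truth.mu

    r = np.exp(-3.0 * dist / truth.rho)
    r[np.diag_indices_from(r)] += 1e-10
    low = linalg.cholesky(r, lower=True)
    z = np.sqrt(truth.sigma2_z) * (rng.standard_normal((n_years, n_sites)) @ low.T)

    raw_surface = np.expm1(mu[:, None] + z)
    surface = np.maximum(raw_surface, 0.0)
    truncated_fraction = float(np.mean(raw_surface < 0.0))

    nmat = _sample_effort(truth, rng)
    obs = nmat > 0
    sd = np.sqrt(truth.sigma2_eps / np.where(obs, nmat, 1.0))
    y = mu[:, None] + z + sd * rng.standard_normal((n_years, n_sites))
    y[~obs] = np.nan
    w = np.maximum(np.expm1(y), 0.0)

    if not daily:
        rows = [
            {"year": truth.years[t], "site_id": grid.site_ids[i],
             "W": float(w[t, i]), "n": int(nmat[t, i])}
            for t in range(n_years) for i in range(n_sites) if obs[t, i]
        ]
        dataset = MonitoringDataset(grid=grid, summaries=pd.DataFrame(rows))
        real = SyntheticRealization(truth, z, y, surface, nmat, truncated_fraction)
        return dataset, real

    # disaggregate to daily counts; W_ti then becomes the realized daily mean
    lo_day, hi_day = DEFAULT_CORE_WINDOW
    daily_rows = []
    sum_rows = []
    import calendar

    for t in range(n_years):
        year = truth.years[t]
        base = pd.Timestamp(year=year, month=1, day=1)
        # core-window Julian days use the non-leap convention: in leap
        # years the calendar day-of-year is one larger past February
        leap_shift = 1 if calendar.isleap(year) else 0
        for i in range(n_sites):
            if not obs[t, i]:
                continue
            days = rng.choice(np.arange(lo_day, hi_day + 1), size=nmat[t, i],
                              replace=False)
            days.sort()
            mean_w = max(w[t, i], 1e-12)
            shape = truth.daily_dispersion
            lam = rng.gamma(shape, mean_w / shape, size=days.size)
            clicks = rng.poisson(lam)
            dpm = np.where(clicks > 0,
                           np.minimum(1 + rng.poisson(0.2 * clicks), 1440), 0)
            for d, c, m in zip(days, clicks, dpm):
                daily_rows.append({
                    "site_id": grid.site_ids[i],
                    "date": base + pd.Timedelta(days=int(d) - 1 + leap_shift),
                    "clicks": float(c),
                    "dpm": float(m),
                    "sampled": True,
                })
            sum_rows.append({"year": year, "site_id": grid.site_ids[i],
                             "W": float(clicks.mean()), "n": int(days.size)})
    records = pd.DataFrame(daily_rows)
    dataset = MonitoringDataset(grid=grid, summaries=pd.DataFrame(sum_rows))
    real = SyntheticRealization(truth, z, y, surface, nmat, truncated_fraction)
    return dataset, real, records


def scenario_study_like(seed: int = 2011) -> SyntheticTruth:
    """Packaged fixture mirroring the vaquita monitoring conditions:
    46 sites, 2011-2018, the study's posterior-mean decline path, a 2011
    grid-average of 4.37 clicks/day, and sparser effort in the early years."""
    return SyntheticTruth(seed=seed)
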