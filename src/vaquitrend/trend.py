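"""Derived trend quantities: yearly activity indices B_t, change ratios
lambda, percentage declines and decline probabilities.

B_t is the grid-average acoustic activity in year t on the click scale,

    B_t = (1/S) * sum_i (exp(mu_t + Z_ti) - 1),

averaged over *all* grid sites (the spatial field supplies Z at sites with
no data that year), acknowledging the realized spatial variation rather
than integrating it out.  The change between two years is the ratio
lambda_{t1,t2} = B_t2 / B_t1; values below 1 indicate decline, and
(1 - lambda) * 100 is the percentage decline.  All summaries are empirical
functionals of the posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def compute_B(draws) -> np.ndarray:
    """Per-draw, per-year activity index B_t; shape (n_draws, n_years).

    Accepts a PosteriorDraws object or a dict with ``mu`` (n, T) and ``Z``
    (n, T, S) arrays.  B can be negative when mu_t + Z_ti < 0 at many
    sites (the index lives on the click scale, exp(.)-1); ratio summaries
    guard against that downstream.
    """
    mu = draws["mu"] if isinstance(draws, dict) else draws.mu
    z = draws["Z"] if isinstance(draws, dict) else draws.Z
    return np.mean(np.expm1(mu[:, :, None] + z), axis=2)


@dataclass(frozen=True)
class LambdaSummary:
    """Posterior summary of the change ratio between two years."""

    year_pair: tuple
    draws: np.ndarray
    mean: float
    cri: tuple  # central 95% (2.5%, 97.5%) quantiles
    n_excluded: int  # draws dropped because B_t1 <= 0

    @property
    def percent_decline(self) -> float:
        return (1.0 - self.mean) * 100.0

    def prob_declining(self, threshold: float = 1.0) -> float:
        """Fraction of draws with lambda < threshold (1.0 = any decline,
        0.8 = faster than 20%/yr, 0.67 = faster than 33%/yr)."""
        return float(np.mean(self.draws < threshold))


def compute_lambda(b_draws: np.ndarray, years: list, t1: int, t2: int) -> LambdaSummary:
    """Ratio lambda_{t1,t2} = B_t2 / B_t1 per draw, with 95% CRI summaries.

    Draws with non-positive B_t1 are excluded (a ratio to a non-positive
    index is meaningless); the exclusion count is reported, and is zero for
    realistic posteriors.
    """
    if t2 <= t1:
        raise ValueError("t2 must be a later year than t1")
    i1, i2 = years.index(t1), years.index(t2)
    denom = b_draws[:, i1]
    keep = denom > 0
    lam = b_draws[keep, i2] / denom[keep]
    if lam.size == 0:
        raise ValueError("no draws with positive B in the earlier year")
    lo, hi = np.quantile(lam, [0.025, 0.975])
    return LambdaSummary(
        year_pair=(t1, t2),
        draws=lam,
        mean=float(lam.mean()),
        cri=(float(lo), float(hi)),
        n_excluded=int(np.sum(~keep)),
    )


def decline_probabilities(lam_draws: np.ndarray, threshold: float = 1.0) -> float:
    """P(lambda < threshold) from posterior draws."""
    lam_draws = np.asarray(lam_draws, dtype=float)
    if lam_draws.size == 0:
        raise ValueError("empty lambda draws")
    return float(np.mean(lam_draws < threshold))


def geometric_mean_lambda(b_draws: np.ndarray, years: list) -> LambdaSummary:
    """Per-draw geometric-mean annual change over the full monitored span.

    ((B_last / B_first))^(1/(n_years-1)) per draw; the exact per-draw
    telescoping of the annual ratios.
    """
    t1, t2 = years[0], years[-1]
    total = compute_lambda(b_draws, years, t1, t2)
    k = years.index(t2) - years.index(t1)
    gm = total.draws ** (1.0 / k)
    lo, hi = np.quantile(gm, [0.025, 0.975])
    return LambdaSummary(
        year_pair=(t1, t2),
        draws=gm,
        mean=float(gm.mean()),
        cri=(float(lo), float(hi)),
        n_excluded=total.n_excluded,
    )


def trend_table(draws, retained: np.ndarray | None = None) -> pd.DataFrame:
    """Posterior trend table: one row per consecutive year pair plus a
    geometric-mean row, with lambda mean, 95% CRI and decline probabilities.

    ``retained`` optionally restricts every summary to a boolean subset of
    draws (used after the minimum-count update)."""
    b = compute_B(draws)
    years = draws["years"] if isinstance(draws, dict) else draws.years
    if retained is not None:
        b = b[np.asarray(retained, dtype=bool)]
    rows = []
    for t1, t2 in zip(years[:-1], years[1:]):
        s = compute_lambda(b, years, t1, t2)
        rows.append({
            "period": f"{t1}-{t2}",
            "lambda_mean": round(s.mean, 2),
            "cri_low": round(s.cri[0], 2),
            "cri_high": round(s.cri[1], 2),
            "prob_declining_pct": round(100 * s.prob_declining(1.0), 1),
            "prob_declining_gt20_pct": round(100 * s.prob_declining(0.8), 1),
            "n_excluded": s.n_excluded,
        })
    g = geometric_mean_lambda(b, years)
    rows.append({
        "period": "geometric mean per-year change",
        "lambda_mean": round(g.mean, 2),
        "cri_low": round(g.cri[0], 2),
        "cri_high": round(g.cri[1], 2),
        "prob_declining_pct": round(100 * g.prob_declining(1.0), 1),
        "prob_declining_gt20_pct": round(100 * g.prob_declining(0.8), 1),
        "n_excluded": g.n_excluded,
    })
    return pd.DataFrame(rows)
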