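"""Abundance projection and the minimum-known-alive posterior update.

An independent survey abundance estimate (for the vaquita study: autumn
2015, arithmetic mean 66 animals, sd 33) is represented as a lognormal
distribution by moment matching.  Trajectories are built by pairing each
lognormal draw with one joint posterior draw of the annual acoustic change
ratios and multiplying forward:

    N_2016 = N_2015 * lambda_{2015,2016},  ... ,  N_2018 = N_2015 * prod(lambda).

Verified minimum counts of living animals (photo-ID / capture: at least 7
in 2017, 6 in 2018) enter as hard truncation data: trajectories whose
projected abundance falls below a minimum are discarded (rejection
sampling from the truncated posterior).  All post-update summaries —
including the retrospective update of the starting-year abundance and of
the acoustic trend itself — are computed over the retained trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AbundancePrior:
    """Lognormal abundance distribution parameterized by arithmetic moments."""

    mean: float
    sd: float
    mu_log: float = field(init=False)
    sigma_log: float = field(init=False)

    def __post_init__(self):
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("mean and sd must be positive")
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        object.__setattr__(self, "sigma_log", math.sqrt(sigma2))
        object.__setattr__(self, "mu_log", math.log(self.mean) - sigma2 / 2.0)

    @property
    def median(self) -> float:
        return math.exp(self.mu_log)

    @property
    def distribution(self):
        """The matching ``scipy.stats.lognorm`` frozen distribution."""
        return stats.lognorm(s=self.sigma_log, scale=math.exp(self.mu_log))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.mu_log, self.sigma_log, size=n)


def lognormal_from_moments(mean: float, sd: float) -> AbundancePrior:
    """Moment-matched lognormal: sigma2 = ln(1+(sd/mean)^2),
    mu = ln(mean) - sigma2/2, so arithmetic mean and sd are reproduced."""
    return AbundancePrior(mean=mean, sd=sd)


@dataclass
class TrajectorySet:
    """Joint abundance trajectories with a retention mask.

    ``table`` has one row per trajectory: columns ``N_<year>`` for every
    projected year, ``lambda_<t1>_<t2>`` for each step, and ``retained``.
    """

    years: list
    table: pd.DataFrame
    minimums: dict = field(default_factory=dict)

    @property
    def n_trajectories(self) -> int:
        return len(self.table)

    @property
    def retained(self) -> np.ndarray:
        return self.table["retained"].to_numpy(dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def abundance(self, year: int, retained_only: bool = True) -> np.ndarray:
        col = self.table[f"N_{year}"].to_numpy(dtype=float)
        return col[self.retained] if retained_only else col

    def long_format(self, retained_only: bool = True) -> pd.DataFrame:
        """Violin-plot-ready long frame (year, N) over trajectories."""
        frames = [
            pd.DataFrame({"year": y, "N": self.abundance(y, retained_only)})
            for y in self.years
        ]
        return pd.concat(frames, ignore_index=True)


def project(
    prior: AbundancePrior,
    lambda_streams: dict,
    n_trajectories: int | None = None,
    seed: int = 0,
) -> TrajectorySet:
    """Build trajectories by pairing abundance draws with joint lambda draws.

    ``lambda_streams`` maps consecutive year pairs ``(t1, t2)`` to arrays of
    posterior draws; the pairs must chain (each t2 is the next pair's t1)
    and all streams must have equal length, because index i across streams
    is one joint MCMC draw.  The i-th lognormal draw is paired with the
    i-th joint draw, preserving between-year posterior correlation.
    """
    pairs = sorted(lambda_streams.keys())
    if not pairs:
        raise ValueError("no lambda streams supplied")
    for (a1, a2), (b1, b2) in zip(pairs[:-1], pairs[1:]):
        if a2 != b1:
            raise ValueError(f"year pairs do not chain: {(a1, a2)} then {(b1, b2)}")
    lengths = {len(v) for v in lambda_streams.values()}
    if len(lengths) != 1:
        raise ValueError(f"lambda stream length mismatch: {sorted(lengths)}")
    n_avail = lengths.pop()
    n = n_avail if n_trajectories is None else n_trajectories
    if n > n_avail:
        raise ValueError(f"requested {n} trajectories but streams have {n_avail} draws")

    rng = np.random.default_rng(seed)
    start_year = pairs[0][0]
    n0 = prior.sample(n, rng)
    cols = {f"N_{start_year}": n0}
    current = n0
    for (t1, t2) in pairs:
        lam = np.asarray(lambda_streams[(t1, t2)], dtype=float)[:n]
        cols[f"lambda_{t1}_{t2}"] = lam
        current = current * lam
        cols[f"N_{t2}"] = current
    table = pd.DataFrame(cols)
    table["retained"] = True
    years = [start_year] + [p[1] for p in pairs]
    return TrajectorySet(years=years, table=table)


def apply_minimum_counts(
    trajectories: TrajectorySet,
    minimums: dict,
    rounding: str = "continuous",
) -> TrajectorySet:
    """Discard trajectories whose projected abundance violates a verified
    minimum count of living animals (rejection-sampling posterior update).

    ``rounding`` selects the comparison scale: ``continuous`` (default;
    the real-valued draw must be >= the minimum), ``floor`` or ``ceil``
    (compare after rounding down / up) for sensitivity analysis.
    """
    rounders = {"continuous": lambda x: x, "floor": np.floor, "ceil": np.ceil}
    if rounding not in rounders:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    rounder = rounders[rounding]
    keep = trajectories.table["retained"].to_numpy(dtype=bool).copy()
    for year, minimum in minimums.items():
        if minimum < 0 or int(minimum) != minimum:
            raise ValueError("minimum counts must be nonnegative integers")
        if year not in trajectories.years:
            raise ValueError(f"year {year} not in trajectories")
        keep &= rounder(trajectories.table[f"N_{year}"].to_numpy(dtype=float)) >= minimum
    if not keep.any():
        raise ValueError(
            "no trajectories satisfy the minimum counts; "
            "increase n_trajectories or check the minimums"
        )
    table = trajectories.table.copy()
    table["retained"] = keep
    return TrajectorySet(years=list(trajectories.years), table=table,
                         minimums=dict(minimums))


def summarize_abundance(trajectories: TrajectorySet, year: int,
                        retained_only: bool = True) -> dict:
    """Posterior mean, median and central 95% CRI of N_year, with the
    integer-rounded presentation used for reporting alongside raw values."""
    n = trajectories.abundance(year, retained_only=retained_only)
    if n.size == 0:
        raise ValueError("no retained trajectories")
    lo, hi = np.quantile(n, [0.025, 0.975])
    out = {
        "year": year,
        "mean": float(n.mean()),
        "median": float(np.median(n)),
        "cri_low": float(lo),
        "cri_high": float(hi),
        "n_trajectories": int(n.size),
    }
    out["rounded"] = {k: int(round(out[k])) for k in ("mean", "median", "cri_low", "cri_high")}
    return out


def abundance_table(trajectories: TrajectorySet, retained_only: bool = True) -> pd.DataFrame:
    rows = []
    for year in trajectories.years:
        s = summarize_abundance(trajectories, year, retained_only=retained_only)
        rows.append({k: s[k] for k in
                     ("year", "mean", "median", "cri_low", "cri_high", "n_trajectories")})
    return pd.DataFrame(rows)


def updated_trend_table(draws, trajectories: TrajectorySet) -> pd.DataFrame:
    """Trend table recomputed over the trajectories retained by the
    minimum-count update.

    Because trajectory i carries MCMC draw i, the retention mask is a mask
    on posterior draws; every year pair — including pairs before the
    projection's start year — is reweighted through its posterior coupling
    with the retained draws.  Requires the trajectory set and the posterior
    draws to be index-aligned (equal lengths).
    """
    from .trend import trend_table

    if trajectories.n_trajectories != draws.n_draws:
        raise ValueError(
            "trajectories and posterior draws are not index-aligned: "
            f"{trajectories.n_trajectories} vs {draws.n_draws}"
        )
    return trend_table(draws, retained=trajectories.retained)
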