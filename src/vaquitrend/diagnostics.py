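"""MCMC convergence diagnostics and posterior-predictive model checking.

Single-chain diagnostics in the classical style: Geweke's two-window mean
comparison and the Heidelberger-Welch stationarity / halfwidth tests, plus
per-observation Bayesian p-values as a goodness-of-fit check of the fitted
geostatistical model.

The spectral density of the chain at frequency zero — the long-run variance
needed by both Geweke and Heidelberger-Welch — is estimated with a Bartlett
lag window of width ``floor(sqrt(n))`` by default (``lag_window`` exposes
the rule).  The Cramer-von Mises tail probability used by the stationarity
test is evaluated with the classical Bessel-function series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


class DegenerateChainError(ValueError):
    """Raised when a chain has zero variance and a diagnostic is undefined."""


def spectral_density_zero(chain: np.ndarray, lag_window: int | None = None) -> float:
    """Long-run variance estimate S(0) via a Bartlett (triangular) lag window.

    S(0) = gamma_0 + 2 * sum_{k=1..L} (1 - k/(L+1)) * gamma_k with
    L = floor(sqrt(n)) unless overridden.  For an iid chain this reduces to
    (approximately) the sample variance; positive autocorrelation inflates it.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateChainError("chain too short for a variance estimate")
    x = x - x.mean()
    if lag_window is None:
        lag_window = int(np.sqrt(n))
    lag_window = min(lag_window, n - 1)
    acov = np.array([x[: n - k] @ x[k:] / n for k in range(lag_window + 1)])
    weights = 1.0 - np.arange(1, lag_window + 1) / (lag_window + 1)
    s0 = acov[0] + 2.0 * np.sum(weights * acov[1:])
    return float(max(s0, 0.0))


def geweke(chain, frac_a: float = 0.1, frac_b: float = 0.5,
           lag_window: int | None = None) -> float:
    """Geweke convergence z-score comparing early and late chain windows.

    z = (mean of first ``frac_a`` - mean of last ``frac_b``) normalized by
    the spectral (long-run) standard errors of the two windows.  Under
    stationarity z is approximately standard normal.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("chain length must be >= 100")
    if not (0 < frac_a and 0 < frac_b and frac_a + frac_b <= 1):
        raise ValueError("window fractions must be positive with sum <= 1")
    if np.std(x) == 0:
        raise DegenerateChainError("constant chain: Geweke z undefined")
    na = int(frac_a * x.size)
    nb = int(frac_b * x.size)
    a, b = x[:na], x[x.size - nb:]
    var_a = spectral_density_zero(a, lag_window) / na
    var_b = spectral_density_zero(b, lag_window) / nb
    if var_a + var_b == 0:
        raise DegenerateChainError("zero spectral variance in both windows")
    return float((a.mean() - b.mean()) / np.sqrt(var_a + var_b))


def cramer_von_mises_sf(q: float, n_terms: int = 10) -> float:
    """P(W2 > q) for the asymptotic Cramer-von Mises distribution.

    Classical series with modified Bessel functions K_{1/4}; the 5% critical
    value of this distribution is 0.4614.
    """
    if q <= 0:
        return 1.0
    total = 0.0
    for k in range(n_terms):
        a = (4 * k + 1) ** 2 / (16.0 * q)
        term = (
            special.gamma(k + 0.5)
            * np.sqrt(4 * k + 1)
            / (special.gamma(0.5) * special.gamma(k + 1.0))
            * np.exp(-a)
            * special.kv(0.25, a)
        )
        total += term
    cdf = total / (np.pi * np.sqrt(q))
    return float(min(max(1.0 - cdf, 0.0), 1.0))


@dataclass(frozen=True)
class HeidelbergerResult:
    stationarity_passed: bool
    start_fraction_discarded: float
    halfwidth_passed: bool
    halfwidth: float
    mean: float
    halfwidth_reliable: bool  # False when |mean| ~ 0: relative test is meaningless
    cvm_pvalue: float


def heidelberger_welch(chain, alpha: float = 0.05, halfwidth_eps: float = 0.1,
                       lag_window: int | None = None) -> HeidelbergerResult:
    """Heidelberger-Welch stationarity and halfwidth tests for one chain.

    Stationarity: a Cramer-von Mises test on the standardized Brownian
    bridge of cumulative sums; on failure the first 10% of the chain is
    discarded and the test repeated, up to 50% discarded.  Halfwidth: the
    (1-alpha) confidence halfwidth of the retained-chain mean must be below
    ``halfwidth_eps * |mean|``; flagged unreliable for near-zero means,
    where a relative criterion cannot be interpreted.
    """
    x = np.asarray(chain, dtype=float)
    n0 = x.size
    if n0 < 100:
        raise ValueError("chain length must be >= 100")
    if np.std(x) == 0:
        raise DegenerateChainError("constant chain")

    passed = False
    frac = 0.0
    pvalue = 0.0
    for drop in range(0, 6):  # discard 0%,10%,...,50% of the original chain
        frac = drop / 10.0
        y = x[int(frac * n0):]
        n = y.size
        s0 = spectral_density_zero(y, lag_window)
        if s0 == 0:
            raise DegenerateChainError("zero spectral variance")
        csum = np.cumsum(y)
        t = np.arange(1, n + 1)
        bridge = (csum - t * y.mean()) / np.sqrt(n * s0)
        cvm = float(np.sum(bridge**2) / n)
        pvalue = cramer_von_mises_sf(cvm)
        if pvalue > alpha:
            passed = True
            break

    y = x[int(frac * n0):] if passed else x[n0 // 2:]
    s0 = spectral_density_zero(y, lag_window)
    mean = float(y.mean())
    halfwidth = float(stats.norm.ppf(1 - alpha / 2) * np.sqrt(s0 / y.size))
    scale = float(np.std(x))
    reliable = abs(mean) > 0.05 * scale  # relative criterion breaks down near zero
    hw_passed = bool(reliable and passed and halfwidth < halfwidth_eps * abs(mean))
    return HeidelbergerResult(
        stationarity_passed=passed,
        start_fraction_discarded=frac,
        halfwidth_passed=hw_passed,
        halfwidth=halfwidth,
        mean=mean,
        halfwidth_reliable=reliable,
        cvm_pvalue=pvalue,
    )


def bayes_p_values(draws, dataset, seed: int = 0) -> pd.DataFrame:
    """Marginal posterior-predictive p-values, one per observed site-year.

    For each observed (t, i), replicate responses
    Y*_ti ~ Normal(mu_t + Z_ti, sigma2_eps / n_ti) are drawn per posterior
    draw and p = P(Y* <= Y_obs) is estimated with a half weight on exact
    ties.  Values near 0 or 1 flag observations the model cannot reproduce;
    a well-fitting model yields roughly uniform p-values.
    """
    ymat, nmat = dataset.response_matrices()
    obs = nmat > 0
    rng = np.random.default_rng(seed)
    rows = []
    years = draws.years
    site_ids = draws.site_ids
    for t in range(len(years)):
        for i in np.flatnonzero(obs[t]):
            mean = draws.mu[:, t] + draws.Z[:, t, i]
            sd = np.sqrt(draws.sigma2_eps / nmat[t, i])
            rep = mean + sd * rng.standard_normal(draws.n_draws)
            yobs = ymat[t, i]
            p = (np.sum(rep < yobs) + 0.5 * np.sum(rep == yobs)) / draws.n_draws
            rows.append({"year": years[t], "site_id": site_ids[i],
                         "p_value": float(p)})
    return pd.DataFrame(rows)


def diagnostic_report(draws, dataset=None, alpha: float = 0.05,
                      halfwidth_eps: float = 0.1, seed: int = 0) -> dict:
    """Full convergence + fit report for a set of posterior draws.

    Returns a dict with a per-parameter frame (Geweke z, Heidelberger-Welch
    outcomes) and, when the dataset is supplied, the Bayesian p-value frame.
    """
    rows = []
    for name, chain in draws.scalar_chains().items():
        if np.std(chain) == 0:
            rows.append({"parameter": name, "geweke_z": np.nan,
                         "hw_stationarity": True, "hw_halfwidth": True,
                         "note": "constant (fixed) chain"})
            continue
        hw = heidelberger_welch(chain, alpha=alpha, halfwidth_eps=halfwidth_eps)
        rows.append({
            "parameter": name,
            "geweke_z": geweke(chain),
            "hw_stationarity": hw.stationarity_passed,
            "hw_halfwidth": hw.halfwidth_passed,
            "note": "" if hw.halfwidth_reliable else "halfwidth unreliable (mean near 0)",
        })
    report = {"parameters": pd.DataFrame(rows)}
    if dataset is not None:
        pvals = bayes_p_values(draws, dataset, seed=seed)
        report["bayes_p"] = pvals
        report["fraction_extreme_p"] = float(
            np.mean((pvals["p_value"] < 0.025) | (pvals["p_value"] > 0.975))
        )
    report["converged"] = bool(
        np.all(np.abs(report["parameters"]["geweke_z"].fillna(0.0)) < 3.0)
        and report["parameters"]["hw_stationarity"].all()
    )
    return report
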