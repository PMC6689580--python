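"""Small plotting helpers for trend and abundance results."""

from __future__ import annotations

import numpy as np


def abundance_violin(trajectories, ax=None, retained_only: bool = True):
    """Violin plot of projected abundance per year (95% band + mean dots)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = [trajectories.abundance(y, retained_only) for y in trajectories.years]
    ax.violinplot(data, positions=range(len(data)), showextrema=False)
    ax.plot(range(len(data)), [np.mean(d) for d in data], "ko", label="posterior mean")
    for k, d in enumerate(data):
        lo, hi = np.quantile(d, [0.025, 0.975])
        ax.plot([k, k], [lo, hi], "k-", lw=1)
    ax.set_xticks(range(len(data)), [str(y) for y in trajectories.years])
    ax.set_ylabel("abundance (animals)")
    ax.legend()
    return ax


def trend_errorbar(table, ax=None):
    """Posterior-mean lambda with 95% CRIs per consecutive year pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows = table[table["period"].str.contains("-", regex=False)]
    x = np.arange(len(rows))
    mean = rows["lambda_mean"].to_numpy()
    err = np.vstack([mean - rows["cri_low"], rows["cri_high"] - mean])
    ax.errorbar(x, mean, yerr=err, fmt="o", capsize=3)
    ax.axhline(1.0, color="grey", ls="--", lw=1)
    ax.set_xticks(x, rows["period"], rotation=45, ha="right")
    ax.set_ylabel(r"annual change ratio $\lambda$")
    return ax
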