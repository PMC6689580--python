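"""Fit the geostatistical trend model and summarize annual change.

Uses a reduced MCMC run (2000 retained draws) so the example finishes in
seconds; the defaults in MCMCConfig mirror the monitoring study's much
longer production run.
"""

import vaquitrend as vt

truth = vt.scenario_study_like(seed=1)
dataset, realization = vt.simulate_dataset(truth)

draws = vt.fit(dataset, config=vt.MCMCConfig(n_burn=400, n_keep=2000, thin=2, seed=1))
print(f"kept {draws.n_draws} draws; "
      f"range-parameter acceptance rate {draws.rho_accept_rate:.2f}")

table = vt.trend_table(draws)
print(table.to_string(index=False))

# lambda_mean < 1 means the grid-average acoustic activity declined between
# the two years; prob_declining_pct is the posterior probability (in %) of
# any decline, and the >20%/yr column the probability lambda < 0.8.
print("\nrealized true ratios for comparison:",
      [round(float(x), 2) for x in realization.lambda_true])
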