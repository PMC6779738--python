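"""Bayesian mixed stock analysis with known ground truth.

Builds well-separated rookery baselines, draws a mixture sample from a known
contribution vector, and shows the Gibbs sampler recovering it, with
Gelman-Rubin convergence diagnostics and 95% credible intervals.
"""

import numpy as np

from stockshift import (
    baselines_from_frequencies,
    gelman_rubin,
    generate_mixture,
    gibbs_msa,
    prepare_mixture,
    structured_frequencies,
    summarize,
)

truth = np.array([0.6, 0.3, 0.1])
freqs = structured_frequencies(3)
baselines = baselines_from_frequencies(freqs, n_per_rookery=500, seed=1)
counts, _ = generate_mixture(freqs, truth, 300, seed=2,
                             haplotype_names=baselines.haplotype_universe)

mixture = prepare_mixture(counts, baselines)
draws = gibbs_msa(mixture, baselines, n_iter=5000, burn_in=2500, n_chains=3, seed=3)

diag = gelman_rubin(draws)
print("Gelman-Rubin R-hat per stock:",
      {s: round(float(r), 3) for s, r in zip(diag.stock_names, diag.rhat)},
      "converged:", diag.converged)

summary = summarize(draws)
for stock, mean, lo, hi, t in zip(summary.labels, summary.mean,
                                  summary.lower, summary.upper, truth):
    print(f"{stock}: posterior mean {mean:.3f} [{lo:.3f}, {hi:.3f}]  (truth {t})")
print("Each stock's true contribution should fall inside its 95% interval;")
print("posterior means typically land within a few percent of the truth at n=300.")
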