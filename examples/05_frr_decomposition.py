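"""Empirical-Bayes decomposition of the familial relative risk.

Part 1 refits the spike-and-exponential effect-size mixture (5% of genes
associated, log-OR ~ Exp(2)) from simulated carrier counts alone.

Part 2 decomposes the FRR in a scenario with a known answer: five strong
genes (carrier frequency 0.002, OR 4) among nulls, where the truth-based
share of a first-degree FRR of 2 follows from the single-gene formula
lambda_j = 1 + p (e^b - 1)^2 / (2 p (e^b - 1) + 1)^2.
"""

import numpy as np

import rvburden as rv
from rvburden.simulate import simulate_gene_counts

counts, _ = simulate_gene_counts(
    n_genes=5000, alpha=0.05, eta=2.0, n1=50_000, n0=50_000,
    carrier_freq=1e-3, seed=1,
)
fit = rv.fit_eb(counts)
print(f"true mixture: alpha = 0.05, eta = 2.0 (median OR {rv.median_or(rv.EBPrior(0.05, 2.0)):.2f})")
print(f"fitted:       alpha = {fit.prior.alpha:.4f}, eta = {fit.prior.eta:.2f} "
      f"(median OR {rv.median_or(fit.prior):.2f})")

rng = np.random.default_rng(2)
n1 = n0 = 50_000
q, beta = 2e-3, float(np.log(4.0))
q_case = q * np.exp(beta) / (1 - q + q * np.exp(beta))
strong = [f"STRONG{k}" for k in range(5)]
counts2 = [
    rv.GeneCounts(g, int(rng.binomial(n1, q_case)), int(rng.binomial(n0, q)), n1, n0)
    for g in strong
]
for i in range(1500):
    a, b = rng.binomial(n1, 5e-4), rng.binomial(n0, 5e-4)
    if a + b:
        counts2.append(rv.GeneCounts(f"N{i}", int(a), int(b), n1, n0))
fit2 = rv.fit_eb(counts2, controls_only_freq=True)

est = rv.frr_percent(fit2, subset=strong, lambda_obs=2.0)
truth = 5 * 100 * (rv.gene_frr(q / 2, beta) - 1) / (2.0 - 1.0)
posteriors = fit2.genes.set_index("gene_id").loc[strong, "posterior_assoc"]
print(f"\nfive strong genes (carrier freq {q}, OR 4):")
print(f"  posterior association probabilities: {np.round(posteriors.to_numpy(), 3)}")
print(f"  estimated share of a lambda=2 FRR: {est:.2f}%  (truth-based {truth:.2f}%)")
print("-> the fit implicates exactly the planted genes and attributes them a")
print("   familial-risk share close to the value implied by their true OR.")
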