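"""Family-history-weighted burden scan on a simulated cohort.

The regression is reversed — carrier status is the outcome and the weighted
phenotype d + f/2 the predictor — so unaffected individuals with a family
history still contribute evidence.  The example contrasts the scan with and
without the family-history term.
"""

import numpy as np

import rvburden as rv

genes = tuple(
    rv.GeneSpec(f"RISK{i}", carrier_freq=0.01, log_or=float(np.log(2.5)))
    for i in range(5)
) + tuple(rv.GeneSpec(f"NULL{i:02d}", carrier_freq=0.01) for i in range(30))
cohort = rv.simulate_cohort(
    rv.SimConfig(n_cases=4000, n_controls=4000, genes=genes,
                 baseline_risk=0.1, seed=11)
)

weighted = rv.run_genome_scan(cohort.carriers, cohort.phenotypes)
plain = rv.run_genome_scan(cohort.carriers, cohort.phenotypes.assign(f=0))

risk = weighted["gene_id"].str.startswith("RISK")
print(weighted.loc[risk, ["gene_id", "n_case_carriers", "n_control_carriers",
                          "beta", "z", "p"]].to_string(index=False))
print(f"\nmean |z| over the 5 risk genes: with d + f/2 "
      f"{weighted.loc[risk, 'z'].abs().mean():.2f} vs disease-only "
      f"{plain.loc[risk, 'z'].abs().mean():.2f}")
print("-> exp(beta) estimates each gene's carrier odds ratio (truth 2.5);")
print("   weighting in family history raises the z-scores of true risk genes.")
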