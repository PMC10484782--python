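"""Classify toy variants into burden categories and collapse to carriers.

Generates transcripts and variants that deliberately sit on every
classification boundary: the NMD-escape windows (last exon, last 50 bp of
the penultimate exon), the dual allele-frequency filter at 0.001, and the
CADD 20 / Helix 0.5 deleteriousness thresholds.
"""

import pandas as pd

import rvburden as rv
from rvburden.classify import classify_all

transcripts, annotations, genotypes = rv.simulate_annotated_variants(
    n_genes=4, seed=7
)
labels = classify_all(
    (
        rv.VariantAnnotation(
            r.variant_id, r.gene_id, r.consequence, int(r.exon_index),
            int(r.position), r.panel_af, r.cohort_af,
            None if pd.isna(r.cadd) else r.cadd,
            None if pd.isna(r.helix) else r.helix,
        )
        for r in annotations.itertuples()
    ),
    transcripts,
)

summary = labels[["PTV", "RARE_MISSENSE", "DELETERIOUS_MISSENSE_CADD",
                  "DELETERIOUS_MISSENSE_HELIX", "OTHER"]].sum()
print("variants per category (a variant may hold several labels):")
print(summary.to_string())

ptv_ids = {g: grp.loc[grp["PTV"], "variant_id"].tolist()
           for g, grp in labels.groupby("gene_id")}
carriers = rv.collapse_carriers(genotypes, "PTV", variant_ids=ptv_ids)
print("\nPTV carriers per gene (0/1 per sample, hets and homs combined):")
print(carriers.carrier_counts().to_string())
print("-> truncating variants in NMD-escape zones were excluded before collapsing.")
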