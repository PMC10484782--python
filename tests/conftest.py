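import numpy as np
import pandas as pd
import pytest

import rvburden as rv


@pytest.fixture(scope="session")
def five_exon_transcript() -> rv.TranscriptModel:
    """5 exons of 200 bp separated by 100-bp introns; penultimate exon is
    [1200, 1400), so its 3' window covers positions 1350..1399."""
    exons = tuple((i * 300, i * 300 + 200) for i in range(5))
    return rv.TranscriptModel(gene_id="G5EX", strand="+", exons=exons)


@pytest.fixture(scope="session")
def small_cohort() -> rv.SimulatedCohort:
    """One strong risk gene plus nulls; big enough for directional checks."""
    genes = (rv.GeneSpec("RISK1", carrier_freq=0.01, log_or=float(np.log(3.0))),) + tuple(
        rv.GeneSpec(f"NULL{i:02d}", carrier_freq=0.01) for i in range(10)
    )
    config = rv.SimConfig(
        n_cases=4000, n_controls=4000, genes=genes,
        baseline_risk=0.1, fh_rate_noncarrier=0.05, seed=1234,
    )
    return rv.simulate_cohort(config)


@pytest.fixture()
def toy_genotypes() -> pd.DataFrame:
    """4 samples x 3 variants with het, hom and missing calls."""
    return pd.DataFrame(
        {
            "v1": [0.0, 0.0, np.nan, 0.0],
            "v2": [2.0, 0.0, 1.0, 0.0],
            "v3": [0.0, 0.0, np.nan, np.nan],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
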