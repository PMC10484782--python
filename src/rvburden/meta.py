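"""Anchor-gene-weighted z-score meta-analysis.

Per-study burden z-scores are combined as

    z_M = sum_j w_j z_j / sqrt(sum_j w_j^2),

a weighted Stouffer combination that is standard normal under the null for
any positive weights and invariant to rescaling all weights by a common
constant.  Rather than inverse-variance weights — which mislead when the
studies' effective effect sizes differ by design (e.g. one study
oversampled familial/early-onset cases) — weights are anchored on an
established risk gene: each study's weight is the ratio of its anchor-gene
z-score to the reference study's, so a study whose design inflates effects
contributes proportionally more per unit of z.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnchorError, ValidationError

#: Median of the chi-squared distribution with 1 degree of freedom.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def two_sided_p(z) -> float | np.ndarray:
    """Two-sided normal tail probability, p = 2 (1 - Phi(|z|))."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def z_quantile(p: float) -> float:
    """|z| such that a two-sided normal test yields the given p-value."""
    if not (0 < p < 1):
        raise ValidationError("p must be in (0, 1)")
    return float(stats.norm.isf(p / 2.0))


def combine_z(zs: Sequence[float], ws: Sequence[float]) -> tuple[float, float]:
    """Weighted z combination: returns (z_M, two-sided p)."""
    zs = np.asarray(zs, dtype=float)
    ws = np.asarray(ws, dtype=float)
    if zs.shape != ws.shape or zs.ndim != 1 or len(zs) == 0:
        raise ValidationError("zs and ws must be equal-length non-empty vectors")
    if (ws <= 0).any():
        raise ValidationError("weights must be strictly positive")
    denom = np.sqrt((ws**2).sum())
    if denom == 0:
        raise ValidationError("sum of squared weights is zero")
    z_m = float((ws * zs).sum() / denom)
    return z_m, two_sided_p(z_m)


def anchor_weights(
    anchor_z: Mapping[str, float | Sequence[float]],
    reference_study: str,
) -> dict[str, float]:
    """Per-study weights from the anchor gene(s)' z-scores.

    Every anchor z must be positive: the anchor is an established risk gene
    and a non-positive z means the study failed to replicate it, in which
    case no meaningful calibration exists.  With several anchor genes, each
    study's z-scores are summed before taking ratios (which reduces to the
    single-gene rule for one gene).  The reference study receives weight 1.
    """
    if reference_study not in anchor_z:
        raise ValidationError(f"reference study {reference_study!r} not in anchor_z")
    sums = {}
    for study, zs in anchor_z.items():
        zs = np.atleast_1d(np.asarray(zs, dtype=float))
        if (zs <= 0).any():
            raise AnchorError(
                f"study {study!r}: anchor z-scores must all be positive, got {zs}"
            )
        sums[study] = float(zs.sum())
    ref = sums[reference_study]
    return {study: s / ref for study, s in sums.items()}


def inflation_lambda(zs: Sequence[float]) -> float:
    """Genomic inflation factor from the median chi-squared statistic.

    lambda = median(z^2) / median of chi^2(1 df); 1 indicates a calibrated
    scan, < 1 a conservative one, > 1 inflation.
    """
    zs = np.asarray(zs, dtype=float)
    zs = zs[np.isfinite(zs)]
    if len(zs) == 0:
        raise ValidationError("no finite z-scores")
    if len(zs) < 20:
        warnings.warn(
            f"inflation lambda from only {len(zs)} z-scores is unstable",
            stacklevel=2,
        )
    return float(np.median(zs**2) / CHI2_1DF_MEDIAN)


def meta_analyze(
    per_study: Mapping[str, pd.DataFrame],
    anchor_genes: Sequence[str],
    reference_study: str,
) -> pd.DataFrame:
    """Combine per-study genome scans into one meta-analysis table.

    ``per_study`` maps study label -> scan results (columns ``gene_id`` and
    ``z``, as produced by :func:`rvburden.burden.run_genome_scan`).  Weights
    come from :func:`anchor_weights` on the anchor genes' z-scores in the
    same scans.  Genes absent from a study are combined over the available
    studies with that study's weight dropped; the ``all_studies`` column
    flags genes seen everywhere.
    """
    if reference_study not in per_study:
        raise ValidationError(f"reference study {reference_study!r} not provided")
    z_maps = {
        study: dict(zip(frame["gene_id"], frame["z"]))
        for study, frame in per_study.items()
    }
    anchor_z = {}
    for study, zmap in z_maps.items():
        missing = [g for g in anchor_genes if g not in zmap]
        if missing:
            raise AnchorError(f"study {study!r} lacks anchor gene(s) {missing}")
        anchor_z[study] = [zmap[g] for g in anchor_genes]
    weights = anchor_weights(anchor_z, reference_study)

    studies = list(per_study)
    genes = sorted({g for zmap in z_maps.values() for g in zmap})
    rows = []
    for gene in genes:
        used = [s for s in studies if gene in z_maps[s]]
        zs = [z_maps[s][gene] for s in used]
        ws = [weights[s] for s in used]
        z_m, p = combine_z(zs, ws)
        rows.append(
            {
                "gene_id": gene,
                "z_m": z_m,
                "p": p,
                "studies_used": ",".join(used),
                "all_studies": len(used) == len(studies),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["weights"] = weights
    return out


def export_ranked_list(meta: pd.DataFrame) -> pd.DataFrame:
    """Genes ordered by descending z_M (ties broken lexicographically).

    The ranked (gene, z_m) list is the input expected by gene-set
    enrichment tools.
    """
    if len(meta) == 0:
        return pd.DataFrame(columns=["gene_id", "z_m"])
    return (
        meta[["gene_id", "z_m"]]
        .sort_values(["z_m", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def qq_data(pvalues: Sequence[float]) -> pd.DataFrame:
    """Expected vs observed -log10 p for a quantile-quantile plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    if n == 0:
        raise ValidationError("no p-values")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame(
        {"expected_neglog10p": expected, "observed_neglog10p": observed}
    )
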