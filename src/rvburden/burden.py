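"""Family-history-weighted gene burden tests.

The association model reverses the usual regression direction: the 0/1
carrier indicator is the *outcome* of a logistic regression and the
family-history-weighted disease status d + (1/2) f is the predictor, with
study covariates alongside.  Because the odds ratio is symmetric, the
coefficient of the weighted phenotype estimates the per-carrier log odds
ratio for disease while letting unaffected relatives' information (and, in
mixed-sex cohorts, males with a family history of female disease) boost
power.  The 1/2 weight reflects that for small effects the log-OR of a
positive first-degree family history is about half that of the disease
itself.

Rare carriers make complete separation routine; the fitter detects it and
falls back to Firth's bias-reduced (Jeffreys-prior penalized) logistic
regression, flagging the result with ``converged=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .classify import CarrierTable
from .errors import (
    CovariateError,
    ScanError,
    ValidationError,
    ZeroCarrierError,
)

logger = logging.getLogger(__name__)

#: Case-restriction filters available in genome scans.
RESTRICTIONS = ("er_pos", "er_neg", "pr_pos", "pr_neg", "tn", "age_lt50")

_YOUNG_BANDS = frozenset({"<40", "40-49"})


def fh_weighted_phenotype(d, f):
    """Family-history-weighted disease status d + (1/2) f.

    ``d`` is case status and ``f`` first-degree family history, both 0/1
    (scalars or arrays).  An unaffected individual with affected relatives
    contributes 0.5 — half a case's worth of evidence.
    """
    d = np.asarray(d)
    f = np.asarray(f)
    if not np.isin(d, (0, 1)).all() or not np.isin(f, (0, 1)).all():
        raise ValidationError("d and f must be 0/1")
    out = d + 0.5 * f
    return float(out) if out.ndim == 0 else out.astype(float)


@dataclass
class BurdenResult:
    """Per-gene burden test result on the log-odds scale."""

    gene_id: str
    variant_class: str
    n_case_carriers: int
    n_control_carriers: int
    beta: float
    se: float
    z: float
    p: float
    converged: bool


def _build_design(
    phenotypes: pd.DataFrame, covariate_spec: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + weighted phenotype + encoded covariates.

    Categorical covariates are dummy-encoded (first level dropped); constant
    columns are silently removed (they are absorbed by the intercept); any
    remaining rank deficiency raises :class:`CovariateError` naming an
    offending column.
    """
    x = fh_weighted_phenotype(
        phenotypes["d"].to_numpy(), phenotypes["f"].to_numpy()
    )
    cols: list[np.ndarray] = [np.ones(len(phenotypes)), x]
    names: list[str] = ["const", "fh_weighted_d"]
    for cov in covariate_spec or ():
        if cov not in phenotypes.columns:
            raise CovariateError(cov, "not found in phenotype table")
        series = phenotypes[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
    X = np.column_stack(cols)
    keep = [0] + [
        j for j in range(1, X.shape[1]) if not np.allclose(X[:, j], X[0, j])
    ]
    dropped = [names[j] for j in range(1, X.shape[1]) if j not in keep]
    if dropped:
        logger.debug("dropping constant covariate columns: %s", dropped)
    X = X[:, keep]
    names = [names[j] for j in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # the column with the smallest |R| diagonal is part of the dependency
        r = np.linalg.qr(X, mode="r")
        bad = names[int(np.argmin(np.abs(np.diag(r))))]
        raise CovariateError(bad, "design matrix is rank deficient")
    return X, names


def _firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 200, tol: float = 1e-9):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Returns (coefficients, standard errors).  Finite estimates exist even
    under complete separation, which is why this is the fallback fitter.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    se = np.sqrt(np.diag(np.linalg.pinv(X.T @ (X * w[:, None]))))
    return beta, se


def burden_regression(
    carriers: np.ndarray,
    phenotypes: pd.DataFrame,
    covariate_spec: Sequence[str] | None = None,
    gene_id: str = "",
    variant_class: str = "PTV",
    _design: tuple[np.ndarray, list[str]] | None = None,
) -> BurdenResult:
    """Test one gene: logistic regression of carrier status on d + (1/2) f.

    ``carriers`` is the per-sample 0/1 indicator for the gene, aligned with
    ``phenotypes``.  The reported beta/se/z/p belong to the weighted
    phenotype coefficient; with f == 0 and no covariates, beta equals the
    2x2-table log odds ratio by the symmetry of the odds ratio.

    Raises :class:`ZeroCarrierError` if no sample carries the gene (the scan
    skips such genes — a burden test needs at least one carrier).
    """
    y = np.asarray(carriers, dtype=float)
    if len(y) != len(phenotypes):
        raise ValidationError("carrier vector and phenotype table differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("carrier indicators must be 0/1")
    if y.sum() == 0:
        raise ZeroCarrierError(
            f"gene {gene_id or '<unnamed>'}: burden tests require at least one carrier"
        )
    d = phenotypes["d"].to_numpy()
    if d.sum() == 0:
        raise ValidationError("no cases in the analysis sample")
    X, names = _design if _design is not None else _build_design(
        phenotypes, covariate_spec
    )
    coef_idx = names.index("fh_weighted_d")

    converged = True
    try:
        # separation makes overflow in the logistic CDF routine; it is
        # detected below and handled by the Firth fallback
        with np.errstate(over="ignore", divide="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, warn_convergence=False)
        beta = fit.params[coef_idx]
        se = fit.bse[coef_idx]
        ok = (
            bool(fit.mle_retvals.get("converged", False))
            and np.isfinite(beta)
            and np.isfinite(se)
            and abs(beta) < 15
            and se < 50
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        ok = False
    if not ok:
        params, ses = _firth_logit(y, X)
        beta, se = params[coef_idx], ses[coef_idx]
        converged = False
    z = beta / se
    p = 2.0 * norm.sf(abs(z))
    carrier_mask = y == 1
    return BurdenResult(
        gene_id=gene_id,
        variant_class=variant_class,
        n_case_carriers=int((d[carrier_mask] == 1).sum()),
        n_control_carriers=int((d[carrier_mask] == 0).sum()),
        beta=float(beta),
        se=float(se),
        z=float(z),
        p=float(p),
        converged=converged,
    )


def _restrict_samples(
    phenotypes: pd.DataFrame, restriction: str | None
) -> np.ndarray:
    """Boolean keep-mask: controls always kept, cases filtered.

    Subtype restrictions drop cases whose marker is missing; the age
    restriction keeps cases diagnosed before 50.
    """
    if restriction is None:
        return np.ones(len(phenotypes), dtype=bool)
    d = phenotypes["d"].to_numpy() == 1
    if restriction == "age_lt50":
        ok = phenotypes["age_band"].isin(_YOUNG_BANDS).to_numpy()
    elif restriction in {"er_pos", "er_neg", "pr_pos", "pr_neg"}:
        col = restriction[:2].upper()
        want = "+" if restriction.endswith("pos") else "-"
        ok = (phenotypes[col] == want).to_numpy()
    elif restriction == "tn":
        ok = (
            (phenotypes["ER"] == "-")
            & (phenotypes["PR"] == "-")
            & (phenotypes["HER2"] == "-")
        ).to_numpy()
    else:
        raise ValidationError(
            f"unknown restriction {restriction!r}; choose from {RESTRICTIONS}"
        )
    return ~d | (d & ok)


def run_genome_scan(
    carrier_table: CarrierTable,
    phenotypes: pd.DataFrame,
    covariate_spec: Sequence[str] | None = None,
    restriction: str | None = None,
) -> pd.DataFrame:
    """Burden-test every gene with at least one carrier.

    Cases may be restricted to a tumor subtype or to age < 50 (controls are
    never dropped by a restriction).  Genes whose chromosome is X (looked up
    in ``carrier_table.gene_chroms``) are tested in females only.  Genes
    with zero carriers after restriction are skipped and listed, with
    reasons, in the result's ``attrs["skipped"]``.
    """
    if carrier_table.samples != phenotypes["sample_id"].tolist():
        raise ValidationError("carrier table and phenotype table sample order differ")
    keep = _restrict_samples(phenotypes, restriction)
    if (phenotypes.loc[keep, "d"] == 1).sum() == 0:
        raise ScanError(f"restriction {restriction!r} leaves no cases")
    pheno = phenotypes.loc[keep].reset_index(drop=True)
    matrix = carrier_table.matrix[keep]

    female = (pheno["sex"] == "F").to_numpy()
    designs: dict[str, tuple] = {}

    def design_for(mask_key: str, frame: pd.DataFrame):
        if mask_key not in designs:
            designs[mask_key] = _build_design(frame, covariate_spec)
        return designs[mask_key]

    pheno_f = pheno.loc[female].reset_index(drop=True)
    results, skipped = [], []
    for j, gene in enumerate(carrier_table.genes):
        on_x = carrier_table.gene_chroms.get(gene) in {"X", "chrX"}
        if on_x:
            y = matrix[female, j]
            frame = pheno_f
            key = "female"
        else:
            y = matrix[:, j]
            frame = pheno
            key = "all"
        if y.sum() == 0:
            reason = (
                "no carriers among females (chrX)" if on_x else "no carriers"
            )
            skipped.append({"gene_id": gene, "reason": reason})
            continue
        if on_x and len(frame) and (frame["d"] == 1).sum() == 0:
            skipped.append({"gene_id": gene, "reason": "no female cases (chrX)"})
            continue
        res = burden_regression(
            y, frame, covariate_spec, gene_id=gene,
            variant_class=carrier_table.variant_class,
            _design=design_for(key, frame),
        )
        results.append(res.__dict__)
    out = pd.DataFrame(
        results,
        columns=[
            "gene_id", "variant_class", "n_case_carriers", "n_control_carriers",
            "beta", "se", "z", "p", "converged",
        ],
    )
    out.attrs["skipped"] = skipped  # list of {gene_id, reason} records
    out.attrs["restriction"] = restriction
    for rec in skipped:
        logger.info("skipped %s: %s", rec["gene_id"], rec["reason"])
    return out
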