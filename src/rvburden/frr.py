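"""Empirical-Bayes decomposition of the familial relative risk (FRR).

Single-gene contribution.  For a rare dominant locus with risk-allele
frequency p and per-carrier relative risk e^beta, the FRR to a first-degree
relative contributed by that gene is

    lambda_j = 1 + p (e^beta - 1)^2 / (2 p (e^beta - 1) + 1)^2,

and contributions of independent genes are additive on the excess scale:
lambda = 1 + sum_j (lambda_j - 1).

Effect-size prior.  Across genes, a proportion alpha are risk-associated
and their log odds ratios beta follow an Exponential(eta) distribution
(median OR = exp(ln 2 / eta)); the remaining genes are exactly null.  The
per-gene evidence is an approximate likelihood of the observed carrier
counts: by default a normal likelihood on the empirical log-OR (Woolf
variance, 0.5 continuity correction for zero cells), optionally the exact
conditional likelihood of the 2x2 table (Fisher's noncentral
hypergeometric).  The mixture marginal has a closed form for the normal
likelihood — an exponentially modified Gaussian tail — and is maximized
numerically over (alpha, eta) to give posterior effect-size distributions
per gene and hence posterior-expected FRR contributions.

Allele frequencies p_j are estimated from the carrier counts of cases and
controls combined and incremented by a per-gene structural-variant allele
frequency, since exome calling misses large rearrangements that truncate
the same genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr, logsumexp

from .errors import DomainError, FitError, ParameterError, ValidationError

# fixed Gauss-Legendre rule on beta in [0, BETA_MAX] for posterior integrals
BETA_MAX = 5.0
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)
_NODES = 0.5 * BETA_MAX * (_GL_NODES + 1.0)
_WEIGHTS = 0.5 * BETA_MAX * _GL_WEIGHTS


def gene_frr(p, beta):
    """FRR contributed by one gene with allele frequency p and log-RR beta.

    Accepts scalars or arrays.  Equals 1 iff p = 0 or beta = 0, and is
    >= 1 for every admissible (p, beta).
    """
    p = np.asarray(p, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if (p < 0).any() or (p > 0.5).any():
        raise ParameterError("allele frequency p must be in [0, 0.5]")
    r1 = np.expm1(beta)  # e^beta - 1
    denom = 2.0 * p * r1 + 1.0
    if (denom <= 0).any():
        raise DomainError("2 p (e^beta - 1) + 1 must be positive")
    out = 1.0 + p * r1**2 / denom**2
    return float(out) if out.ndim == 0 else out


def total_frr(lambdas: Sequence[float]) -> float:
    """Additive total FRR over genes: 1 + sum (lambda_j - 1)."""
    lam = np.asarray(lambdas, dtype=float)
    if (lam < 1.0 - 1e-12).any():
        raise ValidationError("per-gene FRR contributions must be >= 1")
    return float(1.0 + (lam - 1.0).sum())


@dataclass(frozen=True)
class GeneCounts:
    """Carrier counts for one gene: a/n1 in cases, b/n0 in controls."""

    gene_id: str
    a: int
    b: int
    n1: int
    n0: int
    sv_freq: float = 0.0  # structural-variant allele frequency

    def __post_init__(self):
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n0):
            raise ValidationError(f"{self.gene_id}: carrier counts exceed cohort sizes")
        if self.sv_freq < 0:
            raise ValidationError(f"{self.gene_id}: sv_freq must be >= 0")


@dataclass(frozen=True)
class EBPrior:
    """Mixture prior: P(assoc) = alpha; beta | assoc ~ Exponential(eta)."""

    alpha: float
    eta: float

    def __post_init__(self):
        if not (0 <= self.alpha <= 1):
            raise ParameterError("alpha must be in [0, 1]")
        if self.eta <= 0:
            raise ParameterError("eta must be positive")


@dataclass
class EBFit:
    """Fitted prior plus per-gene posterior summaries.

    ``genes`` has one row per gene: the empirical log-OR and its standard
    error, the adjusted allele frequency, the posterior probability of
    association, and the posterior-expected excess FRR contribution
    E[lambda_j - 1 | data].
    """

    prior: EBPrior
    loglik: float
    converged: bool
    genes: pd.DataFrame = field(repr=False)
    likelihood: str = "normal"


def adjusted_frequency(counts: GeneCounts, controls_only: bool = False) -> float:
    """PTV allele frequency from carrier counts, plus the SV allele frequency.

    p_hat = (a + b) / (2 (n1 + n0)) by default; structural variants are
    disjoint rare events to first order, so their allele frequency adds.
    ``controls_only`` uses b / (2 n0) instead — unbiased for the population
    frequency when cases are a small or enriched fraction of the sample.
    """
    if controls_only:
        p = counts.b / (2.0 * counts.n0) + counts.sv_freq
    else:
        p = (counts.a + counts.b) / (2.0 * (counts.n1 + counts.n0)) + counts.sv_freq
    if p > 0.5:
        raise DomainError(f"{counts.gene_id}: adjusted allele frequency {p} > 0.5")
    return float(p)


def empirical_log_or(counts: GeneCounts) -> tuple[float, float]:
    """Empirical log odds ratio and Woolf standard error from the 2x2 table.

    Cells are (a, n1 - a; b, n0 - b); a 0.5 continuity correction is added
    to every cell whenever any cell is zero.
    """
    if counts.a + counts.b < 1:
        raise ValidationError(f"{counts.gene_id}: no carriers at all")
    cells = np.array(
        [counts.a, counts.n1 - counts.a, counts.b, counts.n0 - counts.b],
        dtype=float,
    )
    if (cells == 0).any():
        cells = cells + 0.5
    a, c, b, d = cells
    bhat = float(np.log(a * d / (b * c)))
    se = float(np.sqrt((1.0 / cells).sum()))
    return bhat, se


def _log_assoc_marginal(bhat, s, eta):
    """log integral_0^inf N(bhat; beta, s^2) eta e^(-eta beta) dbeta.

    Closed form (exponentially modified Gaussian tail):
    eta exp(eta^2 s^2 / 2 - eta bhat) Phi(bhat / s - eta s).
    """
    bhat = np.asarray(bhat, dtype=float)
    s = np.asarray(s, dtype=float)
    return np.log(eta) + 0.5 * eta**2 * s**2 - eta * bhat + log_ndtr(bhat / s - eta * s)


def _mixture_logliks(bhat, s, alpha, eta):
    """Per-gene log of (1 - alpha) L0 + alpha L1 under the normal likelihood."""
    l0 = stats.norm.logpdf(bhat, loc=0.0, scale=s)
    if alpha == 0:
        return l0
    l1 = _log_assoc_marginal(bhat, s, eta)
    if alpha == 1:
        return l1
    stacked = np.stack([l0 + np.log1p(-alpha), l1 + np.log(alpha)])
    return logsumexp(stacked, axis=0)


def marginal_loglik(counts: GeneCounts, prior: EBPrior) -> float:
    """Approximate log marginal likelihood of one gene's carrier counts.

    Normal likelihood on the empirical log-OR, marginalized over the
    spike-and-exponential prior; the associated component's integral is
    evaluated in closed form.
    """
    bhat, s = empirical_log_or(counts)
    return float(_mixture_logliks(np.array([bhat]), np.array([s]), prior.alpha, prior.eta)[0])


def _conditional_logpmf_grid(counts: GeneCounts, betas: np.ndarray) -> np.ndarray:
    """log P(a | a + b, beta) under Fisher's noncentral hypergeometric.

    Conditioning on the total carrier count eliminates the nuisance carrier
    frequency; the odds ratio e^beta is the only parameter.
    """
    total = counts.a + counts.b
    n = counts.n1 + counts.n0
    return stats.nchypergeom_fisher.logpmf(
        counts.a, n, counts.n1, total, np.exp(betas)
    )


_Likelihood = Literal["normal", "binomial"]


def _per_gene_evidence(
    gene_counts: Sequence[GeneCounts], likelihood: _Likelihood
):
    """Precompute what each likelihood needs so the (alpha, eta) search is cheap.

    normal:  (bhat, s) vectors — mixture marginal is closed-form.
    binomial: log conditional pmf at beta = 0 and on the quadrature grid —
    the exponential prior is integrated numerically on the same fixed rule.
    """
    if likelihood == "normal":
        bhat = np.empty(len(gene_counts))
        s = np.empty(len(gene_counts))
        for i, gc in enumerate(gene_counts):
            bhat[i], s[i] = empirical_log_or(gc)
        return {"bhat": bhat, "s": s}
    grid = np.empty((len(gene_counts), len(_NODES)))
    null = np.empty(len(gene_counts))
    for i, gc in enumerate(gene_counts):
        grid[i] = _conditional_logpmf_grid(gc, _NODES)
        null[i] = _conditional_logpmf_grid(gc, np.array([0.0]))[0]
    return {"grid": grid, "null": null}


def _total_loglik(alpha, eta, evidence, likelihood: _Likelihood):
    if likelihood == "normal":
        return float(
            _mixture_logliks(evidence["bhat"], evidence["s"], alpha, eta).sum()
        )
    # numeric prior integral on the fixed rule, in log space
    log_prior = np.log(eta) - eta * _NODES + np.log(_WEIGHTS)
    l1 = logsumexp(evidence["grid"] + log_prior[None, :], axis=1)
    l0 = evidence["null"]
    if alpha == 0:
        per_gene = l0
    elif alpha == 1:
        per_gene = l1
    else:
        per_gene = logsumexp(
            np.stack([l0 + np.log1p(-alpha), l1 + np.log(alpha)]), axis=0
        )
    return float(per_gene.sum())


_MULTISTARTS = ((1e-4, 0.5), (1e-3, 1.0), (0.01, 2.0), (0.05, 4.0), (0.2, 8.0))
_BOUNDS = ((1e-8, 0.99), (0.02, 50.0))


def fit_eb(
    gene_counts: Sequence[GeneCounts],
    likelihood: _Likelihood = "normal",
    lambda_obs: float = 2.0,
    controls_only_freq: bool = False,
) -> EBFit:
    """Maximize the summed marginal likelihood over (alpha, eta).

    Bounded quasi-Newton (L-BFGS-B) from five deterministic starting points;
    the best optimum wins.  Per-gene posteriors are then filled in:
    posterior association probability alpha L1 / ((1 - alpha) L0 + alpha L1)
    and E[lambda_j - 1 | data] by 256-node Gauss-Legendre quadrature over
    the posterior of beta on [0, 5].

    ``lambda_obs`` is only recorded for downstream percentage reporting
    (see :func:`frr_percent`); it does not affect the fit.
    """
    gene_counts = list(gene_counts)
    if len(gene_counts) == 0:
        raise ValidationError("no genes to fit")
    if len(gene_counts) < 100:
        warnings.warn(
            f"fitting the effect-size mixture on only {len(gene_counts)} genes; "
            "estimates of (alpha, eta) will be unstable",
            stacklevel=2,
        )
    evidence = _per_gene_evidence(gene_counts, likelihood)

    def nll(theta):
        return -_total_loglik(theta[0], theta[1], evidence, likelihood)

    best = None
    for start in _MULTISTARTS:
        res = optimize.minimize(
            nll, np.array(start), method="L-BFGS-B", bounds=_BOUNDS
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("optimizer failed from every starting point")
    alpha, eta = float(best.x[0]), float(best.x[1])
    prior = EBPrior(alpha=alpha, eta=eta)
    genes = _posterior_table(
        gene_counts, prior, evidence, likelihood, controls_only_freq
    )
    return EBFit(
        prior=prior,
        loglik=float(-best.fun),
        converged=bool(best.success),
        genes=genes,
        likelihood=likelihood,
    )


def _posterior_table(
    gene_counts: Sequence[GeneCounts],
    prior: EBPrior,
    evidence,
    likelihood: _Likelihood,
    controls_only_freq: bool = False,
) -> pd.DataFrame:
    alpha, eta = prior.alpha, prior.eta
    log_prior_w = -eta * _NODES  # exponential prior density up to eta factor
    rows = []
    for i, gc in enumerate(gene_counts):
        p_adj = adjusted_frequency(gc, controls_only=controls_only_freq)
        if likelihood == "normal":
            bhat, s = evidence["bhat"][i], evidence["s"][i]
            l0 = stats.norm.logpdf(bhat, loc=0.0, scale=s)
            log_like_nodes = stats.norm.logpdf(bhat, loc=_NODES, scale=s)
            l1 = float(_log_assoc_marginal(bhat, s, eta))
        else:
            bhat, s = empirical_log_or(gc)
            l0 = evidence["null"][i]
            log_like_nodes = evidence["grid"][i]
            l1 = logsumexp(
                log_like_nodes + log_prior_w + np.log(eta) + np.log(_WEIGHTS)
            )
        if alpha == 0:
            post = 0.0
        elif alpha == 1:
            post = 1.0
        else:
            post = float(
                1.0 / (1.0 + np.exp(np.log1p(-alpha) + l0 - np.log(alpha) - l1))
            )
        # posterior of beta within the associated component, on the nodes
        log_w = log_like_nodes + log_prior_w + np.log(_WEIGHTS)
        w = np.exp(log_w - logsumexp(log_w))
        lam_excess = gene_frr(p_adj, _NODES) - 1.0
        e_lambda_m1 = post * float((w * lam_excess).sum())
        rows.append(
            {
                "gene_id": gc.gene_id,
                "bhat": float(bhat),
                "se": float(s),
                "p_adj": p_adj,
                "posterior_assoc": post,
                "expected_lambda_minus1": e_lambda_m1,
            }
        )
    return pd.DataFrame(rows)


def median_or(prior: EBPrior) -> float:
    """Median odds ratio among associated genes: exp(ln 2 / eta)."""
    return float(np.exp(np.log(2.0) / prior.eta))


def frr_percent(
    fit: EBFit,
    subset: Sequence[str] | None = None,
    lambda_obs: float = 2.0,
) -> float:
    """Percent of the observed first-degree FRR explained by a gene subset.

    100 * sum over the subset of E[lambda_j - 1 | data] / (lambda_obs - 1),
    where ``lambda_obs`` is the observed overall familial relative risk
    (default 2.0, the conventional first-degree value for breast cancer).
    Percentages are additive over disjoint subsets.
    """
    if lambda_obs <= 1:
        raise ParameterError("lambda_obs must exceed 1")
    table = fit.genes
    if subset is not None:
        subset = list(subset)
        known = set(table["gene_id"])
        unknown = [g for g in subset if g not in known]
        if unknown:
            raise ValidationError(f"genes not in the fit: {unknown[:5]}")
        table = table[table["gene_id"].isin(subset)]
    return float(100.0 * table["expected_lambda_minus1"].sum() / (lambda_obs - 1.0))


def counts_from_scan(
    carrier_matrix: np.ndarray,
    d: np.ndarray,
    gene_ids: Sequence[str],
    sv_freqs: dict[str, float] | None = None,
) -> list[GeneCounts]:
    """Build per-gene carrier counts from a carrier matrix and case status."""
    d = np.asarray(d) == 1
    n1, n0 = int(d.sum()), int((~d).sum())
    sv_freqs = sv_freqs or {}
    out = []
    for j, gene in enumerate(gene_ids):
        col = carrier_matrix[:, j]
        out.append(
            GeneCounts(
                gene_id=gene,
                a=int(col[d].sum()),
                b=int(col[~d].sum()),
                n1=n1,
                n0=n0,
                sv_freq=float(sv_freqs.get(gene, 0.0)),
            )
        )
    return out
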