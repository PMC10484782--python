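"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator produces case-control exome cohorts in which each gene has a
rare 0/1 carrier indicator, disease follows a logistic model with
per-carrier log odds ratios summed over genes, and first-degree family
history arises mechanistically: every proband has one simulated relative
who inherits each carried allele with probability 1/2 and whose disease
risk is the baseline lifetime risk K multiplied by e^beta per carried risk
gene (capped at 1).  Because transmission correlates relative genotype with
proband genotype, family history is positively associated with carrier
status — the property the family-history-weighted burden test exploits.

Also provided: an effect-size sampler for the spike-and-exponential gene
mixture, a proband-relative pair simulator that serves as a Monte-Carlo
oracle for the single-gene familial relative risk formula, and a
deterministic generator of toy transcripts/variants that covers every
classification boundary (NMD windows, AF/CADD/Helix thresholds).

Carriers are simulated directly as 0/1 indicators (no diploid genotypes):
the analysis collapses genotypes to carrier status anyway, and for rare
variants the allele frequency is carrier_freq / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .classify import CarrierTable, TranscriptModel
from .errors import ParameterError, SimulationError, UndefinedEstimateError

AGE_BANDS = ("<40", "40-49", "50-59", "60-69", "70+")
AGE_BAND_PROBS = (0.10, 0.20, 0.30, 0.25, 0.15)
YOUNG_BANDS = frozenset({"<40", "40-49"})
COUNTRIES = ("UK", "DE", "FR", "ES")
PC_COLUMNS = tuple(f"PC{i}" for i in range(1, 11))

PHENOTYPE_COLUMNS = (
    "sample_id", "d", "f", "sex", "age_band", "ER", "PR", "HER2",
    "study", "country", "libprep", *PC_COLUMNS,
)


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth parameters for one simulated gene.

    carrier_freq is the aggregate population probability of carrying any
    qualifying (PTV-like) variant in the gene; under the rare-variant
    approximation the allele frequency is carrier_freq / 2.  log_or is the
    per-carrier log odds ratio for disease; log_or_young, if set, replaces
    it for cases in the <50 age bands (used for age-restricted scans).
    """

    gene_id: str
    carrier_freq: float
    log_or: float = 0.0
    sv_carrier_freq: float = 0.0
    missense_count: int = 0
    missense_af: float = 1e-4
    cadd_range: tuple[float, float] = (10.0, 35.0)
    helix_range: tuple[float, float] = (0.05, 0.95)
    chrom: str = "1"
    log_or_young: float | None = None

    def __post_init__(self):
        if not (0 <= self.carrier_freq <= 0.5):
            raise ParameterError(f"{self.gene_id}: carrier_freq must be in [0, 0.5]")
        if self.sv_carrier_freq < 0 or self.carrier_freq + self.sv_carrier_freq >= 1:
            raise ParameterError(
                f"{self.gene_id}: need 0 <= sv_carrier_freq and "
                "carrier_freq + sv_carrier_freq < 1"
            )
        if self.missense_count < 0 or self.missense_af < 0:
            raise ParameterError(f"{self.gene_id}: negative missense parameters")


@dataclass(frozen=True)
class StudySpec:
    """Sampling design of one contributing study.

    Oversampling multipliers enrich accepted cases for family-history
    positivity / young age at diagnosis via rejection sampling, emulating
    studies that preferentially recruit familial or early-onset cases.
    """

    label: str
    fh_oversample: float = 1.0
    young_oversample: float = 1.0
    male_control_fraction: float = 0.0
    libprep: str = "LP1"

    def __post_init__(self):
        if self.fh_oversample < 1 or self.young_oversample < 1:
            raise ParameterError("oversampling multipliers must be >= 1")
        if not (0 <= self.male_control_fraction < 1):
            raise ParameterError("male_control_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated multi-study cohort.

    baseline_risk is the lifetime disease probability K of a non-carrier
    individual (and of a non-carrier's relative); it sets both the logistic
    intercept for probands and the relative's penetrance scale.
    n_cases/n_controls are totals, split evenly across study_specs.
    """

    n_cases: int
    n_controls: int
    genes: tuple[GeneSpec, ...]
    baseline_risk: float = 0.10
    fh_rate_noncarrier: float = 0.05
    seed: int = 0
    study_specs: tuple[StudySpec, ...] = (StudySpec("STUDY1"),)

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ParameterError("n_cases and n_controls must be positive")
        if not (0 < self.baseline_risk < 1):
            raise ParameterError("baseline_risk must be in (0, 1)")
        if not (0 <= self.fh_rate_noncarrier < 1):
            raise ParameterError("fh_rate_noncarrier must be in [0, 1)")
        if not self.genes:
            raise ParameterError("at least one gene required")
        if not self.study_specs:
            raise ParameterError("at least one study required")


@dataclass
class SimulatedCohort:
    """Simulated phenotypes, carrier table, and the generating truth."""

    phenotypes: pd.DataFrame
    carriers: CarrierTable
    truth: dict[str, tuple[float, float]]
    config: SimConfig

    def __post_init__(self):
        if len(self.phenotypes) != len(self.carriers.samples):
            raise SimulationError("phenotype and carrier row counts differ")
        missing = [g for g in self.carriers.genes if g not in self.truth]
        if missing:
            raise SimulationError(f"truth missing genes: {missing[:5]}")


def draw_gene_effects(
    n_genes: int, alpha: float, eta: float, seed: int
) -> np.ndarray:
    """Sample per-gene log odds ratios from the spike-and-exponential mixture.

    Each gene is risk-associated with probability ``alpha``; associated
    genes draw beta from an Exponential distribution with rate ``eta``
    (mean 1/eta, median ln2/eta), the rest are exactly null (beta = 0).
    """
    if not (0 <= alpha <= 1):
        raise ParameterError("alpha must be in [0, 1]")
    if eta <= 0:
        raise ParameterError("eta must be positive")
    rng = np.random.default_rng(seed)
    assoc = rng.random(n_genes) < alpha
    betas = np.zeros(n_genes)
    betas[assoc] = rng.exponential(scale=1.0 / eta, size=int(assoc.sum()))
    return betas


def _draw_sparse_carriers(
    rng: np.random.Generator, n: int, freqs: np.ndarray
) -> np.ndarray:
    """n x G carrier matrix drawn gene-by-gene (rare genes => cheap)."""
    out = np.zeros((n, len(freqs)), dtype=np.int8)
    for g, q in enumerate(freqs):
        k = rng.binomial(n, q)
        if k:
            out[rng.choice(n, size=k, replace=False), g] = 1
    return out


def _simulate_family_history(
    rng: np.random.Generator,
    carriers: np.ndarray,
    betas: np.ndarray,
    freqs: np.ndarray,
    baseline_risk: float,
    fh_rate_noncarrier: float,
) -> np.ndarray:
    """Family history via one simulated first-degree relative per proband.

    The relative carries each gene with probability 1/2 if the proband
    carries it (allele transmission), otherwise at the population carrier
    frequency; the relative is affected with probability
    min(1, K * exp(sum beta over carried risk genes)).  An independent
    background event at rate fh_rate_noncarrier adds non-genetic family
    history (other relatives, phenocopies).
    """
    n = carriers.shape[0]
    nz = np.flatnonzero(betas != 0.0)
    rel_score = np.zeros(n)
    for g in nz:
        p_rel = np.where(carriers[:, g] == 1, 0.5, freqs[g])
        rel_carrier = rng.random(n) < p_rel
        rel_score += betas[g] * rel_carrier
    rel_risk = np.minimum(1.0, baseline_risk * np.exp(rel_score))
    rel_affected = rng.random(n) < rel_risk
    background = rng.random(n) < fh_rate_noncarrier
    return (rel_affected | background).astype(np.int8)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Sample a case-control cohort (possibly multi-study) from the model.

    Individuals are drawn in chunks from the population model: carriers per
    gene, then disease with probability expit(logit(K) + sum beta_g * G_g),
    then the family-history mechanism.  Cases and controls are accepted per
    study until quotas are met, with rejection sampling implementing
    family-history / early-onset oversampling.  Covariates (sex, age band,
    ER/PR/HER2 for cases, country, library prep, ten principal components)
    are populated; PCs and country carry no true effect.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.genes
    gene_ids = [g.gene_id for g in genes]
    freqs = np.array([g.carrier_freq for g in genes])
    betas = np.array([g.log_or for g in genes])
    betas_young = np.array(
        [g.log_or if g.log_or_young is None else g.log_or_young for g in genes]
    )
    b0 = logit(config.baseline_risk)

    n_studies = len(config.study_specs)
    case_quota = _split_evenly(config.n_cases, n_studies)
    control_quota = _split_evenly(config.n_controls, n_studies)

    kept_rows: list[pd.DataFrame] = []
    kept_carriers: list[np.ndarray] = []
    chunk = max(8192, 4 * (config.n_cases + config.n_controls) // max(n_studies, 1))
    chunk = min(chunk, 65536)  # bounds chunk memory at many-gene scale
    max_draws = 400 * (config.n_cases + config.n_controls) + 2_000_000

    for s_idx, study in enumerate(config.study_specs):
        need_cases, need_controls = case_quota[s_idx], control_quota[s_idx]
        drawn = 0
        w_max = study.fh_oversample * study.young_oversample
        while need_cases > 0 or need_controls > 0:
            if drawn > max_draws:
                raise SimulationError(
                    f"study {study.label}: exhausted {drawn} draws with "
                    f"{need_cases} cases / {need_controls} controls still "
                    "needed; baseline_risk or cohort sizes are infeasible"
                )
            m = chunk
            drawn += m
            carriers = _draw_sparse_carriers(rng, m, freqs)
            age_band = rng.choice(len(AGE_BANDS), size=m, p=AGE_BAND_PROBS)
            young = np.isin(age_band, [0, 1])
            # risk score over effect genes only; null genes cannot move it
            nz = np.flatnonzero((betas != 0.0) | (betas_young != betas))
            if len(nz):
                sub = carriers[:, nz].astype(float)
                score = sub @ betas[nz]
                if (betas_young[nz] != betas[nz]).any():
                    score = np.where(young, sub @ betas_young[nz], score)
            else:
                score = np.zeros(m)
            d = (rng.random(m) < expit(b0 + score)).astype(np.int8)
            f = _simulate_family_history(
                rng, carriers, betas, freqs,
                config.baseline_risk, config.fh_rate_noncarrier,
            )
            # oversampling acceptance weights apply to cases only
            w = np.where(f == 1, study.fh_oversample, 1.0)
            w = w * np.where(young, study.young_oversample, 1.0)
            accept_case = (d == 1) & (rng.random(m) < w / w_max)
            case_idx = np.flatnonzero(accept_case)[:need_cases]
            control_idx = np.flatnonzero(d == 0)[:need_controls]
            need_cases -= len(case_idx)
            need_controls -= len(control_idx)
            keep = np.concatenate([case_idx, control_idx])
            if len(keep) == 0:
                continue
            rows = _covariate_frame(
                rng, study, d[keep], f[keep],
                np.asarray(AGE_BANDS)[age_band[keep]],
            )
            kept_rows.append(rows)
            kept_carriers.append(carriers[keep])

    phenotypes = pd.concat(kept_rows, ignore_index=True)
    matrix = np.vstack(kept_carriers)
    phenotypes.insert(
        0, "sample_id", [f"S{i:07d}" for i in range(len(phenotypes))]
    )
    carriers = CarrierTable(
        samples=phenotypes["sample_id"].tolist(),
        genes=gene_ids,
        variant_class="PTV",
        matrix=matrix,
        gene_chroms={g.gene_id: g.chrom for g in genes},
    )
    truth = {g.gene_id: (g.carrier_freq, g.log_or) for g in genes}
    return SimulatedCohort(
        phenotypes=phenotypes[list(PHENOTYPE_COLUMNS)],
        carriers=carriers, truth=truth, config=config,
    )


def _split_evenly(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _covariate_frame(
    rng: np.random.Generator,
    study: StudySpec,
    d: np.ndarray,
    f: np.ndarray,
    age_band: np.ndarray,
) -> pd.DataFrame:
    """Covariates with no true genetic effect: noise PCs, categorical labels."""
    m = len(d)
    sex = np.where(
        (d == 0) & (rng.random(m) < study.male_control_fraction), "M", "F"
    )
    is_case = d == 1
    er = np.where(is_case, np.where(rng.random(m) < 0.80, "+", "-"), "missing")
    pr = np.where(is_case, np.where(rng.random(m) < 0.70, "+", "-"), "missing")
    her2 = np.where(is_case, np.where(rng.random(m) < 0.15, "+", "-"), "missing")
    frame = pd.DataFrame(
        {
            "d": d.astype(np.int8),
            "f": f.astype(np.int8),
            "sex": sex,
            "age_band": age_band,
            "ER": er,
            "PR": pr,
            "HER2": her2,
            "study": study.label,
            "country": rng.choice(COUNTRIES, size=m),
            "libprep": study.libprep,
        }
    )
    pcs = rng.standard_normal((m, 10))
    for i, col in enumerate(PC_COLUMNS):
        frame[col] = pcs[:, i]
    return frame


# ---------------------------------------------------------------------------
# proband-relative pairs: Monte-Carlo oracle for the single-gene FRR formula


def simulate_proband_relative_pairs(
    carrier_freq: float,
    log_or: float,
    baseline_risk: float,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate proband/first-degree-relative pairs at a single gene.

    The proband carries with probability ``carrier_freq``.  The relative
    inherits a transmitted allele with probability 1/2 when the proband is
    a carrier and otherwise carries at the population frequency.  Both are
    affected independently given genotype with probability
    ``baseline_risk * exp(log_or * carrier)``.
    """
    if not (0 <= carrier_freq <= 0.5):
        raise ParameterError("carrier_freq must be in [0, 0.5]")
    if not (0 < baseline_risk < 1):
        raise ParameterError("baseline_risk must be in (0, 1)")
    if baseline_risk * np.exp(log_or) > 1:
        raise ParameterError(
            f"carrier penetrance K*e^beta = "
            f"{baseline_risk * np.exp(log_or):.3f} exceeds 1"
        )
    rng = np.random.default_rng(seed)
    proband = rng.random(n) < carrier_freq
    p_rel = np.where(proband, 0.5 + carrier_freq / 2.0, carrier_freq)
    relative = rng.random(n) < p_rel
    risk = baseline_risk * np.exp(log_or * np.array([0.0, 1.0]))
    proband_aff = rng.random(n) < risk[proband.astype(int)]
    relative_aff = rng.random(n) < risk[relative.astype(int)]
    return pd.DataFrame(
        {
            "proband_carrier": proband.astype(np.int8),
            "proband_affected": proband_aff.astype(np.int8),
            "relative_carrier": relative.astype(np.int8),
            "relative_affected": relative_aff.astype(np.int8),
        }
    )


def empirical_frr(pairs: pd.DataFrame) -> float:
    """Familial relative risk estimated from proband-relative pairs.

    Returns P(relative affected | proband affected) / P(relative affected).
    """
    if len(pairs) == 0:
        raise UndefinedEstimateError("no pairs")
    proband_aff = pairs["proband_affected"].to_numpy(dtype=bool)
    relative_aff = pairs["relative_affected"].to_numpy(dtype=bool)
    if proband_aff.sum() == 0:
        raise UndefinedEstimateError("no affected probands")
    p_rel = relative_aff.mean()
    if p_rel == 0:
        raise UndefinedEstimateError("no affected relatives")
    return float(relative_aff[proband_aff].mean() / p_rel)


# ---------------------------------------------------------------------------
# toy annotated variants covering every classification boundary


def simulate_annotated_variants(
    n_genes: int = 5,
    exons_per_gene: tuple[int, int] = (3, 6),
    variants_per_gene: tuple[int, int] = (8, 14),
    n_samples: int = 40,
    seed: int = 0,
):
    """Toy transcripts, annotations, and genotypes for classification tests.

    Deterministic given the seed.  For every multi-exon gene the variant set
    covers, by construction: an interior-exon PTV, a last-exon PTV, PTVs at
    1, 50 and 51 bases from the penultimate exon's 3' end, and missense
    variants with allele frequencies straddling (and hitting exactly) 0.001,
    CADD scores straddling 20 and Helix scores straddling 0.5.

    Returns ``(transcripts, annotations, genotypes)``: a dict of
    :class:`TranscriptModel` per gene, an annotation DataFrame, and a dict
    gene -> samples x variants allele-count table (NaN = missing call).
    """
    if exons_per_gene[0] < 1:
        raise ParameterError("exons_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    transcripts: dict[str, TranscriptModel] = {}
    ann_rows = []
    genotypes: dict[str, pd.DataFrame] = {}
    samples = [f"T{i:03d}" for i in range(n_samples)]

    for g in range(n_genes):
        gene = f"GENE{g + 1:03d}"
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        # exon lengths >= 120 so the 51-bp position exists in the penultimate exon
        lengths = rng.integers(120, 300, size=n_exons)
        starts = np.concatenate([[0], np.cumsum(lengths[:-1] + rng.integers(50, 500, size=n_exons - 1))]) if n_exons > 1 else np.array([0])
        exons = tuple((int(s), int(s + l)) for s, l in zip(starts, lengths))
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts[gene] = TranscriptModel(gene_id=gene, strand=strand, exons=exons)

        variants: list[dict] = []

        def add(consequence, exon_index, offset_from_3prime=None, position=None,
                panel_af=1e-4, cohort_af=1e-4, cadd=None, helix=None):
            start, end = exons[exon_index - 1]
            if position is None:
                position = end - offset_from_3prime
            variants.append(
                dict(
                    gene_id=gene, consequence=consequence,
                    exon_index=exon_index, position=int(position),
                    panel_af=panel_af, cohort_af=cohort_af,
                    cadd=cadd, helix=helix,
                )
            )

        if n_exons >= 2:
            pen = n_exons - 1
            add("stop_gained", n_exons, position=exons[-1][0])       # last exon
            add("stop_gained", pen, offset_from_3prime=1)            # 1 bp from 3' end
            add("stop_gained", pen, offset_from_3prime=50)           # exactly at window
            add("stop_gained", pen, offset_from_3prime=51)           # just outside
            add("frameshift", pen, position=exons[pen - 1][0])       # 5' of penultimate
        if n_exons >= 3:
            add("stop_gained", 1, position=exons[0][0] + 5)          # interior exon
            add("splice_donor", 2, position=exons[1][0] + 3)
        # missense straddling every threshold
        mid = max(1, n_exons // 2)
        pos0 = exons[mid - 1][0]
        add("missense", mid, position=pos0 + 1, panel_af=5e-4, cohort_af=5e-4,
            cadd=25.0, helix=0.6)
        add("missense", mid, position=pos0 + 2, panel_af=0.001, cohort_af=5e-4,
            cadd=25.0, helix=0.6)                                    # AF exactly 0.001
        add("missense", mid, position=pos0 + 3, panel_af=5e-4, cohort_af=0.002,
            cadd=30.0, helix=0.7)                                    # fails dual filter
        add("missense", mid, position=pos0 + 4, panel_af=5e-4, cohort_af=5e-4,
            cadd=20.0, helix=0.5)                                    # edge scores
        add("missense", mid, position=pos0 + 5, panel_af=5e-4, cohort_af=5e-4,
            cadd=19.9, helix=0.51)
        n_extra = max(0, int(rng.integers(*variants_per_gene)) - len(variants))
        for _ in range(n_extra):
            ei = int(rng.integers(1, n_exons + 1))
            s0, e0 = exons[ei - 1]
            add(
                "missense", ei, position=int(rng.integers(s0, e0)),
                panel_af=float(rng.uniform(0, 0.002)),
                cohort_af=float(rng.uniform(0, 0.002)),
                cadd=float(rng.uniform(10.0, 35.0)),
                helix=float(rng.uniform(0.05, 0.95)),
            )
        for i, v in enumerate(variants):
            v["variant_id"] = f"{gene}:v{i + 1:02d}"
        ann_rows.extend(variants)

        geno = np.zeros((n_samples, len(variants)), dtype=float)
        for j in range(len(variants)):
            k = int(rng.integers(1, 4))
            idx = rng.choice(n_samples, size=k, replace=False)
            geno[idx, j] = rng.choice([1, 1, 2], size=k)
        # sprinkle missing calls
        miss = rng.random(geno.shape) < 0.03
        geno[miss] = np.nan
        genotypes[gene] = pd.DataFrame(
            geno, index=pd.Index(samples, name="sample_id"),
            columns=[v["variant_id"] for v in variants],
        )

    annotations = pd.DataFrame(ann_rows)[
        ["variant_id", "gene_id", "consequence", "exon_index", "position",
         "panel_af", "cohort_af", "cadd", "helix"]
    ]
    return transcripts, annotations, genotypes


def simulate_gene_counts(
    n_genes: int,
    alpha: float,
    eta: float,
    n1: int,
    n0: int,
    carrier_freq: float = 1e-3,
    seed: int = 0,
) -> tuple[list, np.ndarray]:
    """Per-gene case/control carrier counts under the effect-size mixture.

    Gene effects come from :func:`draw_gene_effects`; each gene's control
    carrier frequency is ``carrier_freq`` and its case carrier frequency
    follows from the per-carrier odds ratio e^beta:
    q1 = q e^beta / (1 - q + q e^beta).  Returns the
    :class:`rvburden.frr.GeneCounts` list (genes with zero carriers overall
    are dropped, as they are invisible to any scan) and the true betas.
    """
    from .frr import GeneCounts

    rng = np.random.default_rng(seed)
    betas = draw_gene_effects(n_genes, alpha, eta, seed=int(rng.integers(2**31)))
    q = carrier_freq
    q1 = q * np.exp(betas) / (1.0 - q + q * np.exp(betas))
    a = rng.binomial(n1, q1)
    b = rng.binomial(n0, q, size=n_genes)
    counts = [
        GeneCounts(gene_id=f"G{i + 1:05d}", a=int(a[i]), b=int(b[i]), n1=n1, n0=n0)
        for i in range(n_genes)
        if a[i] + b[i] > 0
    ]
    return counts, betas


def null_gene_specs(
    n_genes: int,
    carrier_freq: float = 0.005,
    chrom: str = "1",
) -> tuple[GeneSpec, ...]:
    """Convenience: a block of null genes at a common carrier frequency."""
    return tuple(
        GeneSpec(gene_id=f"NULL{i + 1:05d}", carrier_freq=carrier_freq, chrom=chrom)
        for i in range(n_genes)
    )
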