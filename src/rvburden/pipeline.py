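"""End-to-end pipeline: simulate -> classify -> burden -> meta -> frr.

Every stage reads and writes TSV in the run directory, so any stage can be
re-run or replaced by external inputs.  Reruns with the same configuration
are byte-identical (floats are written at six significant digits); the run
manifest records the configuration hash, seed and a checksum per output.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import run_genome_scan
from .classify import Thresholds, classify_all, collapse_carriers, missingness_report
from .errors import PipelineError, ValidationError
from .frr import counts_from_scan, fit_eb, frr_percent, median_or
from .io import (
    read_annotations,
    read_transcripts,
    read_vcf_carriers,
    sha256_file,
    write_annotations,
    write_carriers,
    write_gene_counts,
    write_phenotypes,
    write_transcripts,
    write_tsv,
    write_vcf,
    write_yaml,
)
from .meta import export_ranked_list, inflation_lambda, meta_analyze, qq_data
from .simulate import (
    GeneSpec,
    SimConfig,
    StudySpec,
    simulate_annotated_variants,
    simulate_cohort,
)

ALL_STAGES = ("simulate", "classify", "burden", "meta", "frr")

#: covariate scheme per study style: consortium-style studies adjust for
#: country and library preparation; cohort-style studies for 10 PCs and sex.
COVARIATE_SCHEMES = {
    "consortium": ["country", "libprep"],
    "cohort": [f"PC{i}" for i in range(1, 11)] + ["sex"],
}


@dataclass
class StudyConfig:
    """One study's sampling design and covariate scheme."""

    label: str
    scheme: str = "cohort"  # key into COVARIATE_SCHEMES
    fh_oversample: float = 1.0
    young_oversample: float = 1.0
    male_control_fraction: float = 0.0
    libprep: str = "LP1"


@dataclass
class GeneConfig:
    gene_id: str
    carrier_freq: float
    log_or: float = 0.0
    sv_freq: float = 0.0
    chrom: str = "1"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_cases: int = 2000
    n_controls: int = 2000
    baseline_risk: float = 0.10
    fh_rate_noncarrier: float = 0.05
    genes: tuple[GeneConfig, ...] = ()
    studies: tuple[StudyConfig, ...] = (
        StudyConfig(label="CONSORTIUM", scheme="consortium",
                    fh_oversample=3.0, young_oversample=2.0, libprep="LP1"),
        StudyConfig(label="COHORT", scheme="cohort",
                    male_control_fraction=0.0, libprep="LP2"),
    )
    anchor_genes: tuple[str, ...] = ()
    reference_study: str = "COHORT"
    lambda_obs: float = 2.0
    af_max: float = 0.001
    cadd_min: float = 20.0
    helix_min: float = 0.5
    nmd_window: int = 50

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        data["genes"] = tuple(GeneConfig(**g) for g in data.get("genes", ()))
        data["studies"] = tuple(StudyConfig(**s) for s in data.get("studies", ()))
        data["stages"] = tuple(data.get("stages", ALL_STAGES))
        data["anchor_genes"] = tuple(data.get("anchor_genes", ()))
        return cls(**data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    version: str
    config_hash: str
    seed: int
    stages: list[str]
    checksums: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)
    skip_log: dict[str, list] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def demo_config(outdir: str, seed: int = 0) -> RunConfig:
    """A small two-study configuration exercising every stage."""
    genes = [
        GeneConfig("ANCHOR1", carrier_freq=0.01, log_or=float(np.log(2.5))),
        GeneConfig("RISK1", carrier_freq=0.005, log_or=float(np.log(3.0))),
        GeneConfig("RISK2", carrier_freq=0.008, log_or=float(np.log(1.8))),
        GeneConfig("XRISK", carrier_freq=0.008, log_or=float(np.log(2.0)), chrom="X"),
    ] + [
        GeneConfig(f"NULL{i:03d}", carrier_freq=0.006) for i in range(1, 61)
    ]
    return RunConfig(
        outdir=outdir,
        seed=seed,
        genes=tuple(genes),
        anchor_genes=("ANCHOR1",),
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages in order; returns the run manifest.

    Stage outputs are written to a temporary subdirectory and promoted on
    success, so a failed stage leaves its partial outputs quarantined under
    ``<outdir>/quarantine/<stage>/`` instead of mixed with good results.
    """
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # pre-flight: stages that consume another stage's outputs need them
    # present either from this run or a previous one
    order = [s for s in ALL_STAGES if s in config.stages]
    planned = set(order)
    requirements = {
        "classify": ["variants.vcf", "annotations.tsv", "transcripts.tsv"],
        "burden": ["phenotypes.tsv", "carriers.tsv"],
        "meta": [],
        "frr": [],
    }
    for stage in order:
        upstream = {"classify": "simulate", "burden": "simulate",
                    "meta": "burden", "frr": "burden"}.get(stage)
        if upstream and upstream not in planned:
            for name in requirements.get(stage, []):
                if not (outdir / name).exists():
                    raise ValidationError(
                        f"stage {stage!r} needs {name} (run {upstream!r} first)"
                    )

    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=order,
    )
    write_yaml(config.to_dict(), outdir / "config.yaml")
    state: dict = {}
    for stage in order:
        tmp = outdir / f".tmp_{stage}"
        if tmp.exists():
            shutil.rmtree(tmp)
        tmp.mkdir()
        try:
            outputs = _STAGES[stage](config, outdir, tmp, state)
        except Exception as exc:
            quarantine = outdir / "quarantine" / stage
            if quarantine.exists():
                shutil.rmtree(quarantine)
            quarantine.parent.mkdir(exist_ok=True)
            tmp.rename(quarantine)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        for name in outputs:
            target = outdir / name
            if target.exists():
                target.unlink()
            (tmp / name).rename(target)
            manifest.checksums[name] = sha256_file(target)
        shutil.rmtree(tmp)
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.checksums["config.yaml"] = sha256_file(outdir / "config.yaml")
    manifest.write(outdir / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, outdir: Path, tmp: Path, state: dict):
    specs = tuple(
        GeneSpec(
            gene_id=g.gene_id, carrier_freq=g.carrier_freq, log_or=g.log_or,
            sv_carrier_freq=g.sv_freq, chrom=g.chrom,
        )
        for g in config.genes
    )
    sim = SimConfig(
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        genes=specs,
        baseline_risk=config.baseline_risk,
        fh_rate_noncarrier=config.fh_rate_noncarrier,
        seed=config.seed,
        study_specs=tuple(
            StudySpec(
                label=s.label, fh_oversample=s.fh_oversample,
                young_oversample=s.young_oversample,
                male_control_fraction=s.male_control_fraction,
                libprep=s.libprep,
            )
            for s in config.studies
        ),
    )
    cohort = simulate_cohort(sim)
    state["cohort"] = cohort
    write_phenotypes(cohort.phenotypes, tmp / "phenotypes.tsv")
    write_carriers(cohort.carriers, tmp / "carriers.tsv")
    truth = pd.DataFrame(
        [
            {"gene_id": g, "carrier_freq": cf, "log_or": lo}
            for g, (cf, lo) in cohort.truth.items()
        ]
    )
    write_tsv(truth, tmp / "truth.tsv")
    transcripts, annotations, genotypes = simulate_annotated_variants(
        n_genes=5, seed=config.seed
    )
    state["toy"] = (transcripts, annotations, genotypes)
    write_transcripts(transcripts, tmp / "transcripts.tsv")
    write_annotations(annotations, tmp / "annotations.tsv")
    write_vcf(genotypes, tmp / "variants.vcf")
    return [
        "phenotypes.tsv", "carriers.tsv", "truth.tsv",
        "transcripts.tsv", "annotations.tsv", "variants.vcf",
    ]


def _stage_classify(config: RunConfig, outdir: Path, tmp: Path, state: dict):
    transcripts = read_transcripts(outdir / "transcripts.tsv")
    annotations = read_annotations(outdir / "annotations.tsv")
    genotypes = read_vcf_carriers(outdir / "variants.vcf")
    thresholds = Thresholds(
        af_max=config.af_max, cadd_min=config.cadd_min,
        helix_min=config.helix_min, nmd_window=config.nmd_window,
    )
    labels = classify_all(annotations, transcripts, thresholds)
    write_tsv(labels, tmp / "variant_classes.tsv")
    ptv_ids = {
        gene: grp.loc[grp["PTV"], "variant_id"].tolist()
        for gene, grp in labels.groupby("gene_id")
    }
    carriers = collapse_carriers(genotypes, "PTV", variant_ids=ptv_ids)
    write_carriers(carriers, tmp / "toy_ptv_carriers.tsv")
    write_tsv(missingness_report(genotypes), tmp / "missingness.tsv")
    return ["variant_classes.tsv", "toy_ptv_carriers.tsv", "missingness.tsv"]


def _stage_burden(config: RunConfig, outdir: Path, tmp: Path, state: dict):
    cohort = state.get("cohort")
    if cohort is None:
        from .io import read_carriers, read_phenotypes

        phenotypes = read_phenotypes(outdir / "phenotypes.tsv")
        gene_chroms = {g.gene_id: g.chrom for g in config.genes}
        carriers = read_carriers(outdir / "carriers.tsv", gene_chroms=gene_chroms)
    else:
        phenotypes, carriers = cohort.phenotypes, cohort.carriers
    outputs = []
    scans = {}
    for study in config.studies:
        mask = (phenotypes["study"] == study.label).to_numpy()
        pheno = phenotypes.loc[mask].reset_index(drop=True)
        sub = type(carriers)(
            samples=pheno["sample_id"].tolist(),
            genes=carriers.genes,
            variant_class=carriers.variant_class,
            matrix=carriers.matrix[mask],
            gene_chroms=carriers.gene_chroms,
        )
        covariates = COVARIATE_SCHEMES[study.scheme]
        results = run_genome_scan(sub, pheno, covariates)
        scans[study.label] = results
        name = f"burden_{study.label}.tsv"
        write_tsv(results, tmp / name)
        outputs.append(name)
        skips = pd.DataFrame(
            results.attrs["skipped"], columns=["gene_id", "reason"]
        )
        skip_name = f"burden_{study.label}_skipped.tsv"
        write_tsv(skips, tmp / skip_name)
        outputs.append(skip_name)
    state["scans"] = scans
    state["phenotypes"], state["carriers"] = phenotypes, carriers
    return outputs


def _stage_meta(config: RunConfig, outdir: Path, tmp: Path, state: dict):
    scans = state.get("scans")
    if scans is None:
        from .io import read_tsv

        scans = {
            s.label: read_tsv(outdir / f"burden_{s.label}.tsv")
            for s in config.studies
        }
    anchors = config.anchor_genes or ()
    if not anchors:
        raise ValidationError("meta stage requires anchor_genes in the config")
    meta = meta_analyze(scans, anchors, config.reference_study)
    weights = meta.attrs["weights"]
    meta = meta.copy()
    for study, w in weights.items():
        meta[f"weight_{study}"] = w
    write_tsv(meta, tmp / "meta.tsv")
    write_tsv(export_ranked_list(meta), tmp / "ranked_genes.tsv")
    write_tsv(qq_data(meta["p"]), tmp / "qq_data.tsv")
    lam = inflation_lambda(meta["z_m"])
    write_tsv(
        pd.DataFrame([{"statistic": "inflation_lambda", "value": lam}]),
        tmp / "diagnostics.tsv",
    )
    state["meta"] = meta
    return ["meta.tsv", "ranked_genes.tsv", "qq_data.tsv", "diagnostics.tsv"]


def _stage_frr(config: RunConfig, outdir: Path, tmp: Path, state: dict):
    phenotypes, carriers = state.get("phenotypes"), state.get("carriers")
    if phenotypes is None or carriers is None:
        from .io import read_carriers, read_phenotypes

        phenotypes = read_phenotypes(outdir / "phenotypes.tsv")
        carriers = read_carriers(outdir / "carriers.tsv")
    sv_freqs = {g.gene_id: g.sv_freq for g in config.genes}
    counts = counts_from_scan(
        carriers.matrix, phenotypes["d"].to_numpy(), carriers.genes, sv_freqs
    )
    counts = [c for c in counts if c.a + c.b >= 1]
    write_gene_counts(counts, tmp / "gene_counts.tsv")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # small demo gene sets
        fit = fit_eb(counts, lambda_obs=config.lambda_obs)
    write_tsv(fit.genes, tmp / "frr_per_gene.tsv")
    summary = {
        "alpha": fit.prior.alpha,
        "eta": fit.prior.eta,
        "median_or": median_or(fit.prior),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "frr_percent_total": frr_percent(fit, lambda_obs=config.lambda_obs),
        "lambda_obs": config.lambda_obs,
    }
    (tmp / "frr_fit.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return ["gene_counts.tsv", "frr_per_gene.tsv", "frr_fit.json"]


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "burden": _stage_burden,
    "meta": _stage_meta,
    "frr": _stage_frr,
}
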