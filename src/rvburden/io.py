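"""Readers and writers for the interchange formats.

TSV with mandatory headers is the canonical interchange format; VCF is
supported for genotype ingestion (GT fields only, via cyvcf2) and a minimal
GT-only VCF writer exists for round-trip testing.  Exon tables are BED-like:
0-based half-open coordinates.  Floating-point output is fixed at six
significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import CarrierTable, TranscriptModel, VariantAnnotation
from .errors import ValidationError
from .frr import GeneCounts

FLOAT_FORMAT = "%.6g"


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- phenotypes -------------------------------------------------------------

def write_phenotypes(frame: pd.DataFrame, path: str | Path) -> None:
    write_tsv(frame, path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "d", "f"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"phenotype table lacks columns {sorted(missing)}")
    return frame


# --- carrier tables ---------------------------------------------------------

def write_carriers(table: CarrierTable, path: str | Path) -> None:
    write_tsv(table.to_frame(), path, index=True)


def read_carriers(
    path: str | Path,
    variant_class: str = "PTV",
    gene_chroms: Mapping[str, str] | None = None,
) -> CarrierTable:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CarrierTable.from_frame(frame, variant_class, gene_chroms)


# --- transcripts (BED-like exon table) --------------------------------------

def write_transcripts(
    transcripts: Mapping[str, TranscriptModel], path: str | Path
) -> None:
    rows = []
    for t in transcripts.values():
        for rank, (start, end) in enumerate(t.exons, start=1):
            rows.append(
                {
                    "gene_id": t.gene_id, "strand": t.strand,
                    "exon_rank": rank, "start": start, "end": end,
                }
            )
    write_tsv(pd.DataFrame(rows), path)


def read_transcripts(path: str | Path) -> dict[str, TranscriptModel]:
    frame = read_tsv(path)
    out: dict[str, TranscriptModel] = {}
    for gene, grp in frame.groupby("gene_id", sort=False):
        grp = grp.sort_values("exon_rank")
        out[str(gene)] = TranscriptModel(
            gene_id=str(gene),
            strand=str(grp["strand"].iloc[0]),
            exons=tuple(
                (int(r.start), int(r.end)) for r in grp.itertuples()
            ),
        )
    return out


# --- variant annotations ----------------------------------------------------

def write_annotations(frame: pd.DataFrame, path: str | Path) -> None:
    write_tsv(frame, path)


def read_annotations(path: str | Path) -> list[VariantAnnotation]:
    frame = read_tsv(path)
    out = []
    for rec in frame.to_dict("records"):
        out.append(
            VariantAnnotation(
                variant_id=str(rec["variant_id"]),
                gene_id=str(rec["gene_id"]),
                consequence=None if pd.isna(rec["consequence"]) else str(rec["consequence"]),
                exon_index=None if pd.isna(rec.get("exon_index")) else int(rec["exon_index"]),
                position=None if pd.isna(rec.get("position")) else int(rec["position"]),
                panel_af=float(rec.get("panel_af", 0.0)),
                cohort_af=float(rec.get("cohort_af", 0.0)),
                cadd=None if pd.isna(rec.get("cadd")) else float(rec["cadd"]),
                helix=None if pd.isna(rec.get("helix")) else float(rec["helix"]),
            )
        )
    return out


# --- gene counts ------------------------------------------------------------

def write_gene_counts(counts: Sequence[GeneCounts], path: str | Path) -> None:
    write_tsv(
        pd.DataFrame(
            [
                {"gene_id": c.gene_id, "a": c.a, "b": c.b,
                 "n1": c.n1, "n0": c.n0, "sv_freq": c.sv_freq}
                for c in counts
            ]
        ),
        path,
    )


def read_gene_counts(path: str | Path) -> list[GeneCounts]:
    frame = read_tsv(path)
    return [
        GeneCounts(
            gene_id=str(r.gene_id), a=int(r.a), b=int(r.b),
            n1=int(r.n1), n0=int(r.n0), sv_freq=float(r.sv_freq),
        )
        for r in frame.itertuples()
    ]


# --- VCF --------------------------------------------------------------------

def write_vcf(
    genotypes: Mapping[str, pd.DataFrame],
    path: str | Path,
    gene_chroms: Mapping[str, str] | None = None,
) -> None:
    """Write a minimal GT-only VCF, one record per variant, gene in INFO.

    Allele counts 0/1/2 become 0/0, 0/1, 1/1; NaN becomes ./. — sufficient
    for round-trip tests, not a general-purpose VCF emitter.
    """
    gene_chroms = gene_chroms or {}
    sample_index = None
    for table in genotypes.values():
        if sample_index is None:
            sample_index = list(table.index)
        elif list(table.index) != sample_index:
            raise ValidationError("sample order differs between genes")
    if sample_index is None:
        raise ValidationError("no genotypes to write")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = sorted({gene_chroms.get(g, "1") for g in genotypes})
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_index)
    )
    pos = 0
    for gene, table in genotypes.items():
        chrom = gene_chroms.get(gene, "1")
        for variant in table.columns:
            pos += 10
            calls = [
                "./." if np.isnan(v) else gt_map[float(v)]
                for v in table[variant].to_numpy(dtype=float)
            ]
            lines.append(
                f"{chrom}\t{pos}\t{variant}\tA\tT\t.\tPASS\tGENE={gene}\tGT\t"
                + "\t".join(calls)
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_carriers(
    path: str | Path,
    sample_filter: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Read GT-only genotypes from a VCF, keyed by the GENE INFO tag.

    Returns gene -> samples x variants allele-count table with NaN for
    missing calls.  Multi-allelic records must be pre-split.  Variants
    without a GENE tag are grouped under their ID's prefix before ':' if
    present, otherwise rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if sample_filter is not None:
        unknown = set(sample_filter) - set(samples)
        if unknown:
            raise ValidationError(f"unknown samples requested: {sorted(unknown)[:5]}")
    per_gene: dict[str, dict[str, np.ndarray]] = {}
    for record in vcf:
        gene = record.INFO.get("GENE")
        if gene is None:
            vid = record.ID or ""
            if ":" in vid:
                gene = vid.split(":", 1)[0]
            else:
                raise ValidationError(
                    f"variant at {record.CHROM}:{record.POS} lacks a GENE tag"
                )
        # gts012: 0/1/2 = alt allele count, 3 = missing
        counts = record.gt_types.astype(float)
        counts[counts == 3] = np.nan
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        per_gene.setdefault(gene, {})[vid] = counts
    out = {}
    for gene, cols in per_gene.items():
        frame = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
        if sample_filter is not None:
            frame = frame.loc[list(sample_filter)]
        out[gene] = frame
    return out


# --- config / manifest helpers ---------------------------------------------

def read_yaml(path: str | Path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(obj, handle, sort_keys=True)


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()
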