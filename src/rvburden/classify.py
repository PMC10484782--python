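"""Variant classification and per-gene carrier collapsing.

Variants are assigned to burden categories — protein-truncating variants
(PTVs) subject to a nonsense-mediated-decay (NMD) escape rule, rare missense
variants under a dual allele-frequency filter, and predicted-deleterious
missense tiers defined by CADD and Helix score thresholds.  Per-sample
genotypes are then collapsed to a single 0/1 carrier indicator per gene:
a sample carries the gene if it carries at least one qualifying variant,
heterozygous and homozygous carriers combined.

Coordinates are 0-based half-open throughout, with exons ordered 5'->3' in
the coding direction of the transcript.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, UndefinedEstimateError, ValidationError

#: Consequence terms counted as protein-truncating.
PTV_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_donor", "splice_acceptor"}
)


class VariantClass(str, enum.Enum):
    """Burden categories a variant may belong to (possibly several)."""

    PTV = "PTV"
    RARE_MISSENSE = "RARE_MISSENSE"
    DELETERIOUS_MISSENSE_CADD = "DELETERIOUS_MISSENSE_CADD"
    DELETERIOUS_MISSENSE_HELIX = "DELETERIOUS_MISSENSE_HELIX"
    OTHER = "OTHER"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds.

    af_max
        Rare-missense allele-frequency cutoff, applied strictly (< af_max)
        to both the reference-panel AF and the cohort AF.
    cadd_min
        Phred-scaled CADD cutoff for the deleterious tier (>= cadd_min).
    helix_min
        Helix score cutoff for the deleterious tier (> helix_min).
    nmd_window
        Size in bases of the 3' window of the penultimate exon within which
        a PTV is predicted to escape NMD (inclusive of the boundary base).
    """

    af_max: float = 0.001
    cadd_min: float = 20.0
    helix_min: float = 0.5
    nmd_window: int = 50

    def __post_init__(self):
        if not (0 < self.af_max <= 1):
            raise ValidationError("af_max must be in (0, 1]")
        if self.cadd_min < 0 or not (0 <= self.helix_min <= 1):
            raise ValidationError("cadd_min must be >= 0 and helix_min in [0, 1]")
        if self.nmd_window < 0:
            raise ValidationError("nmd_window must be non-negative")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript per gene: ordered exons in transcript-forward coordinates.

    ``exons`` are (start, end) pairs, 0-based half-open, strictly ordered
    5'->3' in the coding direction; for a minus-strand gene the caller is
    expected to have already flipped genomic coordinates into this frame.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValidationError("transcript needs at least one exon")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(f"empty exon ({start}, {end})")
            if start < prev_end:
                raise ValidationError("exons must be non-overlapping and ordered 5'->3'")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class VariantAnnotation:
    """VEP-like annotation record for a single variant."""

    variant_id: str
    gene_id: str
    consequence: str | None
    exon_index: int | None = None  # 1-based
    position: int | None = None  # 0-based transcript-forward coordinate
    panel_af: float = 0.0
    cohort_af: float = 0.0
    cadd: float | None = None
    helix: float | None = None

    def __post_init__(self):
        for name in ("panel_af", "cohort_af"):
            af = getattr(self, name)
            if not (0 <= af <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {af}")


def is_nmd_escaping(
    variant: VariantAnnotation,
    transcript: TranscriptModel,
    window: int = 50,
) -> bool:
    """Predict whether a truncating variant escapes nonsense-mediated decay.

    A PTV escapes NMD if it falls in the last exon of the transcript, or in
    the final ``window`` bases of the penultimate exon (boundary inclusive:
    the base exactly ``window`` bases from the penultimate exon's 3' end
    still escapes).  Single-exon transcripts escape everywhere — their only
    exon is the last exon.

    The distance of a variant at 0-based position ``pos`` within an exon
    ``[start, end)`` from the exon's 3' end is ``end - pos`` (the last base
    of the exon has distance 1).
    """
    if variant.gene_id != transcript.gene_id:
        raise AnnotationError(
            f"variant {variant.variant_id} annotated to {variant.gene_id}, "
            f"not {transcript.gene_id}"
        )
    if variant.exon_index is None or variant.position is None:
        raise AnnotationError(
            f"variant {variant.variant_id} lacks exon_index/position annotation"
        )
    n = transcript.n_exons
    if not (1 <= variant.exon_index <= n):
        raise AnnotationError(
            f"variant {variant.variant_id}: exon index {variant.exon_index} "
            f"outside 1..{n}"
        )
    start, end = transcript.exons[variant.exon_index - 1]
    if not (start <= variant.position < end):
        raise AnnotationError(
            f"variant {variant.variant_id} at {variant.position} falls outside "
            f"exon {variant.exon_index} [{start}, {end})"
        )
    if n == 1 or variant.exon_index == n:
        return True
    if variant.exon_index == n - 1:
        return (end - variant.position) <= window
    return False


def classify_variant(
    variant: VariantAnnotation,
    transcript: TranscriptModel,
    thresholds: Thresholds = Thresholds(),
) -> set[VariantClass]:
    """Assign a variant to its burden categories.

    A truncating consequence yields ``{PTV}`` unless the variant is
    predicted to escape NMD, in which case it is excluded (``{OTHER}``).
    A missense variant is ``RARE_MISSENSE`` only if its allele frequency is
    below ``af_max`` in *both* the reference panel and the analysis cohort;
    the deleterious tiers additionally require CADD >= ``cadd_min`` or
    Helix > ``helix_min``.  Everything else is ``OTHER``.
    """
    if variant.consequence is None:
        raise AnnotationError(f"variant {variant.variant_id} has no consequence")
    cons = variant.consequence
    if cons in PTV_CONSEQUENCES:
        if is_nmd_escaping(variant, transcript, window=thresholds.nmd_window):
            return {VariantClass.OTHER}
        return {VariantClass.PTV}
    if cons == "missense":
        rare = (
            variant.panel_af < thresholds.af_max
            and variant.cohort_af < thresholds.af_max
        )
        if not rare:
            return {VariantClass.OTHER}
        labels = {VariantClass.RARE_MISSENSE}
        if variant.cadd is not None and variant.cadd >= thresholds.cadd_min:
            labels.add(VariantClass.DELETERIOUS_MISSENSE_CADD)
        if variant.helix is not None and variant.helix > thresholds.helix_min:
            labels.add(VariantClass.DELETERIOUS_MISSENSE_HELIX)
        return labels
    return {VariantClass.OTHER}


@dataclass
class CarrierTable:
    """Per-sample, per-gene 0/1 carrier indicators for one variant class."""

    samples: list[str]
    genes: list[str]
    variant_class: str
    matrix: np.ndarray  # shape (n_samples, n_genes), dtype int8
    gene_chroms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.samples), len(self.genes)):
            raise ValidationError(
                f"carrier matrix shape {self.matrix.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("carrier indicators must be 0/1")

    def carrier_counts(self) -> pd.Series:
        """Number of carriers per gene (column sums)."""
        return pd.Series(
            self.matrix.sum(axis=0), index=pd.Index(self.genes, name="gene_id"),
            name="n_carriers",
        )

    def column(self, gene_id: str) -> np.ndarray:
        return self.matrix[:, self.genes.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.samples, name="sample_id"),
            columns=self.genes,
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, variant_class: str = "PTV",
        gene_chroms: Mapping[str, str] | None = None,
    ) -> "CarrierTable":
        return cls(
            samples=list(frame.index.astype(str)),
            genes=list(frame.columns.astype(str)),
            variant_class=variant_class,
            matrix=frame.to_numpy(dtype=np.int8),
            gene_chroms=dict(gene_chroms or {}),
        )


def collapse_carriers(
    genotypes: Mapping[str, pd.DataFrame],
    variant_class: str = "PTV",
    variant_ids: Mapping[str, Sequence[str]] | None = None,
    gene_chroms: Mapping[str, str] | None = None,
) -> CarrierTable:
    """Collapse per-variant allele counts into per-gene carrier indicators.

    ``genotypes`` maps gene -> samples x variants table of minor-allele
    counts in {0, 1, 2} with NaN for missing calls.  A sample is a carrier
    (G_i = 1) if it carries at least one allele of any qualifying variant;
    missing genotypes count as non-carrier.  ``variant_ids`` optionally
    restricts each gene to the listed variant columns (e.g. the output of
    :func:`classify_variant` for one class); genes whose restriction leaves
    no variants yield an all-zero column.

    Collapsing is idempotent: applying it to an already-collapsed 0/1 table
    reproduces that table.
    """
    if not genotypes:
        raise ValidationError("no genes to collapse")
    sample_index = None
    columns = {}
    for gene, table in genotypes.items():
        if sample_index is None:
            sample_index = table.index
        elif not table.index.equals(sample_index):
            raise ValidationError(f"gene {gene}: sample set differs between genes")
        if variant_ids is not None:
            keep = [v for v in variant_ids.get(gene, []) if v in table.columns]
            table = table[keep]
        values = table.to_numpy(dtype=float)
        if values.size and np.nanmax(np.nan_to_num(values)) > 2:
            raise ValidationError(f"gene {gene}: allele counts must be in 0..2")
        if values.shape[1] == 0:
            columns[gene] = np.zeros(len(sample_index), dtype=np.int8)
        else:
            columns[gene] = (np.nansum(values, axis=1) > 0).astype(np.int8)
    matrix = np.column_stack([columns[g] for g in genotypes])
    return CarrierTable(
        samples=list(sample_index.astype(str)),
        genes=list(genotypes),
        variant_class=variant_class,
        matrix=matrix,
        gene_chroms=dict(gene_chroms or {}),
    )


def cohort_af(
    genotypes: pd.DataFrame,
    sample_filter: np.ndarray | pd.Series | None = None,
) -> pd.Series:
    """Per-variant allele frequency in the analysis cohort.

    Allele counts are summed over non-missing genotypes and divided by
    2 x (number of non-missing samples).  For genes on chromosome X the
    caller passes a female-only ``sample_filter`` so the denominator counts
    female samples only.
    """
    table = genotypes
    if sample_filter is not None:
        mask = np.asarray(sample_filter, dtype=bool)
        if mask.shape[0] != len(table):
            raise ValidationError("sample_filter length does not match samples")
        table = table.loc[mask]
    values = table.to_numpy(dtype=float)
    non_missing = (~np.isnan(values)).sum(axis=0)
    if (non_missing == 0).any():
        bad = table.columns[non_missing == 0].tolist()
        raise UndefinedEstimateError(f"all genotypes missing for variants {bad}")
    af = np.nansum(values, axis=0) / (2.0 * non_missing)
    return pd.Series(af, index=table.columns, name="cohort_af")


def missingness_report(genotypes: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene fraction of missing genotype calls.

    Missing calls are collapsed as non-carriers, so genes with substantial
    missingness can produce spurious carrier-frequency differences between
    batches; this report makes such artifacts detectable.
    """
    rows = []
    for gene, table in genotypes.items():
        values = table.to_numpy(dtype=float)
        total = values.size
        missing = int(np.isnan(values).sum()) if total else 0
        rows.append(
            {
                "gene_id": gene,
                "n_variants": table.shape[1],
                "n_calls": total,
                "n_missing": missing,
                "missing_fraction": (missing / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def classify_all(
    annotations: Iterable[VariantAnnotation],
    transcripts: Mapping[str, TranscriptModel],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Classify every annotated variant against its gene's transcript.

    Returns a tidy table with one row per variant and one boolean column per
    burden category.
    """
    rows = []
    for variant in annotations:
        transcript = transcripts.get(variant.gene_id)
        if transcript is None:
            raise AnnotationError(f"no transcript for gene {variant.gene_id}")
        labels = classify_variant(variant, transcript, thresholds)
        rows.append(
            {
                "variant_id": variant.variant_id,
                "gene_id": variant.gene_id,
                "consequence": variant.consequence,
                **{cls.value: cls in labels for cls in VariantClass},
            }
        )
    return pd.DataFrame(rows)
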