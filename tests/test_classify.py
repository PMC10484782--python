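"""Variant classification: NMD-escape rule, threshold edges, collapsing."""

import itertools

import numpy as np
import pandas as pd
import pytest

import rvburden as rv
from rvburden.classify import PTV_CONSEQUENCES, missingness_report
from rvburden.errors import AnnotationError, UndefinedEstimateError, ValidationError


def ptv(transcript, exon_index, position, consequence="stop_gained"):
    return rv.VariantAnnotation(
        variant_id=f"{transcript.gene_id}:{exon_index}:{position}",
        gene_id=transcript.gene_id,
        consequence=consequence,
        exon_index=exon_index,
        position=position,
    )


class TestNmdEscape:
    def test_last_exon_always_escapes(self, five_exon_transcript):
        t = five_exon_transcript
        start, end = t.exons[-1]
        for pos in (start, (start + end) // 2, end - 1):
            assert rv.is_nmd_escaping(ptv(t, 5, pos), t)

    def test_interior_exons_never_escape(self, five_exon_transcript):
        t = five_exon_transcript
        for idx in (1, 2, 3):
            start, end = t.exons[idx - 1]
            assert not rv.is_nmd_escaping(ptv(t, idx, start), t)
            assert not rv.is_nmd_escaping(ptv(t, idx, end - 1), t)

    def test_penultimate_window_brute_force_scan(self, five_exon_transcript):
        """Every position of the penultimate exon, against the distance rule
        computed independently from exon coordinates."""
        t = five_exon_transcript
        start, end = t.exons[3]
        for pos in range(start, end):
            distance_to_3prime = end - pos  # last base has distance 1
            expected = distance_to_3prime <= 50
            assert rv.is_nmd_escaping(ptv(t, 4, pos), t) is expected

    def test_boundary_50_inclusive_51_exclusive(self, five_exon_transcript):
        t = five_exon_transcript
        _, end = t.exons[3]
        assert rv.is_nmd_escaping(ptv(t, 4, end - 50), t)
        assert not rv.is_nmd_escaping(ptv(t, 4, end - 51), t)

    def test_single_exon_transcript_escapes_everywhere(self):
        t = rv.TranscriptModel("MONO", "+", ((0, 300),))
        for pos in (0, 150, 299):
            assert rv.is_nmd_escaping(ptv(t, 1, pos), t)

    def test_position_outside_exon_is_annotation_error(self, five_exon_transcript):
        t = five_exon_transcript
        with pytest.raises(AnnotationError):
            rv.is_nmd_escaping(ptv(t, 4, 250), t)  # intronic position

    def test_missing_annotation_fields_rejected(self, five_exon_transcript):
        t = five_exon_transcript
        bad = rv.VariantAnnotation("x", "G5EX", "stop_gained", exon_index=None,
                                   position=None)
        with pytest.raises(AnnotationError):
            rv.is_nmd_escaping(bad, t)

    def test_wrong_gene_rejected(self, five_exon_transcript):
        other = rv.VariantAnnotation("x", "OTHER", "stop_gained", 1, 0)
        with pytest.raises(AnnotationError):
            rv.is_nmd_escaping(other, five_exon_transcript)


def missense(transcript, panel_af, cohort_af, cadd=None, helix=None):
    start, _ = transcript.exons[1]
    return rv.VariantAnnotation(
        variant_id="m", gene_id=transcript.gene_id, consequence="missense",
        exon_index=2, position=start + 1,
        panel_af=panel_af, cohort_af=cohort_af, cadd=cadd, helix=helix,
    )


class TestClassifyVariant:
    @pytest.mark.parametrize("consequence", sorted(PTV_CONSEQUENCES))
    def test_truncating_in_interior_exon_is_ptv(self, five_exon_transcript, consequence):
        v = ptv(five_exon_transcript, 2, 310, consequence)
        assert rv.classify_variant(v, five_exon_transcript) == {rv.VariantClass.PTV}

    def test_truncating_in_last_exon_is_excluded(self, five_exon_transcript):
        v = ptv(five_exon_transcript, 5, 1250)
        assert rv.classify_variant(v, five_exon_transcript) == {rv.VariantClass.OTHER}

    @pytest.mark.parametrize(
        "panel_af,cohort_af,cadd,helix,expected",
        [
            # both AFs below 0.001, CADD >= 20: rare + deleterious (CADD)
            (5e-4, 5e-4, 25.0, None,
             {rv.VariantClass.RARE_MISSENSE, rv.VariantClass.DELETERIOUS_MISSENSE_CADD}),
            # fails the dual filter on the cohort side
            (5e-4, 2e-3, 30.0, 0.9, {rv.VariantClass.OTHER}),
            # fails on the panel side
            (2e-3, 5e-4, 30.0, 0.9, {rv.VariantClass.OTHER}),
            # AF exactly 0.001 is not rare (strict <)
            (1e-3, 5e-4, 25.0, None, {rv.VariantClass.OTHER}),
            # CADD exactly 20 qualifies (>=), Helix exactly 0.5 does not (>)
            (5e-4, 5e-4, 20.0, 0.5,
             {rv.VariantClass.RARE_MISSENSE, rv.VariantClass.DELETERIOUS_MISSENSE_CADD}),
            # Helix just above 0.5 qualifies, CADD just below 20 does not
            (5e-4, 5e-4, 19.9, 0.51,
             {rv.VariantClass.RARE_MISSENSE, rv.VariantClass.DELETERIOUS_MISSENSE_HELIX}),
            # rare but neither score: rare missense only
            (5e-4, 5e-4, 10.0, 0.1, {rv.VariantClass.RARE_MISSENSE}),
        ],
    )
    def test_missense_thresholds(self, five_exon_transcript, panel_af, cohort_af,
                                 cadd, helix, expected):
        v = missense(five_exon_transcript, panel_af, cohort_af, cadd, helix)
        assert rv.classify_variant(v, five_exon_transcript) == expected

    def test_deleterious_tiers_are_subsets_of_rare_missense(self, five_exon_transcript):
        labels = rv.classify_variant(
            missense(five_exon_transcript, 5e-4, 5e-4, 25.0, 0.9),
            five_exon_transcript,
        )
        assert rv.VariantClass.RARE_MISSENSE in labels

    def test_missing_consequence_is_annotation_error(self, five_exon_transcript):
        v = rv.VariantAnnotation("x", "G5EX", None, 1, 0)
        with pytest.raises(AnnotationError):
            rv.classify_variant(v, five_exon_transcript)

    def test_monotone_in_af_and_cadd_thresholds(self, five_exon_transcript):
        """Relaxing af_max can only grow the rare set; raising cadd_min can
        only shrink the deleterious set."""
        rng = np.random.default_rng(5)
        variants = [
            missense(five_exon_transcript, rng.uniform(0, 2e-3),
                     rng.uniform(0, 2e-3), rng.uniform(10, 35))
            for _ in range(50)
        ]

        def labelled(thresholds, cls):
            return {
                i for i, v in enumerate(variants)
                if cls in rv.classify_variant(v, five_exon_transcript, thresholds)
            }

        loose = rv.Thresholds(af_max=0.0015)
        tight = rv.Thresholds(af_max=0.0005)
        assert labelled(tight, rv.VariantClass.RARE_MISSENSE) <= labelled(
            loose, rv.VariantClass.RARE_MISSENSE
        )
        low = rv.Thresholds(cadd_min=15.0)
        high = rv.Thresholds(cadd_min=25.0)
        assert labelled(high, rv.VariantClass.DELETERIOUS_MISSENSE_CADD) <= labelled(
            low, rv.VariantClass.DELETERIOUS_MISSENSE_CADD
        )


class TestCollapseCarriers:
    def test_hom_and_het_both_carry(self, toy_genotypes):
        table = rv.collapse_carriers({"G": toy_genotypes})
        assert table.column("G").tolist() == [1, 0, 1, 0]

    def test_exhaustive_two_variant_patterns(self):
        """All 16 (value1, value2) patterns over {0, 1, 2, missing}: carrier
        iff any non-missing count is positive."""
        values = [0.0, 1.0, 2.0, np.nan]
        rows = list(itertools.product(values, values))
        frame = pd.DataFrame(
            rows, columns=["v1", "v2"],
            index=pd.Index([f"s{i}" for i in range(len(rows))], name="sample_id"),
        )
        got = rv.collapse_carriers({"G": frame}).column("G")
        expected = [
            int(any(not np.isnan(v) and v > 0 for v in row)) for row in rows
        ]
        assert got.tolist() == expected

    def test_empty_variant_set_gives_zero_column(self, toy_genotypes):
        table = rv.collapse_carriers(
            {"G": toy_genotypes}, variant_ids={"G": []}
        )
        assert table.column("G").sum() == 0

    def test_idempotent(self, toy_genotypes):
        once = rv.collapse_carriers({"G": toy_genotypes})
        twice = rv.collapse_carriers({"G": once.to_frame()[["G"]].rename(columns={"G": "c"})})
        assert np.array_equal(once.matrix, twice.matrix)

    def test_carrier_counts_are_column_sums(self, toy_genotypes):
        table = rv.collapse_carriers({"G": toy_genotypes})
        assert table.carrier_counts()["G"] == table.matrix.sum()


class TestCohortAf:
    def make(self, n, het=0, hom=0, missing=0):
        col = np.zeros(n)
        col[:het] = 1.0
        col[het:het + hom] = 2.0
        col[n - missing:] = np.nan
        return pd.DataFrame({"v": col},
                            index=pd.Index([f"s{i}" for i in range(n)],
                                           name="sample_id"))

    def test_one_het_in_1000(self):
        assert rv.cohort_af(self.make(1000, het=1))["v"] == pytest.approx(0.0005)

    def test_one_hom_in_1000(self):
        assert rv.cohort_af(self.make(1000, hom=1))["v"] == pytest.approx(0.001)

    def test_missing_shrinks_denominator(self):
        # 2 het among 1000 samples but 500 missing calls -> 2 / (2 * 500)
        assert rv.cohort_af(self.make(1000, het=2, missing=500))["v"] == pytest.approx(0.002)

    def test_all_missing_is_error(self):
        with pytest.raises(UndefinedEstimateError):
            rv.cohort_af(self.make(5, missing=5))

    def test_female_only_denominator_via_filter(self):
        frame = self.make(10, het=1)
        females = np.array([True] * 5 + [False] * 5)
        assert rv.cohort_af(frame, sample_filter=females)["v"] == pytest.approx(0.1)

    def test_filter_length_mismatch(self):
        with pytest.raises(ValidationError):
            rv.cohort_af(self.make(4), sample_filter=np.array([True]))


def test_missingness_report(toy_genotypes):
    report = missingness_report({"G": toy_genotypes}).set_index("gene_id")
    assert report.loc["G", "n_missing"] == 3
    assert report.loc["G", "missing_fraction"] == pytest.approx(3 / 12)


def test_transcript_validation():
    with pytest.raises(ValidationError):
        rv.TranscriptModel("bad", "+", ((0, 100), (50, 150)))  # overlap
    with pytest.raises(ValidationError):
        rv.TranscriptModel("bad", "+", ((10, 10),))  # empty exon
    with pytest.raises(ValidationError):
        rv.TranscriptModel("bad", "*", ((0, 100),))  # bad strand
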