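"""Catalog parsing, classification and gene/arm rollups."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from pcriterion import (
    VariantClass,
    VariantRecord,
    allele_diff,
    classify_variant,
    odds_ratio_from_freqs,
    parse_cytoband,
    read_catalog,
    summarize_catalog,
    write_catalog,
)
from pcriterion.catalog import CatalogSchemaError


def make_record(gene="G1", variant_id="rsX", location="1p36.1",
                mA=0.3, mU=0.28, **kw):
    return VariantRecord(
        gene=gene, variant_id=variant_id, location=location,
        allele_minor="A", allele_major="G", risk_allele="A",
        freq_cases=mA, freq_controls=mU, **kw,
    )


class TestParseCytoband:
    @pytest.mark.parametrize(
        "location, chrom, arm, sub",
        [
            ("1p36.22", "1", "p", "36.22"),
            ("10q26.11", "10", "q", "26.11"),
            ("Xq28", "X", "q", "28"),
            ("8p12", "8", "p", "12"),
            ("2q13", "2", "q", "13"),
        ],
    )
    def test_splits_at_first_arm_letter(self, location, chrom, arm, sub):
        band = parse_cytoband(location)
        assert (band.chromosome, band.arm, band.sub_band) == (chrom, arm, sub)
        assert str(band) == location
        assert band.arm_label == chrom + arm

    @pytest.mark.parametrize("bad", ["", "36.22", "23p11", "1r36", "0p1"])
    def test_invalid_locations_raise(self, bad):
        with pytest.raises(ValueError):
            parse_cytoband(bad)


class TestAlleleDiffAndClassify:
    def test_d_computed_from_frequencies(self):
        assert allele_diff(make_record(mA=0.3532, mU=0.3211)) == pytest.approx(0.0321)
        assert allele_diff(make_record(mA=0.7943, mU=0.8058)) == pytest.approx(-0.0115)
        assert allele_diff(make_record(mA=0.4, mU=0.4)) == 0.0

    def test_boundary_variants_against_unrounded_nu(self, nu_highest):
        """d=0.0176 sits just under nu~0.0176219; d=0.0179 just over."""
        assert classify_variant(0.4920 - 0.4744, nu_highest) is VariantClass.MEETS
        assert classify_variant(0.3106 - 0.2927, nu_highest) is VariantClass.EXCEEDS
        assert classify_variant(-0.0115, nu_highest) is VariantClass.NONPOSITIVE

    def test_tie_with_nu_is_exceeds(self, nu_highest):
        assert classify_variant(nu_highest.nu, nu_highest) is VariantClass.EXCEEDS

    def test_zero_d_is_nonpositive(self, nu_highest):
        assert classify_variant(0.0, nu_highest) is VariantClass.NONPOSITIVE

    @settings(derandomize=True, max_examples=200)
    @given(
        d=st.floats(-0.5, 0.5),
        nu_small=st.floats(1e-6, 0.1),
        factor=st.floats(1.0, 10.0),
    )
    def test_raising_nu_never_demotes_meets(self, d, nu_small, factor):
        """Monotonicity: a MEETS variant stays MEETS when nu grows."""
        before = classify_variant(d, nu_small)
        after = classify_variant(d, nu_small * factor)
        if before is VariantClass.MEETS:
            assert after is VariantClass.MEETS
        classes = {before, after}
        assert classes <= {VariantClass.MEETS, VariantClass.EXCEEDS,
                           VariantClass.NONPOSITIVE}

    def test_classes_exhaustive_and_exclusive(self, nu_highest):
        for d in (-1.0, 0.0, 1e-9, nu_highest.nu * 0.999, nu_highest.nu, 1.0):
            assert classify_variant(d, nu_highest) in VariantClass


class TestOddsRatio:
    def test_disc1_row_matches_printed_or(self):
        """Where the meta-analytic OR happens to be frequency-consistent."""
        assert odds_ratio_from_freqs(0.03069, 0.01735) == pytest.approx(1.793, abs=5e-4)

    def test_identity_at_equal_freqs(self):
        assert odds_ratio_from_freqs(0.3, 0.3) == pytest.approx(1.0)

    def test_printed_or_is_meta_analytic_not_reproducible(self):
        """rs910694's printed OR (1.30) differs from the frequency-based 1.13."""
        assert odds_ratio_from_freqs(0.5780, 0.5477) == pytest.approx(1.131, abs=5e-4)

    def test_boundary_frequencies_raise(self):
        with pytest.raises(ValueError):
            odds_ratio_from_freqs(0.0, 0.5)
        with pytest.raises(ValueError):
            odds_ratio_from_freqs(0.5, 1.0)


class TestReferenceCatalog:
    def test_row_and_chromosome_counts(self, reference_catalog):
        assert len(reference_catalog) == 64
        chr1 = [r for r in reference_catalog if r.cytoband.chromosome == "1"]
        assert len(chr1) == 10

    def test_headline_counts(self, reference_catalog, nu_highest):
        summary = summarize_catalog(reference_catalog, nu_highest)
        assert summary.n_meeting_variants == 21
        assert summary.n_meeting_loci == 18
        assert summary.n_protective_loci_outside == 19
        assert summary.outside_arms["1p"] == ["GRIK3", "GSTM1", "MHTFR", "PDE4B"]

    def test_outside_arms_match_published_list(self, reference_catalog, nu_highest):
        summary = summarize_catalog(reference_catalog, nu_highest)
        assert set(summary.outside_arms) == {
            "1p", "2q", "5q", "7q", "10q", "11p", "12p", "12q",
            "13p", "13q", "16p", "17p", "19q",
        }
        n_outside_other = sum(
            len(g) for arm, g in summary.outside_arms.items() if arm != "1p"
        )
        assert n_outside_other == 15

    def test_meets_set_is_exactly_the_bold_rows(self, reference_catalog, nu_highest):
        """4 highlighted rows on chromosome 1, 17 on chromosomes 2-22."""
        expected_meets = {
            "rs2661319", "rs1327175", "rs3737597", "rs999710",
            "rs1800857", "rs3213207", "rs1474605", "rs6913660", "rs13219354",
            "rs13211507", "rs3131296", "rs12191311", "rs11154801", "rs9321521",
            "rs2461491", "rs10108011", "rs1801028", "rs3803300", "rs9922369",
            "rs9960767", "rs737865",
        }
        summary = summarize_catalog(reference_catalog, nu_highest)
        meets = set(
            summary.variants.loc[summary.variants["variant_class"] == "MEETS",
                                 "variant_id"]
        )
        assert meets == expected_meets
        nonpos = set(
            summary.variants.loc[summary.variants["variant_class"] == "NONPOSITIVE",
                                 "variant_id"]
        )
        assert nonpos == {"rs6932590"}

    def test_computed_d_close_to_printed_d(self, reference_catalog):
        """Printed d is 3-decimal rounded; two rows are known catalog errata
        (their printed d is inconsistent with their own printed frequencies,
        though the class is unaffected)."""
        known_discrepant = {"rs1800857", "rs2461491"}
        for rec in reference_catalog:
            if rec.printed_d is None:
                continue
            diff = abs(allele_diff(rec) - rec.printed_d)
            if rec.variant_id in known_discrepant:
                assert 5e-4 < diff < 5e-3
            else:
                assert diff <= 5e-4 + 1e-12

    def test_every_gene_on_one_arm(self, reference_catalog, nu_highest):
        summary = summarize_catalog(reference_catalog, nu_highest)
        assert summary.genes.index.is_unique
        assert (summary.genes["n_variants"] >= 1).all()

    def test_fewer_loci_than_variants(self, reference_catalog, nu_highest):
        summary = summarize_catalog(reference_catalog, nu_highest)
        assert summary.n_meeting_variants >= summary.n_meeting_loci


class TestSummarize:
    def test_empty_catalog_all_zero(self, nu_highest):
        summary = summarize_catalog([], nu_highest)
        assert summary.n_meeting_variants == 0
        assert summary.n_meeting_loci == 0
        assert summary.n_protective_loci_outside == 0
        assert summary.outside_arms == {}

    def test_row_order_invariance(self, reference_catalog, nu_highest):
        shuffled = list(reference_catalog)
        random.Random(42).shuffle(shuffled)
        a = summarize_catalog(reference_catalog, nu_highest)
        b = summarize_catalog(shuffled, nu_highest)
        assert a.n_meeting_variants == b.n_meeting_variants
        assert a.n_meeting_loci == b.n_meeting_loci
        assert a.n_protective_loci_outside == b.n_protective_loci_outside
        assert a.outside_arms == b.outside_arms

    def test_gene_on_two_arms_rejected(self, nu_highest):
        records = [
            make_record(gene="G1", variant_id="v1", location="1p36.1"),
            make_record(gene="G1", variant_id="v2", location="1q21.1"),
        ]
        with pytest.raises(ValueError, match="multiple arms"):
            summarize_catalog(records, nu_highest)

    def test_brute_force_recount_oracle(self, reference_catalog, nu_highest):
        """Independent set-based recount of the summary's aggregates."""
        nu = nu_highest.nu
        by_gene: dict[str, list] = {}
        gene_arm: dict[str, str] = {}
        for rec in reference_catalog:
            d = rec.freq_cases - rec.freq_controls
            by_gene.setdefault(rec.gene, []).append(d)
            band = rec.cytoband
            gene_arm[rec.gene] = band.chromosome + band.arm
        meets_variants = sum(
            1 for ds in by_gene.values() for d in ds if 0 < d < nu
        )
        meeting_genes = {g for g, ds in by_gene.items() if any(0 < d < nu for d in ds)}
        meeting_arms = {gene_arm[g] for g in meeting_genes}
        outside = {
            g for g, ds in by_gene.items()
            if g not in meeting_genes
            and any(d >= nu for d in ds)
            and gene_arm[g] not in meeting_arms
        }
        summary = summarize_catalog(reference_catalog, nu_highest)
        assert summary.n_meeting_variants == meets_variants
        assert summary.n_meeting_loci == len(meeting_genes)
        assert summary.n_protective_loci_outside == len(outside)


class TestIO:
    def test_round_trip(self, reference_catalog, tmp_path):
        path = tmp_path / "cat.csv"
        write_catalog(reference_catalog, path)
        back = read_catalog(path)
        assert back == reference_catalog

    def test_tsv_round_trip(self, reference_catalog, tmp_path):
        path = tmp_path / "cat.tsv"
        write_catalog(reference_catalog, path, dialect="tsv")
        assert read_catalog(path, dialect="tsv") == reference_catalog

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("gene,variant_id,location\nG1,v1,1p36\n")
        with pytest.raises(CatalogSchemaError, match="freq_controls"):
            read_catalog(path)

    def test_malformed_value_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "gene,variant_id,location,allele_minor,allele_major,risk_allele,"
            "freq_cases,freq_controls\n"
            "G1,v1,1p36,A,G,A,0.3,0.2\n"
            "G2,v2,1q21,A,G,A,oops,0.2\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_catalog(path)

    def test_risk_allele_must_be_one_of_the_pair(self):
        with pytest.raises(ValueError, match="risk allele"):
            VariantRecord(
                gene="G", variant_id="v", location="1p36",
                allele_minor="A", allele_major="G", risk_allele="T",
                freq_cases=0.3, freq_controls=0.2,
            )
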