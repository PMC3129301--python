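"""Clone-composition accounting, gene-island geometry, in-silico PCR."""

from importlib import resources

import pytest

from retroclock import (
    AnnotationRecord,
    GeneRecord,
    NucSequence,
    composition_report,
    fraction_within,
    gene_density,
    gene_island,
    insilico_pcr,
    protein_length_from_cds,
)
from retroclock.composition import revcomp
from retroclock.io_formats import read_annotation_table, read_gene_table

BAC_LEN = 113_605


@pytest.fixture(scope="module")
def bac_records():
    with resources.as_file(
        resources.files("retroclock") / "data" / "bac_2383A24_elements.tsv"
    ) as p:
        return read_annotation_table(p)


@pytest.fixture(scope="module")
def bac_genes():
    with resources.as_file(
        resources.files("retroclock") / "data" / "bac_2383A24_genes.tsv"
    ) as p:
        return read_gene_table(p)


class TestCompositionReport:
    def test_bundled_clone_fractions(self, bac_records):
        rep = composition_report(bac_records, BAC_LEN)
        assert rep.fraction("class I") == 51.6
        assert rep.fraction("LTR retrotransposons") == 50.7
        assert rep.fraction("gypsy") == 27.9
        assert rep.fraction("copia") == 21.4
        assert rep.fraction("genes") == 4.3
        assert rep.fraction("tandem repeats") == 0.9
        assert rep.fraction("class II") == 3.3
        assert rep.fraction("MITE") == 0.7
        assert rep.rollups["tandem repeats"].length_bp == 1010  # 5*177 + 125

    def test_family_share_of_a_rollup(self, bac_records):
        rep = composition_report(bac_records, BAC_LEN)
        ltr_bp = rep.rollups["LTR retrotransposons"].length_bp
        assert ltr_bp == 57_590
        assert fraction_within(bac_records, "RLG_Fatima", ltr_bp) == 47.2

    def test_empty_records_are_fully_unassigned(self):
        rep = composition_report([], 1000)
        assert rep.rollups["unassigned"].fraction_pct == 100.0

    def test_overassignment_rejected(self):
        recs = [AnnotationRecord("x", "gene", 1, 2000)]
        with pytest.raises(ValueError):
            composition_report(recs, 1000)

    def test_fraction_rounding_is_half_up(self):
        # 125/1000 = 12.5% exactly; 0.05% boundary: 5/10000 -> 0.1 (half-up)
        rep = composition_report([AnnotationRecord("x", "gene", 1, 5)], 10_000)
        assert rep.fraction("genes") == 0.1


class TestGeneIsland:
    def test_bundled_gene_island_geometry(self, bac_genes):
        isl = gene_island(bac_genes)
        assert isl.offset_5prime == 9_737
        assert isl.span == 23_670
        assert isl.n_genes == 5

    def test_single_gene_span_is_a_difference(self):
        isl = gene_island([GeneRecord("g", 100, 400)])
        assert (isl.offset_5prime, isl.span) == (100, 300)

    def test_order_invariance(self, bac_genes):
        assert gene_island(list(reversed(bac_genes))) == gene_island(bac_genes)


class TestGeneDensity:
    @pytest.mark.parametrize("total,n,expected", [
        (113_605, 5, 23),
        (100_000, 1, 100),
        (113_605, 1, 114),
    ])
    def test_kb_per_gene(self, total, n, expected):
        assert gene_density(total, n) == expected


class TestProteinLength:
    def test_bundled_cds_spans(self, bac_genes):
        expected = {"2383A24.1": 429, "2383A24.2": 502, "2383A24.3": 424,
                    "2383A24.4": 164, "2383A24.5": 114}
        assert {g.name: protein_length_from_cds(g) for g in bac_genes} == expected

    def test_single_codon_plus_stop(self):
        assert protein_length_from_cds(GeneRecord("g", 1, 6)) == 1

    def test_non_codon_multiple_rejected(self):
        with pytest.raises(ValueError):
            protein_length_from_cds(GeneRecord("g", 1, 7))


FWD = "CCAGATACCCATTCACCAAC"
REV = "CCGAGGAGCACAACCTTAC"


class TestInsilicoPCR:
    def _template(self, rng, fwd_at, product, total=400):
        from retroclock.synthetic_data import SimConfig, random_sequence

        seq = list(random_sequence(total, SimConfig(), rng))
        site_r = revcomp(REV)
        seq[fwd_at : fwd_at + len(FWD)] = FWD
        rev_start = fwd_at + product - len(site_r)
        seq[rev_start : rev_start + len(site_r)] = site_r
        return NucSequence("synthetic_template", "".join(seq))

    def test_product_length_from_constructed_sites(self, rng):
        tpl = self._template(rng, fwd_at=10, product=80)
        assert insilico_pcr(tpl, FWD, REV) == [80]

    def test_missing_forward_primer_gives_no_product(self, rng):
        from retroclock.synthetic_data import SimConfig, random_sequence

        tpl = NucSequence("t", random_sequence(300, SimConfig(), rng))
        assert insilico_pcr(tpl, FWD, REV) == []

    def test_abutting_primers_with_n_spacer(self):
        tpl = NucSequence("t", FWD + "N" * 10 + revcomp(REV))
        assert insilico_pcr(tpl, FWD, REV) == [len(FWD) + 10 + len(REV)]

    def test_reverse_complement_swap_invariance(self, rng):
        tpl = self._template(rng, fwd_at=25, product=150)
        flipped = NucSequence("rc", revcomp(tpl.residues))
        assert insilico_pcr(flipped, REV, FWD) == insilico_pcr(tpl, FWD, REV)

    def test_hyphenated_lowercase_primers_accepted(self, rng):
        tpl = self._template(rng, fwd_at=10, product=100)
        assert insilico_pcr(tpl, "ccaga-taccc-attca-ccaac",
                            "ccgag-gagca-caacc-ttac") == [100]

    def test_short_primer_rejected(self, rng):
        with pytest.raises(ValueError):
            insilico_pcr(NucSequence("t", "ACGT" * 30), "ACGTACG", REV)

    def test_oversized_products_filtered(self, rng):
        tpl = self._template(rng, fwd_at=10, product=300)
        assert insilico_pcr(tpl, FWD, REV, max_product=200) == []
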