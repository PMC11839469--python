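"""Consensus calling, variant classification and barcode counting."""

import pytest

import rubiscan as rb
from rubiscan.design import INVALID, WILD_TYPE
from rubiscan.simulate import BARCODE_FLANK_3, BARCODE_FLANK_5


@pytest.fixture(scope="module")
def design():
    return rb.make_design(length=8, seed=5)


class TestConsensus:
    def test_identical_reads_return_the_sequence(self):
        assert rb.call_consensus(["ACGTAC"] * 5) == "ACGTAC"

    def test_majority_wins_per_column(self):
        # brute-force vote: column 2 has A,A,G -> A
        assert rb.call_consensus(["ACATGC", "ACATGC", "ACGTGC"]) == "ACATGC"

    def test_two_read_tie_is_ambiguous(self):
        assert rb.call_consensus(["ACATGC", "ACGTGC"]) == "ACNTGC"

    def test_empty_bundle_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rb.call_consensus([])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            rb.call_consensus(["ACGT", "ACG"])


class TestClassification:
    def test_wild_type_sequence(self, design):
        assert rb.classify_consensus(design.cds, design) == WILD_TYPE

    def test_designed_substitution(self, design):
        v = design.variants[0]
        assert rb.classify_consensus(design.variant_cds(v), design) == v.variant_id

    def test_synonymous_change_still_wild_type(self, design):
        # amino-acid-level comparison: a silent codon change is WT
        from Bio.Data import CodonTable
        from Bio.Seq import Seq

        table = CodonTable.unambiguous_dna_by_id[1].forward_table
        cds = design.cds
        for i, aa in enumerate(design.protein):
            alts = [c for c, a in table.items() if a == aa and c != cds[3 * i : 3 * i + 3]]
            if alts:
                mutated = cds[: 3 * i] + alts[0] + cds[3 * i + 3 :]
                assert str(Seq(mutated).translate()) == design.protein
                assert rb.classify_consensus(mutated, design) == WILD_TYPE
                return
        raise AssertionError("protein unexpectedly has no degenerate codon")

    def test_extra_backbone_substitution_invalidates(self, design):
        v = next(v for v in design.variants if v.position > 2)
        cds = design.variant_cds(v)
        # second amino-acid change at position 1 (M -> K)
        cds = "AAA" + cds[3:]
        assert rb.classify_consensus(cds, design) == INVALID

    def test_undesigned_substitution_invalidates(self, design):
        # position 1 is not mutable in the design
        assert rb.classify_consensus("AAA" + design.cds[3:], design) == INVALID

    def test_indel_or_ambiguity_invalidates(self, design):
        assert rb.classify_consensus(design.cds[:-3], design) == INVALID
        assert rb.classify_consensus("N" + design.cds[1:], design) == INVALID

    def test_pure_function(self, design):
        v = design.variants[3]
        cds = design.variant_cds(v)
        assert rb.classify_consensus(cds, design) == rb.classify_consensus(cds, design)


class TestBuildLookup:
    def test_error_free_reads_give_perfect_lookup(self, design):
        config = rb.SimulationConfig(seed=6, barcodes_per_variant=2, reads_per_barcode=4)
        _, barcodes = rb.generate_library(design, config)
        long_reads, _ = rb.simulate_reads(design, barcodes, config)
        lookup = rb.build_lookup(long_reads, design, min_support=3)
        assert rb.lookup_accuracy(lookup, barcodes) == 1.0
        assert set(lookup["assignment"]) >= {WILD_TYPE}
        retained = set(lookup.loc[lookup["assignment"] != INVALID, "assignment"])
        assert retained - {WILD_TYPE} == set(design.variant_ids)

    def test_empty_input_gives_empty_lookup(self, design):
        lookup = rb.build_lookup([], design)
        assert lookup.empty
        assert lookup.attrs["summary"]["n_barcodes"] == 0

    def test_min_support_filters_thin_barcodes(self, design):
        config = rb.SimulationConfig(seed=6, barcodes_per_variant=1, reads_per_barcode=2)
        _, barcodes = rb.generate_library(design, config)
        long_reads, _ = rb.simulate_reads(design, barcodes, config)
        assert rb.build_lookup(long_reads, design, min_support=3).empty
        assert not rb.build_lookup(long_reads, design, min_support=2).empty

    def test_unparseable_reads_dropped_and_logged(self, design):
        bad = [("r1", "TTTT"), ("r2", "GATTACA" * 10)]
        lookup = rb.build_lookup(bad, design)
        assert lookup.empty
        assert lookup.attrs["summary"]["n_reads_dropped"] == 2


class TestCountBarcodes:
    @pytest.fixture()
    def lookup(self, design):
        config = rb.SimulationConfig(seed=6, barcodes_per_variant=2, reads_per_barcode=3)
        _, barcodes = rb.generate_library(design, config)
        long_reads, _ = rb.simulate_reads(design, barcodes, config)
        return rb.build_lookup(long_reads, design, min_support=3)

    @staticmethod
    def _amplicon(barcode):
        return BARCODE_FLANK_5 + barcode + BARCODE_FLANK_3

    def test_counts_equal_occurrences(self, lookup):
        bcs = list(lookup["barcode"][:3])
        reads = [("r", self._amplicon(b)) for b, n in zip(bcs, (3, 2, 1)) for _ in range(n)]
        counts = rb.count_barcodes(reads, lookup)
        tallied = counts.set_index("barcode")["count"]
        assert list(tallied[bcs]) == [3, 2, 1]
        assert counts.attrs["unassigned"] == 0
        assert counts.attrs["total"] == 6

    def test_unknown_barcode_goes_to_unassigned(self, lookup):
        reads = [("r", self._amplicon("A" * 30))]
        counts = rb.count_barcodes(reads, lookup)
        assert counts["count"].sum() == 0
        assert counts.attrs["unassigned"] == 1

    def test_zero_reads_zero_counts(self, lookup):
        counts = rb.count_barcodes([], lookup)
        assert (counts["count"] == 0).all()
        assert counts.attrs["total"] == 0

    def test_retained_plus_unassigned_equals_total(self, design, lookup):
        config = rb.SimulationConfig(seed=9, barcodes_per_variant=2, short_read_depth=5000)
        _, barcodes = rb.generate_library(design, config)
        _, short_reads = rb.simulate_reads(design, barcodes, config)
        counts = rb.count_barcodes(short_reads, lookup)
        assert counts["count"].sum() + counts.attrs["unassigned"] == counts.attrs["total"]

    def test_empty_lookup_rejected(self, design):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            rb.count_barcodes([], pd.DataFrame())


def test_merge_timepoints_preserves_reads(design):
    config = rb.SimulationConfig(seed=6, barcodes_per_variant=2, reads_per_barcode=3)
    _, barcodes = rb.generate_library(design, config)
    long_reads, short_reads = rb.simulate_reads(design, barcodes, config)
    lookup = rb.build_lookup(long_reads, design)
    from rubiscan.barcodes import merge_timepoints

    pre = rb.count_barcodes(short_reads, lookup)
    post = rb.count_barcodes(short_reads[: len(short_reads) // 2], lookup)
    merged = merge_timepoints(pre, post)
    assert merged["n_pre"].sum() + merged.attrs["pre_unassigned"] == pre.attrs["total"]
    assert merged["n_post"].sum() + merged.attrs["post_unassigned"] == post.attrs["total"]
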