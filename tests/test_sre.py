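"""SRE scanning against brute-force oracles, SNP intersection and the
splicing decision rules."""

import numpy as np
import pytest

from exonskip.diffexon import SkippingEvent
from exonskip.intervals import GeneModel, GenomicInterval, Variant
from exonskip.sre import (
    MotifSet,
    SRESite,
    filter_candidate_snps,
    map_snps_to_sres,
    motif_offset,
    reverse_complement,
    scan_sre_sites,
    splicing_decision,
)


def brute_force_scan(seq, model, motif_sets, intron_flank="full"):
    """All-positions oracle: test every 6-mer window of every region."""
    hits = set()
    for mset in motif_sets:
        if mset.is_exonic:
            regions = [(iv, "exonic") for iv in model.intervals]
        else:
            regions = []
            for intron in model.introns():
                if intron_flank == "full" or len(intron) <= 2 * intron_flank:
                    regions.append((intron, "intronic"))
                else:
                    regions.append(
                        (GenomicInterval(intron.chrom, intron.start,
                                         intron.start + intron_flank, intron.strand),
                         "intronic")
                    )
                    regions.append(
                        (GenomicInterval(intron.chrom, intron.end - intron_flank,
                                         intron.end, intron.strand),
                         "intronic")
                    )
        for region, context in regions:
            for start in range(region.start, region.end - 5):
                window = seq[start : start + 6].upper()
                if model.strand == "-":
                    window = reverse_complement(window)
                if window in mset.hexamers:
                    hits.add((start, mset.sre_class, window, context))
    return hits


def _event(exon_id):
    return SkippingEvent(exon_id, exon_id.split(":")[0], 0.001, 0.01, 2.0,
                         "lower_in_case", 0.2, 0.4)


def _gene(exon_spans, strand="+", gene_id="g1"):
    return GeneModel(
        gene_id=gene_id,
        intervals=[GenomicInterval("chr1", s, e, strand) for s, e in exon_spans],
        exon_ids=[f"{gene_id}:E{i + 1:03d}" for i in range(len(exon_spans))],
    )


class TestScan:
    def test_worked_example_one_ise_site(self):
        # AACCTTCCAA with exons flanking a 6 bp intron [2, 8): the single
        # CCTTCC occupies 1-based positions 3-8
        seq = "AACCTTCCAA"
        model = _gene([(0, 2), (8, 10)])
        sites = scan_sre_sites(seq, [model], [MotifSet("ISE", frozenset({"CCTTCC"}))])
        assert len(sites) == 1
        assert (sites[0].interval.start, sites[0].interval.end) == (2, 8)
        assert sites[0].context == "intronic"
        assert sites[0].flanking_exon_ids == ("g1:E001", "g1:E002")

    def test_empty_motif_sets_give_no_sites(self):
        model = _gene([(0, 10), (20, 30)])
        assert scan_sre_sites("A" * 30, [model], [MotifSet("ESE", frozenset())]) == []

    def test_exonic_class_not_reported_in_introns(self):
        seq = "AA" + "CCTTCC" + "AA"  # motif only inside the intron [2, 8)
        model = _gene([(0, 2), (8, 10)])
        sites = scan_sre_sites(seq, [model], [MotifSet("ESE", frozenset({"CCTTCC"}))])
        assert sites == []

    def test_overlapping_matches_all_reported(self):
        seq = "TT" + "AAAAAAA" + "TT"  # AAAAAA at offsets 2 and 3 in exon [2, 9)
        model = _gene([(2, 9)])
        sites = scan_sre_sites(seq, [model], [MotifSet("ESS", frozenset({"AAAAAA"}))])
        assert sorted(s.interval.start for s in sites) == [2, 3]

    def test_sequence_shorter_than_span_rejected(self):
        model = _gene([(0, 10), (20, 30)])
        with pytest.raises(ValueError, match="shorter"):
            scan_sre_sites("ACGT", [model], [MotifSet("ISE", frozenset({"CCTTCC"}))])

    def test_minus_strand_scans_reverse_complement(self):
        # forward GGAAGG in the intron reads CCTTCC on the minus strand
        seq = "AA" + "GGAAGG" + "AA"
        model = _gene([(0, 2), (8, 10)], strand="-")
        sites = scan_sre_sites(seq, [model], [MotifSet("ISE", frozenset({"CCTTCC"}))])
        assert len(sites) == 1
        assert sites[0].hexamer == "CCTTCC"
        assert (sites[0].interval.start, sites[0].interval.end) == (2, 8)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("flank", ["full", 50])
    def test_matches_brute_force_oracle_on_random_instances(self, rng, strand, flank):
        for _ in range(25):  # 25 instances × 4 parameter combos = 100
            seq = "".join(rng.choice(list("ACGT"), 1000))
            bounds = np.sort(rng.choice(np.arange(10, 990), 6, replace=False))
            model = _gene(
                [(bounds[0], bounds[1]), (bounds[2], bounds[3]), (bounds[4], bounds[5])],
                strand=strand,
            )
            motif_sets = [
                MotifSet(
                    klass,
                    frozenset(
                        "".join(rng.choice(list("ACGT"), 6)) for _ in range(8)
                    ),
                )
                for klass in ("ESE", "ESS", "ISE")
            ]
            got = {
                (s.interval.start, s.sre_class, s.hexamer, s.context)
                for s in scan_sre_sites(seq, [model], motif_sets, flank)
            }
            expected = set()
            for mset in motif_sets:
                expected |= brute_force_scan(seq, model, [mset], flank)
            assert got == expected

    def test_strand_mirror_property(self, rng):
        """A minus-strand gene equals its reverse-complemented plus mirror."""
        seq = "".join(rng.choice(list("ACGT"), 300))
        spans = [(20, 80), (140, 200), (240, 290)]
        minus = _gene(spans, strand="-")
        motifs = [MotifSet("ISE", frozenset({"CCTTCC", "GGAAGG", "ACGTAC"}))]
        sites_minus = scan_sre_sites(seq, [minus], motifs)
        # mirror: reverse-complement the sequence, mirror the coordinates
        L = len(seq)
        mirror_seq = reverse_complement(seq)
        mirror_spans = sorted((L - e, L - s) for s, e in spans)
        plus = _gene(mirror_spans, strand="+")
        sites_plus = scan_sre_sites(mirror_seq, [plus], motifs)
        got = {(L - s.interval.end, s.hexamer) for s in sites_plus}
        assert {(s.interval.start, s.hexamer) for s in sites_minus} == got


class TestSnpIntersection:
    def _site(self, start=2, strand="+", klass="ISE", hexamer="CCTTCC"):
        context = "intronic" if klass == "ISE" else "exonic"
        return SRESite(
            interval=GenomicInterval("chr1", start, start + 6, strand),
            sre_class=klass,
            hexamer=hexamer,
            context=context,
            gene_id="g1",
            anchor_exon_id="g1:E001",
            flanking_exon_ids=("g1:E001", "g1:E002") if context == "intronic" else (),
        )

    def test_fifth_base_offset(self):
        site = self._site(start=2)
        v = Variant("rs1", "chr1", 7, "C", "T", 0.3)  # 1-based 7 = 0-based 6
        [(got_v, got_s, offset)] = map_snps_to_sres([v], [site])
        assert offset == 5

    def test_snp_past_site_end_not_mapped(self):
        site = self._site(start=2)  # covers 0-based [2, 8) = 1-based 3..8
        v = Variant("rs1", "chr1", 9, "A", "G", 0.3)
        assert map_snps_to_sres([v], [site]) == []

    def test_snp_in_two_overlapping_sites_yields_two_records(self):
        s1 = self._site(start=2, hexamer="AAAAAA")
        s2 = self._site(start=4, hexamer="AAAAAA")
        v = Variant("rs1", "chr1", 6, "A", "G", 0.3)
        recs = map_snps_to_sres([v], [s1, s2])
        assert len(recs) == 2
        assert {r[2] for r in recs} == {4, 2}

    def test_minus_strand_offset_counts_from_other_end(self):
        site = self._site(start=2, strand="-")
        # 0-based 6 is the 5th-from-start on +, 2nd on the motif's (−) strand
        assert motif_offset(site, 6) == 2


class TestDecision:
    def _setup(self):
        seq = "AA" + "CCTTCC" + "AA" + "GGGGGG" + "AA"
        model = _gene([(0, 2), (8, 10), (16, 18)])
        ise = MotifSet("ISE", frozenset({"CCTTCC"}))
        sites = scan_sre_sites(seq, [model], [ise])
        return seq, model, ise, sites

    def test_intronic_site_adjacent_to_skipped_exon_emits_enhancer_loss(self):
        _, model, ise, sites = self._setup()
        v = Variant("rs1", "chr1", 7, "C", "T", 0.3)  # 5th motif base
        overlaps = map_snps_to_sres([v], sites)
        calls = splicing_decision(overlaps, [_event("g1:E002")], [model], [ise])
        assert len(calls) == 1
        assert calls[0].effect_call == "enhancer_loss_promotes_skipping"
        assert calls[0].offset_in_motif == 5
        assert calls[0].skipped_exon_id == "g1:E002"

    def test_no_call_when_linked_exon_not_skipped(self):
        _, model, ise, sites = self._setup()
        v = Variant("rs1", "chr1", 7, "C", "T", 0.3)
        overlaps = map_snps_to_sres([v], sites)
        assert splicing_decision(overlaps, [_event("g1:E003")], [model], [ise]) == []

    def test_exonic_ess_in_skipped_exon_emits_silencer_loss(self):
        seq = "TT" + "ACGTAC" + "TT"
        model = _gene([(2, 8)])
        ess = MotifSet("ESS", frozenset({"ACGTAC"}))
        sites = scan_sre_sites(seq, [model], [ess])
        v = Variant("rs1", "chr1", 5, "G", "A", 0.2)  # 0-based 4 = motif base G
        calls = splicing_decision(
            map_snps_to_sres([v], sites), [_event("g1:E001")], [model], [ess]
        )
        assert len(calls) == 1
        assert calls[0].effect_call == "silencer_loss_promotes_inclusion"

    def test_exonic_ese_in_unskipped_exon_no_call(self):
        seq = "TT" + "ACGTAC" + "TT" + "ACGTACGTAC"
        model = _gene([(2, 8), (12, 14)])
        ese = MotifSet("ESE", frozenset({"ACGTAC"}))
        sites = scan_sre_sites(seq, [model], [ese])
        v = Variant("rs1", "chr1", 5, "G", "A", 0.2)
        calls = splicing_decision(
            map_snps_to_sres([v], sites), [_event("g1:E002")], [model], [ese]
        )
        assert calls == []

    def test_ref_mismatch_dropped_with_warning(self, caplog):
        _, model, ise, sites = self._setup()
        v = Variant("rs1", "chr1", 7, "A", "T", 0.3)  # motif base there is C
        with caplog.at_level("WARNING"):
            calls = splicing_decision(
                map_snps_to_sres([v], sites), [_event("g1:E002")], [model], [ise]
            )
        assert calls == []
        assert "does not match" in caplog.text

    def test_alt_creating_another_motif_is_recorded(self):
        _, model, ise, sites = self._setup()
        both = MotifSet("ISE", frozenset({"CCTTCC", "CCTTAC"}))
        sites = scan_sre_sites("AACCTTCCAAGGGGGGAA", [model], [both])
        v = Variant("rs1", "chr1", 7, "C", "A", 0.3)
        calls = splicing_decision(
            map_snps_to_sres([v], [s for s in sites if s.hexamer == "CCTTCC"]),
            [_event("g1:E002")], [model], [both],
        )
        assert calls[0].alt_creates_motif == ("ISE", "CCTTAC")

    def test_minus_strand_ref_check_uses_forward_base(self):
        seq = "AA" + "GGAAGG" + "AA"  # CCTTCC on the minus strand
        model = _gene([(0, 2), (8, 10)], strand="-")
        ise = MotifSet("ISE", frozenset({"CCTTCC"}))
        sites = scan_sre_sites(seq, [model], [ise])
        # motif offset 5 is base C on the motif strand → forward base G at 0-based 3
        v = Variant("rs1", "chr1", 4, "G", "A", 0.3)
        calls = splicing_decision(
            map_snps_to_sres([v], sites), [_event("g1:E001")], [model], [ise]
        )
        assert len(calls) == 1
        assert calls[0].offset_in_motif == 5


class TestMafFilter:
    def _call(self, maf):
        from exonskip.sre import SplicingSNPCall

        site = SRESite(
            interval=GenomicInterval("chr1", 2, 8, "+"),
            sre_class="ISE", hexamer="CCTTCC", context="intronic",
            gene_id="g1", anchor_exon_id="g1:E001",
            flanking_exon_ids=("g1:E001", "g1:E002"),
        )
        v = Variant(f"rs_{maf}", "chr1", 5, "T", "C", maf)
        return SplicingSNPCall(v, site, 3, "g1:E001", "enhancer_loss_promotes_skipping")

    def test_strictly_greater_than_threshold(self):
        calls = [self._call(m) for m in (0.02, 0.01, 0.009)]
        kept = filter_candidate_snps(calls, 0.01)
        assert [c.variant.maf for c in kept] == [0.02]

    def test_empty_input_empty_output(self):
        assert filter_candidate_snps([], 0.01) == []

    def test_zero_threshold_keeps_all_polymorphic(self):
        calls = [self._call(m) for m in (0.02, 0.4)]
        assert len(filter_candidate_snps(calls, 0.0)) == 2
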