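"""Retained-CDS construction and PTC classification under the ciliate code."""

import numpy as np
import pytest
from Bio.Seq import Seq

from iesretention import (
    GeneModel,
    ValidationError,
    build_retained_cds,
    classify_ptc,
    ptc_enrichment,
    translate,
)
from iesretention.ptc import PTCAnnotation

from conftest import make_locus

# independent codon table for the brute-force oracle (not Biopython's)
_CILIATE_STOPS = {"TGA"}
_STANDARD_STOPS = {"TAA", "TAG", "TGA"}


def _oracle_classify(gene, ies, genome, stops=_CILIATE_STOPS):
    """Naive reconstruction: splice in + strand space, orient, scan codons."""
    scaf = genome[gene.scaffold]
    s, e = gene.cds_segments[0]
    ip = ies.mac_insertion_point
    plus = scaf[s:ip] + ies.ies_sequence[:-2] + scaf[ip:e]
    coding = plus if gene.strand == "+" else str(Seq(plus).reverse_complement())
    stops_at = [
        i for i in range(len(coding) // 3) if coding[3 * i : 3 * i + 3] in stops
    ]
    mac_len = e - s
    native_nt = mac_len - 3 + (len(ies.ies_sequence) - 2)
    premature = [i for i in stops_at if 3 * i < native_nt]
    shift = (len(ies.ies_sequence) - 2) % 3
    if premature:
        return "PTC_INDUCING", premature[0], shift
    return ("ORF_INTACT" if shift == 0 else "FRAMESHIFT_NO_STOP"), None, shift


class TestBuildRetainedCDS:
    def test_splice_then_excise_round_trip(self, toy_locus):
        genome, gene, locus = toy_locus
        retained = build_retained_cds(gene, locus, genome)
        mac_cds = gene.mac_cds_sequence(genome)
        assert len(retained) == len(mac_cds) + locus.length
        # excise: remove the eliminated segment at its coding offset
        q = locus.mac_insertion_point - gene.cds_segments[0][0]
        assert retained[:q] + retained[q + locus.length :] == mac_cds

    def test_27nt_segment_extends_by_27(self, toy_locus):
        genome, gene, _ = toy_locus
        locus = make_locus(ip=42, interior="G" * 25, location_class="exon", host_gene_id="gene_T1")
        retained = build_retained_cds(gene, locus, genome)
        assert len(retained) == gene.cds_length + 27

    def test_minus_strand_is_revcomp_of_plus_construction(self, toy_locus):
        genome, gene, locus = toy_locus
        minus = GeneModel(
            gene_id="gene_T1m",
            scaffold="scaf",
            strand="-",
            cds_segments=gene.cds_segments,
        )
        plus_built = build_retained_cds(gene, locus, genome)
        minus_built = build_retained_cds(minus, locus, genome)
        assert minus_built == str(Seq(plus_built).reverse_complement())

    def test_insertion_outside_cds_rejected(self, toy_locus):
        genome, gene, _ = toy_locus
        outside = make_locus(ip=5, location_class="exon", host_gene_id="gene_T1")
        with pytest.raises(ValidationError, match="inside"):
            build_retained_cds(gene, outside, genome)

    def test_scaffold_mismatch_rejected(self, toy_locus):
        genome, gene, locus = toy_locus
        other = make_locus(ip=locus.mac_insertion_point, scaffold="other")
        genome = {**genome, "other": genome["scaf"]}
        with pytest.raises(ValidationError, match="scaffold|on "):
            build_retained_cds(gene, other, genome)


class TestTranslate:
    def test_ciliate_code_taa_is_glutamine(self):
        protein, stops = translate("ATGTAAGGGTGA", genetic_code="ciliate")
        assert protein == "MQG*"
        assert stops == [3]

    def test_standard_code_taa_is_stop(self):
        protein, stops = translate("ATGTAAGGGTGA", genetic_code="standard")
        assert stops[0] == 1

    def test_tga_free_sequence_has_no_ciliate_stop(self):
        rng = np.random.default_rng(1)
        codons = [c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3)) if c != "TGA"]
        seq = "".join(rng.choice(codons, size=333))
        _, stops = translate(seq, genetic_code="ciliate")
        assert stops == []
        assert "TGA" not in {seq[3 * i : 3 * i + 3] for i in range(333)}  # oracle scan

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            translate("AT")
        with pytest.raises(ValidationError):
            translate("ATGNNNTGA")
        with pytest.raises(ValidationError):
            translate("ATGTGA", genetic_code="klingon")


class TestClassifyPTC:
    def test_inframe_tga_in_27nt_segment_is_ptc(self, toy_locus):
        genome, gene, _ = toy_locus
        # eliminated segment "TA" + interior, length 27 (frame shift 0);
        # the insertion offset is 12, so an in-frame TGA must start at an
        # eliminated-segment position = 0 mod 3, i.e. interior index 7
        base = "GCC" * 8 + "C"
        interior = base[:7] + "TGA" + base[10:]
        locus = make_locus(ip=42, interior=interior, location_class="exon", host_gene_id="gene_T1")
        assert locus.length == 27
        ann = classify_ptc(gene, locus, genome)
        assert ann.frame_shift == 0
        assert ann.consequence == "PTC_INDUCING"

    def test_no_tga_27nt_segment_is_orf_intact(self, toy_locus):
        genome, gene, _ = toy_locus
        locus = make_locus(ip=42, interior="GCC" * 8 + "C", location_class="exon", host_gene_id="gene_T1")
        assert locus.length == 27
        ann = classify_ptc(gene, locus, genome)
        assert ann.consequence == "ORF_INTACT"
        assert ann.first_stop_codon_index is None

    def test_frameshift_never_orf_intact(self, toy_locus):
        genome, gene, _ = toy_locus
        locus = make_locus(ip=42, interior="GCC" * 8, location_class="exon", host_gene_id="gene_T1")
        assert locus.length % 3 != 0
        ann = classify_ptc(gene, locus, genome)
        assert ann.consequence in ("PTC_INDUCING", "FRAMESHIFT_NO_STOP")

    def test_matches_brute_force_oracle_on_random_fixtures(self, small_truth):
        """Classification equals a naive splice-translate-scan oracle."""
        truth = small_truth
        genes = {g.gene_id: g for g in truth.genes}
        checked = 0
        for locus in truth.ies_loci:
            if locus.location_class != "exon":
                continue
            gene = genes[locus.host_gene_id]
            ann = classify_ptc(gene, locus, truth.mac_genome)
            cons, first, shift = _oracle_classify(gene, locus, truth.mac_genome)
            assert (ann.consequence, ann.first_stop_codon_index, ann.frame_shift) == (
                cons,
                first,
                shift,
            )
            checked += 1
        assert checked > 50

    def test_premature_stop_is_upstream_of_native(self, small_truth):
        truth = small_truth
        genes = {g.gene_id: g for g in truth.genes}
        for locus in truth.ies_loci[:80]:
            if locus.location_class != "exon":
                continue
            gene = genes[locus.host_gene_id]
            ann = classify_ptc(gene, locus, truth.mac_genome)
            if ann.consequence == "PTC_INDUCING":
                native_nt = gene.cds_length - 3 + locus.length
                assert 3 * ann.first_stop_codon_index < native_nt


class TestPTCEnrichment:
    @staticmethod
    def _annotations(flags):
        return {
            f"i{k}": PTCAnnotation(f"i{k}", "g", "PTC_INDUCING" if f else "ORF_INTACT", 0 if f else None, 0)
            for k, f in enumerate(flags)
        }

    def test_observed_equals_background_gives_p_one(self):
        anns = self._annotations([True, False] * 10)
        ids = list(anns)
        obs, exp, p = ptc_enrichment(ids, ids, anns, n_perm=200, seed=0)
        assert obs == pytest.approx(exp)
        assert p == pytest.approx(1.0)

    def test_zero_ptc_background_expected_zero(self):
        anns = self._annotations([False] * 20)
        obs, exp, p = ptc_enrichment(list(anns)[:5], list(anns), anns, n_perm=200, seed=0)
        assert exp == 0.0 and obs == 0.0

    def test_planted_excess_detected(self):
        """An observed set with ~3x the background PTC rate: p < 0.05."""
        rng = np.random.default_rng(12)
        flags = list(rng.random(400) < 0.2)
        anns = self._annotations(flags)
        ids = list(anns)
        ptc_ids = [i for i in ids if anns[i].ptc_inducing]
        free_ids = [i for i in ids if not anns[i].ptc_inducing]
        observed = ptc_ids[:30] + free_ids[:20]  # 60% vs 20% background
        obs, exp, p = ptc_enrichment(observed, ids, anns, n_perm=2000, seed=1)
        assert obs > exp
        assert p < 0.05

    def test_background_smaller_than_observed_rejected(self):
        anns = self._annotations([True] * 5)
        with pytest.raises(ValidationError):
            ptc_enrichment(list(anns), list(anns)[:3], anns, n_perm=10, seed=0)
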