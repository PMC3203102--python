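"""Effect annotation: coding consequences, positional categories, novelty."""

import math

import numpy as np
import pytest

from lclfidelity.annotation import (GeneModel, Transcript, annotate_indel,
                                    annotate_snv, is_novel, toy_gene_model)
from lclfidelity.config import SimulationConfig
from lclfidelity.simulate import DictReference, generate_pedigree_truth, generate_targets

# Independent standard-genetic-code lookup (the implementation translates
# with a library routine; this table is the cross-check).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _single_exon_model(seq, strand="+", cds=(0, None), chrom="chr1"):
    cds_end = cds[1] if cds[1] is not None else len(seq)
    tx = Transcript("tx", chrom, strand, 0, len(seq), ((0, len(seq)),),
                    cds[0], cds_end)
    return GeneModel([tx]), DictReference({chrom: seq})


class TestCodingEffects:
    def test_gaa_to_gag_synonymous(self):
        model, ref = _single_exon_model("GAA" * 4)
        ann = annotate_snv(("chr1", 3, "A", "G"), model, ref)  # GAA -> GAG
        assert ann.effect == "synonymous"
        assert ann.amino_acid_change == ("E", 1, "E")

    def test_tac_to_taa_nonsense(self):
        model, ref = _single_exon_model("TAC" + "GAA" * 3)
        ann = annotate_snv(("chr1", 3, "C", "A"), model, ref)
        assert ann.effect == "nonsense"
        assert ann.amino_acid_change == ("Y", 1, "*")

    def test_missense(self):
        model, ref = _single_exon_model("ATGGCA" + "GAA" * 2)
        ann = annotate_snv(("chr1", 4, "G", "A"), model, ref)  # GCA -> ACA, A->T
        assert ann.effect == "non-synonymous"
        assert ann.amino_acid_change == ("A", 2, "T")

    def test_reference_mismatch_rejected(self):
        model, ref = _single_exon_model("GAA" * 4)
        with pytest.raises(ValueError, match="mismatch"):
            annotate_snv(("chr1", 1, "C", "T"), model, ref)

    def test_all_single_base_mutations_of_random_codons_match_table(self, rng):
        """Translation oracle: every mutation of 50 random codons classified
        identically by the annotator and an independent codon lookup."""
        bases = "ACGT"
        codons = ["".join(rng.choice(list(bases), 3)) for _ in range(50)]
        for codon in codons:
            seq = codon + "GGGTAA"  # pad to keep CDS %3 == 0
            model, ref = _single_exon_model(seq, cds=(0, len(seq)))
            for offset in range(3):
                for alt in bases:
                    if alt == codon[offset]:
                        continue
                    ann = annotate_snv(("chr1", offset + 1, codon[offset], alt),
                                       model, ref)
                    mutated = codon[:offset] + alt + codon[offset + 1:]
                    ref_aa, alt_aa = CODON_TABLE[codon], CODON_TABLE[mutated]
                    if alt_aa == "*" and ref_aa != "*":
                        expected = "nonsense"
                    elif alt_aa == ref_aa:
                        expected = "synonymous"
                    else:
                        expected = "non-synonymous"
                    assert ann.effect == expected, (codon, offset, alt)

    def test_minus_strand_equals_reverse_complement_construction(self):
        """Metamorphic check: annotating a minus-strand gene matches the
        plus-strand annotation of the reverse-complemented locus."""
        comp = str.maketrans("ACGT", "TGCA")
        seq = "ATGGCATTAGAAGGGTGCTAA"  # 21 bp ORF on the plus strand
        rc = seq.translate(comp)[::-1]
        plus_model, plus_ref = _single_exon_model(seq, strand="+")
        minus_model, minus_ref = _single_exon_model(rc, strand="-")
        L = len(seq)
        for pos in range(1, L + 1):
            base = seq[pos - 1]
            for alt in "ACGT":
                if alt == base:
                    continue
                a_plus = annotate_snv(("chr1", pos, base, alt), plus_model, plus_ref)
                rc_pos = L - pos + 1
                rc_base = base.translate(comp)
                rc_alt = alt.translate(comp)
                a_minus = annotate_snv(("chr1", rc_pos, rc_base, rc_alt),
                                       minus_model, minus_ref)
                assert a_plus.effect == a_minus.effect
                assert a_plus.amino_acid_change == a_minus.amino_acid_change


class TestPositionalEffects:
    def _spliced_model(self, strand="+"):
        # 60 bp locus: exon1 [0,18), intron [18,36), exon2 [36,60)
        seq = "ATG" + "GCA" * 5 + "GTAAGTATATATATCAAG" + "GCA" * 7 + "TAA"
        tx = Transcript("tx", "chr1", strand, 0, 60, ((0, 18), (36, 60)), 0, 60)
        return GeneModel([tx]), DictReference({"chr1": seq})

    def test_far_from_any_gene_is_intergenic(self):
        model, _ = self._spliced_model()
        ref = DictReference({"chr1": "A" * 20000})
        ann = annotate_snv(("chr1", 10_000, "A", "G"), model, ref)
        assert ann.effect == "intergenic"

    def test_splice_site_within_2bp_of_exon_boundary(self):
        model, ref = self._spliced_model()
        for pos in (19, 20, 35, 36):  # 1-based, intronic side
            base = ref.get_base("chr1", pos)
            alt = "A" if base != "A" else "G"
            ann = annotate_snv(("chr1", pos, base, alt), model, ref)
            assert ann.effect == "splice-site", pos
        mid = 27
        base = ref.get_base("chr1", mid)
        alt = "A" if base != "A" else "G"
        assert annotate_snv(("chr1", mid, base, alt), model, ref).effect == "intronic"

    def test_near_gene_50bp_upstream_only(self):
        seq = "T" * 200 + "ATG" + "GCA" * 4 + "TAA" + "T" * 200
        tx = Transcript("tx", "chr1", "+", 200, 218, ((200, 218),), 200, 218)
        model = GeneModel([tx])
        ref = DictReference({"chr1": seq})
        assert annotate_snv(("chr1", 171, "T", "A"), model, ref).effect == "near_gene"
        assert annotate_snv(("chr1", 150, "T", "A"), model, ref).effect == "intergenic"
        # downstream is not "near gene"
        assert annotate_snv(("chr1", 230, "T", "A"), model, ref).effect == "intergenic"

    def test_utrs_are_strand_aware(self):
        seq = "T" * 6 + "ATG" + "GCA" * 3 + "TAA" + "T" * 6  # UTRs flank the ORF
        for strand in "+-":
            tx = Transcript("tx", "chr1", strand, 0, 27, ((0, 27),), 6, 21)
            model = GeneModel([tx])
            ref = DictReference({"chr1": seq})
            left = annotate_snv(("chr1", 3, "T", "A"), model, ref).effect
            right = annotate_snv(("chr1", 25, "T", "A"), model, ref).effect
            if strand == "+":
                assert (left, right) == ("utr5", "utr3")
            else:
                assert (left, right) == ("utr3", "utr5")

    def test_mirna_interval(self):
        model = GeneModel([], mirnas=[("chr1", 100, 120, "mir1")])
        ref = DictReference({"chr1": "A" * 200})
        assert annotate_snv(("chr1", 110, "A", "G"), model, ref).effect == "microRNA"


class TestIndelEffects:
    def _model(self):
        seq = "T" * 10 + "ATG" + "GCA" * 10 + "TAA" + "T" * 50
        tx = Transcript("tx", "chr1", "+", 10, 46, ((10, 46),), 10, 46)
        return GeneModel([tx]), seq

    def test_2bp_deletion_in_cds_is_frameshift(self):
        model, _ = self._model()
        ann = annotate_indel(("chr1", 15, "AGC", "A"), model)
        assert ann.effect == "frameshift"

    def test_3bp_insertion_in_cds_is_inframe(self):
        model, _ = self._model()
        ann = annotate_indel(("chr1", 15, "A", "AGCA"), model)
        assert ann.effect == "inframe_indel"

    def test_deletion_outside_gene_is_intergenic(self):
        model, _ = self._model()
        ann = annotate_indel(("chr1", 60, "T" + "A" * 11, "T"), model)
        assert ann.effect == "intergenic"

    def test_zero_length_rejected(self):
        model, _ = self._model()
        with pytest.raises(ValueError, match="zero-length"):
            annotate_indel(("chr1", 15, "A", "A"), model)

    def test_frameshift_iff_length_not_multiple_of_3(self):
        model, _ = self._model()
        for n in range(1, 12):
            ann = annotate_indel(("chr1", 15, "A" + "G" * n, "A"), model)
            assert ann.effect == ("inframe_indel" if n % 3 == 0 else "frameshift"), n


class TestNovelty:
    def test_known_key_not_novel(self):
        key = ("chr1", 100, "A", "G")
        assert not is_novel(key, {key})
        assert is_novel(("chr1", 100, "A", "T"), {key})
        assert not is_novel(("chr1", 100, "A", "T"), {key}, position_only=True)

    def test_empty_known_sites_all_novel(self):
        assert is_novel(("chr1", 1, "A", "C"), set())

    def test_simulated_novel_share_matches_config(self):
        """Per-site novelty flags recover the configured novel fraction."""
        cfg = SimulationConfig(seed=29, genome_length=60_000_000,
                               n_target_regions=300, target_region_length=2_000,
                               variant_density=19_354 / 38_000_000 * 20)
        truth = generate_pedigree_truth(generate_targets(cfg), cfg)
        v = truth.variants
        known = truth.known_site_keys()
        keys = list(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))
        novel = sum(1 for k in keys if is_novel(k, known))
        n = len(keys)
        assert n > 5_000
        se = math.sqrt(0.0275 * (1 - 0.0275) / n)
        assert abs(novel / n - 0.0275) < 3 * se


class TestToyModel:
    def test_toy_model_invariants(self):
        cfg = SimulationConfig(seed=1)
        targets = generate_targets(cfg)
        model = toy_gene_model(targets)
        assert len(model.transcripts) > 0 and len(model.mirnas) > 0
        for tx in model.transcripts:
            assert len(tx.cds_positions()) % 3 == 0
            assert tx.start <= tx.cds_start < tx.cds_end <= tx.end
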