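"""Mutation-record parsing, consequence calls, contexts and signature estimation."""
import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from structmut import catalog as cat
from structmut import simulate

TOY = cat.CodingGene(gene="TOY", cds="ATGGCTTGC", flank5="A", flank3="G")


class TestClassifyConsequence:
    def test_missense_call(self):
        # GCT (A) -> GTT (V) at CDS position 5
        assert cat.classify_consequence(TOY, 5, "C", "T") == ("missense", "A2V")

    def test_synonymous_third_position(self):
        # GCT -> GCC, both alanine
        assert cat.classify_consequence(TOY, 6, "T", "C") == ("synonymous", "A2=")

    def test_reference_mismatch_raises(self):
        with pytest.raises(cat.ReferenceMismatchError):
            cat.classify_consequence(TOY, 5, "G", "T")

    def test_agrees_with_biopython_translation_oracle(self, random_gene):
        """Exhaustive scan of a 30-codon gene vs whole-CDS re-translation."""
        ref_protein = str(Seq(random_gene.cds).translate())
        for pos in range(1, len(random_gene.cds) + 1):
            ref = random_gene.cds[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mutated = random_gene.cds[: pos - 1] + alt + random_gene.cds[pos:]
                mut_protein = str(Seq(mutated).translate())
                diffs = [
                    i for i, (a, b) in enumerate(zip(ref_protein, mut_protein)) if a != b
                ]
                consequence, change = cat.classify_consequence(random_gene, pos, ref, alt)
                if not diffs:
                    assert consequence == "synonymous"
                else:
                    (i,) = diffs
                    if mut_protein[i] == "*":
                        assert consequence == "nonsense"
                    elif ref_protein[i] == "*":
                        assert consequence == "other"
                    else:
                        assert consequence == "missense"
                        assert change == f"{ref_protein[i]}{i + 1}{mut_protein[i]}"

    def test_enumerate_snvs_matches_scalar_path(self, random_gene):
        snvs = cat.enumerate_snvs(random_gene)
        assert len(snvs) == 3 * len(random_gene.cds)
        for _, row in snvs.sample(60, random_state=0).iterrows():
            consequence, _ = cat.classify_consequence(
                random_gene, int(row.cds_position), row.ref_base, row.alt_base
            )
            channel = cat.trinucleotide_context(
                random_gene, int(row.cds_position), row.ref_base, row.alt_base
            )
            assert consequence == row.consequence
            assert channel == row.channel


class TestTrinucleotideContext:
    def test_pyrimidine_centred_definition(self):
        # A[C>T]G is class C>T (index 2), 5' A (0), 3' G (2)
        gene = cat.CodingGene(gene="g", cds="ACGCAT", flank5="T", flank3="A")
        assert cat.trinucleotide_context(gene, 2, "C", "T") == 2 * 16 + 0 * 4 + 2

    def test_purine_collapses_to_reverse_complement(self):
        # C[G>A]T reverse-complements to A[C>T]G
        gene = cat.CodingGene(gene="g", cds="CGTCAT", flank5="T", flank3="A")
        assert cat.trinucleotide_context(gene, 2, "G", "A") == 2 * 16 + 0 * 4 + 2

    def test_strand_collapse_symmetry_all_192_contexts(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for five, ref, three in itertools.product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == ref:
                    continue
                fwd = cat.context_channel(five, ref, alt, three)
                rev = cat.context_channel(comp[three], comp[ref], comp[alt], comp[five])
                assert fwd == rev

    def test_missing_flank_raises(self):
        gene = cat.CodingGene(gene="g", cds="ATGAAA")
        with pytest.raises(cat.FlankError):
            cat.trinucleotide_context(gene, 1, "A", "C")

    def test_channel_enumeration_matches_hand_tally(self):
        """Per-channel counts of a designed sequence equal a direct tally."""
        rng = np.random.default_rng(3)
        gene = simulate.random_coding_gene(34, rng, gene="tally")
        snvs = cat.enumerate_snvs(gene)
        padded = (gene.flank5 or "") + gene.cds + (gene.flank3 or "")
        tally = np.zeros(96, dtype=int)
        for p in range(1, len(gene.cds) + 1):
            tri = padded[p - 1 : p + 2]
            for alt in "ACGT":
                if alt == tri[1]:
                    continue
                tally[cat.context_channel(tri[0], tri[1], alt, tri[2])] += 1
        counts = np.bincount(snvs["channel"], minlength=96)
        assert (counts == tally).all()


class TestSignatureEstimation:
    def test_single_record_concentrates_mass(self):
        gene = cat.CodingGene(gene="g", cds="ACGCAT", flank5="T", flank3="A")
        rec = cat.MutationRecord(
            gene="g", sample_id="s1", cds_position=2, ref_base="C", alt_base="T"
        )
        sig = cat.estimate_signature([rec], {"g": gene}, pseudocount=0.0)
        channel = cat.trinucleotide_context(gene, 2, "C", "T")
        assert sig.channel_probs[channel] == 1.0
        assert sig.channel_probs.sum() == pytest.approx(1.0)

    def test_no_usable_records_raises(self):
        with pytest.raises(ValueError):
            cat.estimate_signature([], {}, pseudocount=0.5)

    def test_planted_signature_recovered(self, skewed_signature):
        """A 10,000-mutation cohort recovers each channel within +/- 0.01.

        Signatures are estimated from raw CDS-context counts without
        opportunity normalization, so the recoverable truth is the planted
        signature weighted by each channel's context count in the gene — the
        same convention the generator draws from.
        """
        rng = np.random.default_rng(17)
        gene = simulate.random_coding_gene(400, rng, gene="BIG")
        snvs = cat.enumerate_snvs(gene)
        w = skewed_signature.channel_probs[snvs["channel"].to_numpy()]
        truth = np.bincount(snvs["channel"], weights=w, minlength=96)
        truth = truth / truth.sum()
        w = w / w.sum()
        picks = rng.choice(len(snvs), size=10_000, p=w)
        sub = snvs.iloc[picks]
        records = [
            cat.MutationRecord(
                gene="BIG", sample_id=f"s{i}", cds_position=int(p), ref_base=r, alt_base=a
            )
            for i, (p, r, a) in enumerate(
                zip(sub["cds_position"], sub["ref_base"], sub["alt_base"])
            )
        ]
        est = cat.estimate_signature(records, {"BIG": gene}, pseudocount=0.0)
        assert np.abs(est.channel_probs - truth).max() < 0.01


class TestSubstitutionSpectrum:
    def test_pure_ct_cohort(self):
        recs = [
            cat.MutationRecord(gene="g", sample_id=str(i), cds_position=1,
                               ref_base="C", alt_base="T")
            for i in range(5)
        ]
        spec = cat.substitution_spectrum(recs)
        assert spec["C>T"] == 1.0
        assert sum(spec.values()) == pytest.approx(1.0)

    def test_uniform_six_classes(self):
        pairs = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
        recs = [
            cat.MutationRecord(gene="g", sample_id=str(i), cds_position=1,
                               ref_base=r, alt_base=a)
            for i, (r, a) in enumerate(pairs)
        ]
        spec = cat.substitution_spectrum(recs)
        assert all(v == pytest.approx(1 / 6) for v in spec.values())

    def test_planted_ct_dominance(self, skewed_signature):
        rng = np.random.default_rng(2)
        gene = simulate.random_coding_gene(200, rng, gene="G")
        recs, _ = simulate.make_mutation_cohort(gene, skewed_signature, 500, seed=4)
        spec = cat.substitution_spectrum(recs)
        assert max(spec, key=spec.get) == "C>T"


class TestTableReaders:
    def test_simple_tsv_fixture(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene\tcds_pos\tref\talt\tsample\tprotein_change\n"
            "TOY\t5\tC\tT\ts1\tA2V\n"
            "TOY\t6\tT\tC\ts2\tA2=\n"
            "TOY\t4\tG\tT\ts3\tA2S\n"
        )
        records, rejects = cat.read_mutation_table(path, "simple_tsv")
        assert len(records) == 3 and not rejects
        assert records[0].protein_change == "A2V"
        assert records[0].consequence == "missense"

    def test_unparseable_protein_change_routed_to_rejects(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "Gene name\tMutation CDS\tMutation AA\tSample name\tPrimary site\n"
            "WNT5A\tc.928G>A\tp.V310M\tS1\tlarge_intestine\n"
            "WNT5A\tc.10_12del\tp.?\tS2\tlarge_intestine\n"
        )
        records, rejects = cat.read_mutation_table(path, "cosmic_export")
        assert len(records) == 1
        assert records[0].protein_change == "V310M"
        assert len(rejects) == 1 and "c.10_12del" in rejects[0].reason

    def test_maf_dialect(self, tmp_path):
        path = tmp_path / "m.maf"
        path.write_text(
            "Hugo_Symbol\tHGVSc\tHGVSp_Short\tTumor_Sample_Barcode\n"
            "TOY\tc.5C>T\tp.A2V\tTCGA-01\n"
        )
        records, rejects = cat.read_mutation_table(path, "maf_like")
        assert len(records) == 1 and not rejects
        assert records[0].cds_position == 5 and records[0].alt_base == "T"

    def test_unknown_dialect_raises(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\n")
        with pytest.raises(ValueError, match="dialect"):
            cat.read_mutation_table(path, "vcfish")

    def test_reference_mismatch_rejected_loudly(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tcds_pos\tref\talt\tsample\nTOY\t5\tG\tT\ts1\n")
        records, rejects = cat.read_mutation_table(path, genes={"TOY": TOY})
        assert not records and len(rejects) == 1

    def test_generator_round_trip(self, tmp_path, uniform_signature):
        gene = simulate.random_coding_gene(80, 9, gene="RT")
        recs, _ = simulate.make_mutation_cohort(gene, uniform_signature, 500, seed=1)
        path = tmp_path / "cohort.tsv"
        cat.write_simple_tsv(recs, path)
        back, rejects = cat.read_mutation_table(path, genes={"RT": gene})
        assert not rejects
        assert back == recs


class TestCodingGeneInvariants:
    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            cat.CodingGene(gene="g", cds="ATGTAAAAA")

    def test_non_triplet_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            cat.CodingGene(gene="g", cds="ATGA")
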