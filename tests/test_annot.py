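import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_seq
from savmir import annot
from savmir._seq import revcomp
from savmir.annot import (Hit, MirnaAnnotation, ReferenceIndex, assign_families,
                          classify, extract_seed, fold_hairpin, match_le1,
                          subtract, validate_hairpin)
from savmir.synthio import embed_hairpin

LET7 = "TGAGGTAGTAGGTTGTATAGTT"


def brute_force_hits(tag, sequences, genome_kind):
    """Independent oracle: exhaustive Hamming scan of all positions/strands."""
    hits = []
    queries = [(tag, "+")]
    if genome_kind:
        queries.append((revcomp(tag), "-"))
    for rid, ref in sequences.items():
        for query, strand in queries:
            for start in range(len(ref) - len(tag) + 1):
                window = ref[start:start + len(tag)]
                mm = sum(a != b or a == "N" for a, b in zip(query, window))
                if mm <= 1:
                    hits.append((rid, start, strand, mm))
    return sorted(hits)


class TestMatchLe1:
    def test_exact_hit(self):
        idx = ReferenceIndex("m", {"ref1": "AAAA" + LET7 + "CCCC"}, "mature")
        hits = match_le1(LET7, idx)
        assert hits == [Hit("ref1", 4, "+", 0)]

    def test_two_mismatches_no_hit(self):
        mutated = "CC" + LET7[2:]
        idx = ReferenceIndex("m", {"only": LET7}, "mature")
        assert match_le1(mutated, idx) == []

    def test_short_tag_rejected(self):
        idx = ReferenceIndex("m", {"r": LET7}, "mature")
        with pytest.raises(ValueError):
            match_le1("ACGTACGTACGT", idx)

    def test_brute_force_oracle(self, rng):
        genome = {"chr1": random_seq(rng, 2000), "chr2": random_seq(rng, 500)}
        idx = ReferenceIndex("g", genome, "genome")
        for _ in range(50):
            if rng.random() < 0.5:
                tag = random_seq(rng, 20)
            else:  # planted, possibly mutated, possibly reverse strand
                start = int(rng.integers(0, 1980))
                tag = genome["chr1"][start:start + 20]
                if rng.random() < 0.5:
                    pos = int(rng.integers(0, 20))
                    tag = tag[:pos] + "ACGT"[int(rng.integers(4))] + tag[pos + 1:]
                if rng.random() < 0.5:
                    tag = revcomp(tag)
            got = sorted((h.ref_id, h.start, h.strand, h.mismatches)
                         for h in match_le1(tag, idx))
            assert got == brute_force_hits(tag, genome, True)

    def test_revcomp_strand_symmetry(self, rng):
        genome = {"chr1": random_seq(rng, 1000)}
        idx = ReferenceIndex("g", genome, "genome")
        start = int(rng.integers(0, 980))
        tag = genome["chr1"][start:start + 20]
        plus = {(h.ref_id, h.start) for h in match_le1(tag, idx) if h.strand == "+"}
        minus = {(h.ref_id, h.start) for h in match_le1(revcomp(tag), idx)
                 if h.strand == "-"}
        assert plus == minus


class TestSubtract:
    def test_decoy_hit_removed(self):
        trna = "GGGCGTGTGGCGTAGTCGGTAGCGCGCTCCCTTAGCATGGGAGAGG"
        idx = ReferenceIndex("ncrna", {"trna1": trna}, "ncrna")
        kept, removed = subtract([trna[5:30], LET7], idx)
        assert removed == [trna[5:30]]
        assert kept == [LET7]

    def test_partition_exhaustive(self, rng):
        idx = ReferenceIndex("rep", {"r": random_seq(rng, 300)}, "repeat")
        tags = [random_seq(rng, 20) for _ in range(20)]
        kept, removed = subtract(tags, idx)
        assert sorted(kept + removed) == sorted(tags)

    def test_wrong_kind_rejected(self):
        idx = ReferenceIndex("g", {"chr": "ACGT" * 100}, "genome")
        with pytest.raises(ValueError):
            subtract([LET7], idx)

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndex("empty", {}, "ncrna")


class TestExtractSeed:
    def test_let7_seed(self):
        assert extract_seed(LET7) == "GAGGTAG"

    def test_length_eight(self):
        assert extract_seed("ACGTACGT") == "CGTACGT"

    def test_too_short(self):
        with pytest.raises(ValueError):
            extract_seed("ACGTACG")


class TestFamilies:
    def _ann(self, mid, seq):
        return MirnaAnnotation(mid, seq, "conserved", extract_seed(seq))

    def test_shared_seed_one_family(self):
        a = self._ann("mir-a", "TGAGGTAGTAGGTTGTATAGTT")
        b = self._ann("mir-b", "TGAGGTAGTTGGTTGTATAG")  # same positions 2-8
        fam = assign_families([a, b])
        assert len(fam) == 1
        assert fam.iloc[0]["size"] == 2
        assert fam.iloc[0]["family"] == "mir-a"  # lexicographically smallest id

    def test_empty(self):
        assert len(assign_families([])) == 0

    def test_distinct_seed_count_oracle(self, rng):
        anns = [self._ann(f"m{i}", random_seq(rng, 22)) for i in range(30)]
        fam = assign_families(anns)
        assert len(fam) == len({a.family_seed for a in anns})
        assert fam["size"].sum() == 30


class TestFold:
    def test_polya_no_structure(self):
        f = fold_hairpin("A" * 60)
        assert f.structure == "." * 60
        assert f.mfe == 0.0 and f.stem_pairs == 0

    def test_gc_stem_beats_threshold(self):
        seq = "G" * 20 + "A" * 8 + "C" * 20
        f = fold_hairpin(seq)
        # closed-form oracle for the designed structure: 20 GC pairs with 19
        # stacks and an 8-nt loop bounds the MFE from above
        designed = 20 * -3.0 + 19 * -0.5 + (1.5 + 0.1 * 8)
        assert f.mfe <= designed + 1e-9
        assert f.mfe < -18
        assert f.stem_pairs >= 16

    def test_alphabet_error(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 10 + "X" + "ACGT" * 5)

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 5)  # 20 nt

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=40, max_size=90))
    def test_structure_always_balanced_with_min_loop(self, seq):
        f = fold_hairpin(seq)
        assert len(f.structure) == len(seq)
        assert f.structure.count("(") == f.structure.count(")")
        assert f.mfe <= 0.0
        if f.stem_pairs:
            assert f.loop_length >= 3  # steric constraint
            i, j = max(f.pairs)
            assert j - i - 1 == f.loop_length


class TestValidateHairpin:
    def test_designed_precursor_passes(self):
        prec = embed_hairpin(LET7, seed=3)
        start = prec.find(LET7)
        chk = validate_hairpin(fold_hairpin(prec), (start, start + len(LET7)))
        assert chk.passed and chk.reasons == []
        assert chk.mature_arm == "5p"

    def test_weak_mfe_fails(self):
        prec = embed_hairpin(LET7, seed=3)
        start = prec.find(LET7)
        chk = validate_hairpin(fold_hairpin(prec), (start, start + len(LET7)),
                               max_mfe=-100.0)
        assert not chk.passed
        assert any("mfe" in r for r in chk.reasons)

    def test_loop_centred_mature_fails(self):
        seq = "G" * 25 + "A" * 12 + "C" * 25
        fold = fold_hairpin(seq)
        chk = validate_hairpin(fold, (20, 40))  # spans the loop
        assert not chk.passed
        assert any("placement" in r for r in chk.reasons)

    def test_unstructured_fails(self):
        chk = validate_hairpin(fold_hairpin("A" * 60), (5, 27))
        assert not chk.passed

    def test_coordinate_error(self):
        fold = fold_hairpin("A" * 60)
        with pytest.raises(ValueError):
            validate_hairpin(fold, (50, 70))


class TestClassify:
    @pytest.fixture()
    def refs(self, rng):
        prec = embed_hairpin(LET7, seed=9)
        genome_seq = random_seq(rng, 400) + prec + random_seq(rng, 400)
        mirbase = ReferenceIndex("mb", {"mat:let7": LET7, "pre:let7": prec},
                                 "mature")
        genome = ReferenceIndex("g", {"chr1": genome_seq}, "genome")
        return mirbase, genome

    def test_both_hits_conserved(self, refs):
        mirbase, genome = refs
        cls = classify(LET7, mirbase, genome)
        assert cls.label == "conserved"
        assert cls.mirbase_hit is not None and cls.genome_hits

    def test_mirbase_only_semi_conserved(self, rng):
        mirbase = ReferenceIndex("mb", {"mat:let7": LET7}, "mature")
        genome = ReferenceIndex("g", {"chr1": random_seq(rng, 500)}, "genome")
        assert classify(LET7, mirbase, genome).label == "semi-conserved"

    def test_genome_only_valid_hairpin_novel(self, rng):
        novel = "TCGGATCCGTTAGCAATCGAC"
        prec = embed_hairpin(novel, seed=21)
        genome_seq = random_seq(rng, 300) + prec + random_seq(rng, 300)
        mirbase = ReferenceIndex("mb", {"mat:let7": LET7}, "mature")
        genome = ReferenceIndex("g", {"chr1": genome_seq}, "genome")
        cls = classify(novel, mirbase, genome, fold_check=True)
        assert cls.label == "novel" and cls.hairpin_valid

    def test_genome_only_without_hairpin_not_novel(self, rng):
        # purine-only genome: no Watson-Crick/GU pairs, so no hairpin exists
        genome_seq = "".join(rng.choice(list("AG"), size=600))
        tag = genome_seq[100:122]
        mirbase = ReferenceIndex("mb", {"mat:let7": LET7}, "mature")
        genome = ReferenceIndex("g", {"chr1": genome_seq}, "genome")
        cls = classify(tag, mirbase, genome, fold_check=True)
        assert cls.label in {"semi-conserved"}  # falls back, never novel
        assert cls.hairpin_valid is False

    def test_no_hits_unclassified(self, rng):
        mirbase = ReferenceIndex("mb", {"mat:let7": LET7}, "mature")
        genome = ReferenceIndex("g", {"chr1": random_seq(rng, 500)}, "genome")
        assert classify("TTACGGACCGGTTACGGATCCA", mirbase, genome).label == "unclassified"

    def test_total_function_on_bundle(self, small_bundle):
        """Every spiked conserved mature -> conserved; others -> novel."""
        conserved_ids = [m for m, c in small_bundle.conserved.items() if c]
        mb_seqs = {f"mat:{m}": small_bundle.matures[m] for m in conserved_ids}
        mb_seqs.update({f"pre:{small_bundle.mature_precursor[m]}":
                        small_bundle.precursors[small_bundle.mature_precursor[m]]
                        for m in conserved_ids})
        mirbase = ReferenceIndex("mb", mb_seqs, "mature")
        genome = ReferenceIndex("g", small_bundle.genome, "genome")
        for mid, mature in small_bundle.matures.items():
            cls = classify(mature, mirbase, genome, fold_check=True)
            expected = "conserved" if small_bundle.conserved[mid] else "novel"
            assert cls.label == expected, (mid, cls.label, cls.hairpin_valid)
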