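import numpy as np
import pytest

from mars.errors import DataError, ReferenceError
from mars.origin_mapping import (
    ReferenceCollection,
    biotype_summary,
    categorize,
    match_exact,
    match_hamming1,
    match_hamming1_brute,
    translate_frames,
)

#: codons for a minimal reverse translation (one codon per residue)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT", "P": "CCT",
    "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG",
    "Y": "TAT",
}


def reverse_translate(peptide):
    return "".join(CODON[aa] for aa in peptide)


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path


class TestTranslateFrames:
    def test_codon_table_and_min_length(self):
        frags = translate_frames("ATGGCTAAA", mode="three_frame", min_fragment=1)
        frame0 = [f for f in frags if f.frame == 0]
        assert frame0[0].peptide == "MAK"
        # the default 8-aa floor discards it
        assert translate_frames("ATGGCTAAA", mode="three_frame") == []

    def test_six_frame_count_on_open_sequence(self):
        # poly-GCT translates without stops in every frame on both strands
        seq = "GCT" * 20
        frags = translate_frames(seq, mode="six_frame")
        assert len(frags) == 6
        assert {(f.strand, f.frame) for f in frags} == {
            (s, f) for s in "+-" for f in range(3)
        }

    def test_stop_codon_splits_fragments(self):
        pep_a, pep_b = "MAKLMAKV", "GHKLMNPQ"
        seq = reverse_translate(pep_a) + "TAA" + reverse_translate(pep_b)
        frags = [
            f
            for f in translate_frames(seq, mode="three_frame")
            if f.frame == 0
        ]
        assert [f.peptide for f in frags] == [pep_a, pep_b]
        assert frags[0].nt_start == 0
        assert frags[1].nt_start == 3 * len(pep_a) + 3

    def test_n_codons_break_fragments(self):
        seq = reverse_translate("MAKLMAKV") + "ANA" + reverse_translate("GHKLMNPQ")
        frags = [f for f in translate_frames(seq, "three_frame") if f.frame == 0]
        assert [f.peptide for f in frags] == ["MAKLMAKV", "GHKLMNPQ"]

    def test_non_dna_rejected(self):
        with pytest.raises(DataError, match="non-DNA"):
            translate_frames("ATGU")

    def test_reverse_strand_embedding_found(self, tmp_path):
        # embedding a peptide's codons reverse-complemented must surface it
        from Bio.Seq import Seq

        pep = "KLMNPQRV"
        coding = reverse_translate(pep)
        rc = str(Seq(coding).reverse_complement())
        frags = translate_frames("GGGG" + rc + "GGGG", mode="six_frame")
        assert any(pep in f.peptide for f in frags if f.strand == "-")


class TestMatchExact:
    def _coll(self, tmp_path, entries):
        return ReferenceCollection.from_protein_fasta(
            write_fasta(tmp_path / "p.fasta", entries)
        )

    def test_full_entry_hit_at_offset_zero(self, tmp_path):
        coll = self._coll(tmp_path, [("p1", "KLMNPQRVW")])
        (hit,) = match_exact("KLMNPQRVW", coll)
        assert (hit.entry_id, hit.offset) == ("p1", 0)

    def test_repeated_occurrence(self, tmp_path):
        coll = self._coll(tmp_path, [("p1", "AKLMNPQRVWGGGAKLMNPQRVW")])
        hits = match_exact("KLMNPQRVW", coll)
        assert [h.offset for h in hits] == [1, 14]

    def test_il_collapse_both_sides(self, tmp_path):
        # database entry spelled with I must match an L-collapsed query
        coll = self._coll(tmp_path, [("p1", "XVIITDVFQKX")])
        hits = match_exact("VLLTDVFQK", coll)
        assert len(hits) == 1

    def test_embedded_lncrna_translation_hit(self, tmp_path):
        # embed the coding sequence of a 9-mer into a transcript background
        pep = "VLLTDVFQK"
        transcript = "GGGC" + reverse_translate(pep) + "CGGG"
        path = write_fasta(
            tmp_path / "t.fasta", [("snhg6-like biotype=lncRNA src=transcriptome", transcript)]
        )
        coll = ReferenceCollection.from_nucleotide_fasta(path)
        hits = match_exact(pep, coll)
        assert hits and all(h.biotype == "lncRNA" for h in hits)


class TestMatchHamming1:
    def test_single_substitution_reported(self, tmp_path):
        coll = ReferenceCollection.from_protein_fasta(
            write_fasta(tmp_path / "p.fasta", [("p1", "GGGAAAAAAAARGGG")])
        )
        (hit,) = match_hamming1("AAAAAAAAK", coll)
        assert hit.offset == 3
        assert hit.sub_position == 8
        assert (hit.query_residue, hit.ref_residue) == ("K", "R")

    def test_distance_two_not_reported(self, tmp_path):
        coll = ReferenceCollection.from_protein_fasta(
            write_fasta(tmp_path / "p.fasta", [("p1", "AAAAAAARR")])
        )
        assert match_hamming1("AAAAAAAKK", coll) == []

    def test_exact_match_not_reported_as_hamming1(self, tmp_path):
        coll = ReferenceCollection.from_protein_fasta(
            write_fasta(tmp_path / "p.fasta", [("p1", "KLMNPQRVW")])
        )
        assert match_hamming1("KLMNPQRVW", coll) == []
        assert match_exact("KLMNPQRVW", coll)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pigeonhole_equals_brute_force(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        aas = np.array(list("ACDEFGHKLMNPQRSTVWY"))
        text = "".join(rng.choice(aas, 3000))
        coll = ReferenceCollection.from_protein_fasta(
            write_fasta(tmp_path / f"r{seed}.fasta", [("ref", text)])
        )
        for _ in range(25):
            if rng.random() < 0.5:
                peptide = "".join(rng.choice(aas, int(rng.integers(8, 14))))
            else:  # planted near-match: mutate a window of the reference
                start = int(rng.integers(0, 2980))
                length = int(rng.integers(8, 14))
                window = list(text[start : start + length])
                pos = int(rng.integers(length))
                window[pos] = "W" if window[pos] != "W" else "Y"
                peptide = "".join(window)
            assert match_hamming1(peptide, coll) == match_hamming1_brute(
                peptide, coll
            )


class TestCategorize:
    @pytest.fixture()
    def collections(self, tmp_path):
        protein = ReferenceCollection.from_protein_fasta(
            write_fasta(
                tmp_path / "prot.fasta",
                [
                    ("prot1 biotype=protein_coding", "GGGGKLMNPQRVWGGGG"),
                    ("prot2", "AAAAAAAAKCCCC"),
                ],
            )
        )
        lnc_pep, pseudo_pep = "VLLTDVFQK", "MTMSTLLSK"
        nc = ReferenceCollection.from_nucleotide_fasta(
            write_fasta(
                tmp_path / "nc.fasta",
                [
                    ("lnc1 biotype=lncRNA", "GGGC" + reverse_translate(lnc_pep) + "CGGG"),
                    ("ps1 biotype=pseudogene", "GGGC" + reverse_translate(lnc_pep) + "CGGG"),
                    ("lnc2 biotype=lncRNA", "GGGC" + reverse_translate(pseudo_pep) + "CGGG"),
                    # the canonical peptide also appears inside a lncRNA frame
                    ("lnc3 biotype=lncRNA", "GGGC" + reverse_translate("KLMNPQRVW") + "CGGG"),
                ],
            )
        )
        return protein, nc

    def test_canonical_takes_precedence_over_noncanonical(self, collections):
        protein, nc = collections
        a = categorize("KLMNPQRVW", protein, nc)
        assert a.category == "HumanProtein"

    def test_one_substitution(self, collections):
        protein, nc = collections
        a = categorize("AAAAAAAAR", protein, nc)
        assert a.category == "OneAASubstitution"
        assert a.hits[0].sub_position == 8

    def test_noncanonical_multilabel_biotypes(self, collections):
        protein, nc = collections
        a = categorize("VLLTDVFQK", protein, nc)
        assert a.category == "NonCanonical"
        assert a.biotypes == {"lncRNA", "pseudogene"}

    def test_unmatched(self, collections):
        protein, nc = collections
        assert categorize("WWWWWWWWW", protein, nc).category == "Unmatched"

    def test_counts_invariant_to_entry_order(self, collections, tmp_path):
        protein, nc = collections
        reversed_nc = ReferenceCollection(list(reversed(nc.entries)))
        peps = ["KLMNPQRVW", "AAAAAAAAR", "VLLTDVFQK", "MTMSTLLSK", "WWWWWWWWW"]
        a1 = [categorize(p, protein, nc).category for p in peps]
        a2 = [categorize(p, protein, reversed_nc).category for p in peps]
        assert a1 == a2

    def test_summary_tables(self, collections):
        protein, nc = collections
        peps = ["KLMNPQRVW", "AAAAAAAAR", "VLLTDVFQK", "MTMSTLLSK", "WWWWWWWWW"]
        assignments = [categorize(p, protein, nc) for p in peps]
        cat_df, combo_df = biotype_summary(assignments)
        counts = dict(zip(cat_df["category"], cat_df["count"]))
        assert counts == {
            "HumanProtein": 1,
            "OneAASubstitution": 1,
            "NonCanonical": 2,
            "Unmatched": 1,
        }
        combos = dict(zip(combo_df["biotypes"], combo_df["count"]))
        assert combos == {"lncRNA+pseudogene": 1, "lncRNA": 1}

    def test_empty_summary(self):
        cat_df, combo_df = biotype_summary([])
        assert cat_df.empty and combo_df.empty


def test_empty_reference_rejected(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    with pytest.raises(ReferenceError):
        ReferenceCollection.from_protein_fasta(path)
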