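import collections

import numpy as np
import pytest

from massnovo.grounding import (
    DecoyDatabase,
    ProteomeIndex,
    assign_cluster_peptides,
    blosum62_score,
    blosum62_stats,
    ground_predictions,
    match_one_mismatch,
    snp_explainable,
    snp_explainable_fraction,
)

PROTEINS = [
    "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
    "GAVLIPFWMSTCYNQDEKRH" * 3,
]


class TestDecoyDatabase:
    def test_decoys_preserve_length_and_composition(self):
        db = DecoyDatabase.from_sequences(
            [(f"p{i}", s) for i, s in enumerate(PROTEINS)], seed=1
        )
        for target, decoy in zip(db.targets, db.decoys):
            assert len(decoy) == len(target)
            assert collections.Counter(decoy) == collections.Counter(target)

    def test_seed_reproducible(self):
        pairs = [(f"p{i}", s) for i, s in enumerate(PROTEINS)]
        assert (
            DecoyDatabase.from_sequences(pairs, seed=7).decoys
            == DecoyDatabase.from_sequences(pairs, seed=7).decoys
        )

    def test_il_collapsed_matching(self):
        db = DecoyDatabase.from_sequences([("p", "AGIKW")], seed=0)
        assert db.matches_target("GLK")  # I matched via L equivalence

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            DecoyDatabase.from_sequences([], seed=0)

    def test_fasta_round_trip(self, tmp_path):
        db = DecoyDatabase.from_sequences([("prot1", PROTEINS[0])], seed=3)
        path = tmp_path / "db.fa"
        db.write_fasta(path)
        text = path.read_text()
        assert ">prot1" in text and ">decoy_prot1" in text
        back = DecoyDatabase.from_fasta(path, seed=3)
        assert back.targets[0] == PROTEINS[0]


class TestGroundPredictions:
    def test_all_targets_accepted_when_no_decoy_matches(self):
        db = DecoyDatabase.from_sequences([("p", PROTEINS[0])], seed=0)
        preds = [("MKTAYIAK", 0.9), ("QRQISFVK", 0.5), ("SHFSRQLE", 0.2)]
        result = ground_predictions(preds, db, alpha=0.01)
        assert all(g.label == "target" for g in result.peptides)
        assert all(g.accepted for g in result.peptides)

    def test_cutoff_stops_before_alpha_exceeded(self):
        """Constructed stratum: ranks alternate target/decoy so D_k/T_k
        crosses alpha at the first decoy."""
        db = DecoyDatabase.from_sequences([("p", "AAAAGGGGWWWW")], seed=0)
        db.decoys = ["CCCCHHHHYYYY"]  # force known decoy content
        preds = [
            ("AAAG", 0.9),  # target
            ("CCCH", 0.8),  # decoy
            ("GGGW", 0.7),  # target
            ("HHHY", 0.6),  # decoy
        ]
        result = ground_predictions(preds, db, alpha=0.01)
        assert result.cutoffs[4] == 1
        accepted = [g.peptide for g in result.accepted]
        assert accepted == ["AAAG"]

    def test_alpha_zero_with_zero_decoys_accepts_all(self):
        db = DecoyDatabase.from_sequences([("p", PROTEINS[0])], seed=0)
        preds = [("MKTAYIAK", 0.9), ("QRQISFVK", 0.5)]
        result = ground_predictions(preds, db, alpha=0.0)
        assert all(g.accepted for g in result.peptides)

    def test_alpha_zero_stops_at_first_decoy(self):
        db = DecoyDatabase.from_sequences([("p", "AAAAGGGG")], seed=0)
        db.decoys = ["CCCCHHHH"]
        preds = [("AAAG", 0.9), ("CCCH", 0.8), ("AAGG", 0.7)]
        result = ground_predictions(preds, db, alpha=0.0)
        assert [g.peptide for g in result.accepted] == ["AAAG"]

    def test_both_match_resolved_by_seed(self):
        db = DecoyDatabase.from_sequences([("p", "AAAAAAA")], seed=0)
        db.decoys = ["AAAAAAA"]
        labels = {
            ground_predictions([("AAAA", 0.9)], db, seed=s).peptides[0].label
            for s in range(20)
        }
        assert labels == {"target", "decoy"}
        one = ground_predictions([("AAAA", 0.9)], db, seed=3).peptides[0].label
        two = ground_predictions([("AAAA", 0.9)], db, seed=3).peptides[0].label
        assert one == two

    def test_unmatched_labelled_none(self):
        db = DecoyDatabase.from_sequences([("p", PROTEINS[0])], seed=0)
        result = ground_predictions([("WWWWWWWW", 0.9)], db)
        assert result.peptides[0].label == "none"
        assert not result.peptides[0].accepted


class TestClusterAssignment:
    PROTEOME = ["AAAGGGKWWW", "CCCHHHK"]

    def test_plurality_vs_proteome_first(self):
        clusters = {"c1": ["AAAGGGK", "AAAGGGK", "CCCHHHK"]}
        plural = assign_cluster_peptides(clusters, self.PROTEOME, "plurality_first")
        assert plural == {"c1": "AAAGGGK"}
        unanimous = assign_cluster_peptides(clusters, self.PROTEOME, "proteome_first")
        assert unanimous == {}  # the dissenting CCCHHHK blocks unanimity

    def test_single_spectrum_cluster_unassigned(self):
        clusters = {"c1": ["AAAGGGK"]}
        for mode in ("plurality_first", "proteome_first"):
            assert assign_cluster_peptides(clusters, self.PROTEOME, mode) == {}

    def test_two_agreeing_spectra_assigned_both_modes(self):
        clusters = {"c1": ["AAAGGGK", "AAAGGGK"]}
        for mode in ("plurality_first", "proteome_first"):
            assert assign_cluster_peptides(clusters, self.PROTEOME, mode) == {
                "c1": "AAAGGGK"
            }

    def test_plurality_tie_unassigned(self):
        clusters = {"c1": ["AAAGGGK", "AAAGGGK", "CCCHHHK", "CCCHHHK"]}
        assert (
            assign_cluster_peptides(clusters, self.PROTEOME, "plurality_first") == {}
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            assign_cluster_peptides({}, self.PROTEOME, "majority")


class TestOneMismatchMatching:
    def test_exact_match_distance_zero(self):
        calls = match_one_mismatch("TAYIAK", [PROTEINS[0]])
        assert len(calls) == 1
        assert calls[0].exact

    def test_single_mismatch_reports_pair(self):
        calls = match_one_mismatch("TAYWAK", [PROTEINS[0]])
        assert len(calls) == 1
        assert not calls[0].exact
        assert (calls[0].from_residue, calls[0].to_residue) == ("I", "W")

    def test_two_mismatches_no_call(self):
        assert match_one_mismatch("TWYWAK", [PROTEINS[0]]) == []

    def test_il_equivalence_not_a_mismatch(self):
        calls = match_one_mismatch("TAYLAK", [PROTEINS[0]])  # I in protein
        assert len(calls) == 1 and calls[0].exact


class TestSubstitutionPlausibility:
    def test_d_to_e_single_nucleotide(self):
        assert snp_explainable("D", "E")  # GAT -> GAA

    def test_m_to_w_not_single_nucleotide(self):
        assert not snp_explainable("M", "W")  # ATG vs TGG differ at >= 2

    def test_symmetry(self):
        for a, b in [("A", "G"), ("K", "R"), ("F", "Y"), ("M", "W")]:
            assert snp_explainable(a, b) == snp_explainable(b, a)

    def test_identical_residues_rejected(self):
        with pytest.raises(ValueError):
            snp_explainable("A", "A")

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            snp_explainable("A", "B")

    def test_fraction_standard_twenty(self):
        # 150 of the 380 ordered pairs of the 20 standard residues
        assert snp_explainable_fraction(include_selenocysteine=False) == pytest.approx(
            150 / 380
        )

    def test_fraction_with_selenocysteine(self):
        # 162 of 420 ordered pairs once U (UGA-recoded) is included
        assert snp_explainable_fraction() == pytest.approx(162 / 420)


class TestBlosum62:
    def test_positive_offdiagonal_fraction(self):
        frac, _ = blosum62_stats()
        assert frac == pytest.approx(42 / 380)

    def test_il_score(self):
        assert blosum62_score("I", "L") == 2

    def test_symmetry(self):
        _, scores = blosum62_stats()
        for (a, b), v in scores.items():
            assert scores[(b, a)] == v
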