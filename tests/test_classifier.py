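"""Naive-Bayes word classifier: word extraction, training maths, bootstrap."""

import math

import numpy as np
import pytest

from amplipair.amplicon import make_fragment
from amplipair.classifier import (
    UNCLASSIFIED,
    WordModel,
    assign_with_threshold,
    classify,
    classify_fragments,
    extract_words,
    train,
)
from amplipair.taxonomy import ReferenceDB, ReferenceRecord, parse_lineage


class TestExtractWords:
    def test_plain_windows(self):
        assert extract_words("ACGTACGTA") == ["ACGTACGT", "CGTACGTA"]

    def test_no_window_clears_the_joint(self):
        assert extract_words("AAAA" + "N" * 8 + "CCCC") == []

    def test_windows_never_span_the_joint(self):
        # enumerated by hand: 3 windows per 10 bp flank, none containing N
        words = extract_words("ACGTACGTAC" + "N" * 8 + "GTACGTACGT")
        assert len(words) == 6
        assert words[:3] == ["ACGTACGT", "CGTACGTA", "GTACGTAC"]
        assert all("N" not in w for w in words)

    def test_ambiguity_codes_skipped(self):
        assert extract_words("ACGTRACGT", k=4) == ["ACGT", "ACGT"]

    def test_k_validation(self):
        with pytest.raises(ValueError):
            extract_words("ACGT", k=0)


def _db(*entries):
    records = []
    for i, (taxon, seq) in enumerate(entries):
        records.append(
            ReferenceRecord(f"r{i}", seq, parse_lineage(f"Bacteria;P1;C;O;F;G;{taxon}"))
        )
    return ReferenceDB(records)


class TestTrain:
    def test_word_prior_and_conditional_formulas(self):
        # 4 training sequences, k=4; word AAAA occurs in r0 only.
        # P(AAAA) = (1 + 0.5) / 5 = 0.3
        # taxon sA has 2 sequences, one containing AAAA:
        #   P(AAAA|sA) = (1 + 0.3) / 3
        db = _db(("sA", "AAAACCCC"), ("sA", "CCCCGGGG"),
                 ("sB", "GGGGTTTT"), ("sB", "TTTTCCCC"))
        model = train(db, k=4)
        code = sum({"A": 0, "C": 1, "G": 2, "T": 3}[b] * 4 ** (3 - i) for i, b in enumerate("AAAA"))
        j = int(np.searchsorted(model.vocab, code))
        assert model.vocab[j] == code
        ti = model.taxa.index("sA")
        assert model.log_cond[ti, j] == pytest.approx(math.log((1 + 0.3) / 3))
        tj = model.taxa.index("sB")
        assert model.log_cond[tj, j] == pytest.approx(math.log((0 + 0.3) / 3))

    def test_unseen_word_prior_at_m_zero(self):
        # 9 training sequences: unseen-word prior = 0.5/10 = 0.05
        db = _db(*[(f"s{i}", "ACGT" * 10 + "AC" * i) for i in range(9)])
        model = train(db, k=8)
        assert model.n_train == 9
        for ti in range(len(model.taxa)):
            expected = math.log(0.05) - math.log(model.taxon_counts[ti] + 1)
            assert model.log_unseen[ti] == pytest.approx(expected)

    def test_identical_taxa_get_identical_conditionals(self):
        db = _db(("sA", "ACGTACGTACGT"), ("sB", "ACGTACGTACGT"))
        model = train(db, k=8)
        a, b = model.taxa.index("sA"), model.taxa.index("sB")
        assert np.allclose(model.log_cond[a], model.log_cond[b])

    def test_missing_rank_rejected(self):
        rec = ReferenceRecord("x", "ACGT" * 4, parse_lineage("Bacteria;P1"))
        with pytest.raises(ValueError, match="species"):
            train(ReferenceDB([rec]))


class TestClassify:
    def test_single_taxon_model_full_confidence(self):
        db = _db(("sA", "ACGTTGCAACGTTGCA"))
        model = train(db, k=8)
        cls = classify(model, "ACGTTGCAACGT", seed=0)
        assert cls.winner == "sA"
        assert all(conf == 1.0 for _, conf in cls.assignments.values())

    def test_all_ambiguous_fragment_unclassifiable(self, species_model):
        cls = classify(species_model, "N" * 40, seed=0)
        assert not cls.classifiable
        assert assign_with_threshold(cls, "species") == UNCLASSIFIED

    def test_training_sequence_recovers_own_taxon(self, db, species_model):
        rec = next(iter(db))
        cls = classify(species_model, rec.sequence, rec.id, seed=1)
        assert cls.winner == rec.lineage.name_at("species")
        assert cls.assignments["species"][1] >= 0.9

    def test_deterministic_and_order_independent(self, db, species_model):
        recs = list(db)[:3]
        frags = [(r.id, r.sequence[:400]) for r in recs]
        a = classify_fragments(species_model, frags, seed=4)
        b = classify_fragments(species_model, list(reversed(frags)), seed=4)
        by_id = {c.fragment_id: c for c in b}
        for c in a:
            assert c.assignments == by_id[c.fragment_id].assignments

    def test_shared_word_does_not_change_ranking(self):
        # appending N*8 + w to every sequence adds exactly the word w to each
        # taxon; with equal-size taxa the score shift is constant, so the
        # ranking for any query is unchanged
        entries = [("sA", "ACGTTGCAACGTAGGC"), ("sB", "TTGGCCAATTGGCCAA"),
                   ("sC", "GGGTTTCCCAAAGGGT")]
        shared = "ACACACAC"
        db1 = _db(*entries)
        db2 = _db(*[(t, s + "N" * 8 + shared) for t, s in entries])
        m1, m2 = train(db1, k=8), train(db2, k=8)
        assert m1.taxa == m2.taxa
        for query in ["ACGTTGCAACGTAGGC" + shared, "TTGGCCAATT" + shared]:
            c1 = classify(m1, query, "q", seed=0)
            c2 = classify(m2, query, "q", seed=0)
            assert c1.winner == c2.winner


class TestThreshold:
    @pytest.mark.parametrize(
        "confidence,threshold,assigned",
        [(0.80, 0.8, True), (0.79, 0.8, False), (0.0, 0.0, True)],
    )
    def test_inclusive_threshold(self, confidence, threshold, assigned):
        from amplipair.classifier import Classification

        cls = Classification("f", True, "sA", {"species": ("sA", confidence)})
        result = assign_with_threshold(cls, "species", threshold)
        assert (result == "sA") is assigned


class TestModelPersistence:
    def test_save_load_round_trip(self, species_model, db, tmp_path):
        path = tmp_path / "model.npz"
        species_model.save(path)
        loaded = WordModel.load(path)
        rec = next(iter(db))
        a = classify(species_model, rec.sequence[:500], rec.id, seed=2)
        b = classify(loaded, rec.sequence[:500], rec.id, seed=2)
        assert a.winner == b.winner
        assert a.assignments == b.assignments


class TestAccuracyProperties:
    def test_self_classification_genus_accuracy(self, db, region_map, species_model):
        frags = [
            (r.id, make_fragment(r, region_map, ("V1", "V4")).sequence) for r in db
        ]
        results = classify_fragments(species_model, frags, seed=3)
        correct = sum(
            assign_with_threshold(c, "genus") == db[fid].lineage.name_at("genus")
            for (fid, _), c in zip(frags, results)
        )
        assert correct / len(frags) >= 0.95

    def test_heldout_strain_genus_accuracy(self, db, region_map, heldout_split, heldout_model):
        _, test_ids = heldout_split
        frags = [
            (rid, make_fragment(db[rid], region_map, ("V1", "V4")).sequence)
            for rid in test_ids
        ]
        results = classify_fragments(heldout_model, frags, seed=3)
        correct = sum(
            assign_with_threshold(c, "genus") == db[rid].lineage.name_at("genus")
            for (rid, _), c in zip(frags, results)
        )
        assert correct / len(frags) >= 0.80
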