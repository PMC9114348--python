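import math

import numpy as np
import pytest

from lncpig import codepot
from .conftest import random_seq

STOPS = ("TAA", "TAG", "TGA")


def brute_force_orf(seq):
    """Independent ORF oracle: scan every (ATG, in-frame stop) pair."""
    s = seq.upper().replace("U", "T")
    n = len(s)
    best = (0, 0, -1)  # start, length, integrity
    for start in range(n - 2):
        if s[start : start + 3] != "ATG":
            continue
        end = None
        for j in range(start + 3, n - 2, 3):
            if s[j : j + 3] in STOPS:
                end = j + 3
                break
        if end is not None:
            length, integ = end - start, 1
        else:
            last = start + ((n - start) // 3) * 3
            length, integ = last - start, -1
        if length > best[1]:
            best = (start, length, integ)
    return best


class TestLongestOrf:
    def test_minimal_complete_orf(self):
        assert codepot.longest_orf("ATGAAATAG") == (0, 9, 1.0, 1)

    def test_no_orf(self):
        start, length, cov, integ = codepot.longest_orf("CCCCCC")
        assert length == 0 and cov == 0.0 and integ == -1

    def test_open_ended_orf(self):
        start, length, cov, integ = codepot.longest_orf("ATGAAAAAA")
        assert (start, length, integ) == (0, 9, -1)

    def test_against_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(120):
            seq = random_seq(rng, 300)
            start, length, cov, integ = codepot.longest_orf(seq)
            o_start, o_length, o_integ = brute_force_orf(seq)
            assert (start, length, integ) == (o_start, o_length, o_integ)
            assert cov == pytest.approx(length / 300)


class TestFickett:
    def test_homopolymer_hand_value(self):
        """Hand evaluation of the lookup tables for poly-A: position
        parameter 100/101 and composition 1.0 for A, zero for the rest."""
        assert codepot.fickett_score("A" * 300) == pytest.approx(0.3458)

    def test_case_and_ut_invariance(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 200)
        assert codepot.fickett_score(s) == codepot.fickett_score(s.lower())
        assert codepot.fickett_score(s) == codepot.fickett_score(s.replace("T", "U"))

    def test_bounds_from_tables(self):
        """Scores stay within [sum of weighted min probs, sum of weighted
        max probs] of the lookup tables."""
        rng = np.random.default_rng(1)
        lo = sum(min(codepot._POSITION_PROB[b]) * codepot._POSITION_WEIGHT[b] for b in "ACGT")
        lo += sum(min(codepot._CONTENT_PROB[b]) * codepot._CONTENT_WEIGHT[b] for b in "ACGT")
        hi = sum(max(codepot._POSITION_PROB[b]) * codepot._POSITION_WEIGHT[b] for b in "ACGT")
        hi += sum(max(codepot._CONTENT_PROB[b]) * codepot._CONTENT_WEIGHT[b] for b in "ACGT")
        for _ in range(50):
            s = random_seq(rng, int(rng.integers(30, 500)))
            assert lo <= codepot.fickett_score(s) <= hi


class TestHexamer:
    def test_identical_tables_give_zero(self):
        tab = {"ATGATG": 0.5, "AAAAAA": 0.5}
        rng = np.random.default_rng(2)
        assert codepot.hexamer_ratio(random_seq(rng, 120), tab, tab) == pytest.approx(0.0)

    def test_toy_tables_hand_value(self):
        fc = {"ATGATG": 0.1}
        fn = {"ATGATG": 0.01}
        assert codepot.hexamer_ratio("ATGATGATGATG", fc, fn) == pytest.approx(math.log(10))

    def test_short_sequence_zero(self):
        assert codepot.hexamer_ratio("ATGAT", {}, {}) == 0.0


class TestTrainChannel:
    def test_separable_toy_perfect_accuracy(self):
        X = np.array([[0.0, 0], [0, 1], [5, 0], [5, 1], [0, 2], [5, 2]])
        y = np.array([0, 0, 1, 1, 0, 1])
        ch = codepot.train_channel(X, y)
        pred = codepot.predict_logistic(ch, X) > 0.5
        assert (pred == y.astype(bool)).all()

    def test_duplicated_rows_same_weights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        a = codepot.train_channel(X, y)
        b = codepot.train_channel(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(a["weights"], b["weights"], atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            codepot.train_channel(np.ones((4, 2)), np.zeros(4))

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(400, 4))
        y = rng.integers(0, 2, 400)
        ch = codepot.train_channel(X[:200], y[:200])
        acc = ((codepot.predict_logistic(ch, X[200:]) > 0.5) == y[200:].astype(bool)).mean()
        assert 0.4 <= acc <= 0.6


class TestSelectCutoff:
    def test_separable_enumeration(self):
        scores = np.array([0.7, 0.8, 0.9, 0.1, 0.2, 0.3])
        labels = np.array([1, 1, 1, 0, 0, 0])
        cutoff, info = codepot.select_cutoff(scores, labels, folds=1)
        assert cutoff == pytest.approx(0.3)
        assert info[0]["sensitivity"] == 1.0 and info[0]["specificity"] == 1.0

    def test_interleaved_scores_within_range(self):
        rng = np.random.default_rng(6)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        cutoff, info = codepot.select_cutoff(scores, labels, folds=3, seed=0)
        assert scores.min() <= cutoff <= scores.max()
        assert all(f["sensitivity"] + f["specificity"] - 1 < 1 for f in info)

    def test_same_seed_same_cutoff(self):
        rng = np.random.default_rng(7)
        scores = rng.random(100)
        labels = (scores + rng.normal(0, 0.2, 100) > 0.5).astype(int)
        a, _ = codepot.select_cutoff(scores, labels, folds=10, seed=3)
        b, _ = codepot.select_cutoff(scores, labels, folds=10, seed=3)
        assert a == b


class TestConsensus:
    def test_all_gates_pass(self):
        assert codepot.consensus_rule(0.4, 0.30, -1.0, cpat_cutoff=0.36) == "noncoding"

    def test_cpc2_gate_is_strict(self):
        assert codepot.consensus_rule(0.5, 0.30, -1.0, cpat_cutoff=0.36) == "coding_potential"

    def test_cpat_gate_is_inclusive(self):
        assert codepot.consensus_rule(0.4, 0.36, -1.0, cpat_cutoff=0.36) == "noncoding"

    def test_plek_gate_is_strict(self):
        assert codepot.consensus_rule(0.4, 0.30, 0.0, cpat_cutoff=0.36) == "coding_potential"

    def test_classification_is_pure_function(self):
        from lncpig import syndata

        recs, _, _ = syndata.generate_transcriptome(30, 30, seed=17)
        seqs = [r.sequence for r in recs]
        model = codepot.train_model(seqs[:30], seqs[30:], folds=5, seed=0)
        v1 = [codepot.classify_consensus(s, model) for s in seqs[:10]]
        v2 = [codepot.classify_consensus(s, model) for s in seqs[:10]]
        assert v1 == v2

    def test_model_json_round_trip(self, tmp_path):
        from lncpig import syndata

        recs, _, _ = syndata.generate_transcriptome(20, 20, seed=18)
        seqs = [r.sequence for r in recs]
        model = codepot.train_model(seqs[:20], seqs[20:], folds=5, seed=0)
        p = tmp_path / "model.json"
        model.to_json(str(p))
        back = codepot.CodingPotentialModel.from_json(str(p))
        assert back.cpat_cutoff == model.cpat_cutoff
        s = seqs[0]
        assert codepot.classify_consensus(s, back) == codepot.classify_consensus(s, model)
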