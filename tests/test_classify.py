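"""Naive-Bayes k-mer classifier: training statistics, scoring, bootstrap,
cutoffs, determinism."""

import math

import numpy as np
import pytest

from pollenpipe.classify import (
    ClassifierParams,
    KmerModel,
    apply_cutoff,
    classify,
    classify_sample,
    train,
)
from pollenpipe.refdb import RANKS, Lineage, ReferenceDB

from conftest import make_lineage


def bayes_oracle(db: ReferenceDB, seq: str, k: int):
    """Brute-force naive-Bayes scores: dicts and pure python only."""
    records = [(sid, s, lin.key()) for sid, s, lin in db.records if len(s) >= k]
    n_total = len(records)
    word_sets = {sid: {s[i : i + k] for i in range(len(s) - k + 1)} for sid, s, _ in records}
    all_words = sorted(set().union(*word_sets.values()))
    n_w = {w: sum(1 for ws in word_sets.values() if w in ws) for w in all_words}
    prior = {w: (n_w[w] + 0.5) / (n_total + 1) for w in all_words}
    leaves = {}
    for sid, s, key in records:
        leaves.setdefault(key, []).append(word_sets[sid])
    query_words = {seq[i : i + k] for i in range(len(seq) - k + 1)} & set(all_words)
    scores = {}
    for key, sets in leaves.items():
        M = len(sets)
        total = 0.0
        for w in query_words:
            m_w = sum(1 for ws in sets if w in ws)
            total += math.log((m_w + prior[w]) / (M + 1))
        scores[key] = total
    return scores


class TestTrain:
    def test_single_record_prior(self):
        db = ReferenceDB([("a", "ACG", make_lineage())])
        model = train(db, ClassifierParams(k=2))
        # n(w)=1, N=1 -> P(w) = 1.5/2 for both observed words AC, CG
        assert np.allclose(model.word_prior, 0.75)
        assert set(model.word_index) == {"AC", "CG"}

    def test_duplicate_records_same_leaf(self):
        db = ReferenceDB(
            [("a", "ACGT", make_lineage()), ("b", "ACGT", make_lineage())]
        )
        model = train(db, ClassifierParams(k=2))
        assert model.n_leaves == 1
        assert model.leaf_seq_counts[0] == 2
        # m(w)=2, M=2, P(w)=(2+0.5)/3 -> P(w|leaf)=(2+2.5/3)/3
        expected = math.log((2 + 2.5 / 3) / 3)
        assert np.allclose(model.log_cond, expected)

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            train(ReferenceDB([]), ClassifierParams(k=2))

    def test_short_records_dropped(self):
        db = ReferenceDB(
            [("a", "ACGTACGTAC", make_lineage()), ("b", "ACG", make_lineage(species="s2"))]
        )
        model = train(db, ClassifierParams(k=8))
        assert model.n_leaves == 1

    def test_record_order_invariant(self, toy_db):
        model_fwd = train(toy_db, ClassifierParams(k=4))
        shuffled = ReferenceDB(list(reversed(toy_db.records)))
        model_rev = train(shuffled, ClassifierParams(k=4))
        assert model_fwd.leaf_keys == model_rev.leaf_keys
        assert np.array_equal(model_fwd.log_cond, model_rev.log_cond)


class TestClassify:
    def test_matches_brute_force_oracle(self, toy_db):
        params = ClassifierParams(k=4, n_bootstrap=10, rng_seed=0)
        model = train(toy_db, params)
        for query in ["ACGTACGTACGTACGT", "GGGGCCCCGGGG", "ACGTACGTTTTTGGGG"]:
            oracle = bayes_oracle(toy_db, query, 4)
            res = classify(query, model, params)
            best = min(sorted(oracle), key=lambda k: (-oracle[k], k))
            assert res.leaf_key == best
            assert res.raw_score * res.n_words == pytest.approx(oracle[best], abs=1e-12)

    def test_single_leaf_full_confidence(self):
        db = ReferenceDB([("a", "ACGTACGTACGT", make_lineage())])
        params = ClassifierParams(k=4, n_bootstrap=20)
        res = classify("ACGTACGTACGT", train(db, params), params)
        assert res.confidences == (1.0,) * 7

    def test_self_classification_on_divergent_leaves(self, sim_db):
        params = ClassifierParams(k=8, n_bootstrap=30, rng_seed=3)
        model = train(sim_db, params)
        hits = 0
        for sid, seq, lin in sim_db.records:
            res = classify(seq, model, params, read_id=sid)
            hits += res.leaf_key == lin.key()
        assert hits == len(sim_db)

    def test_training_sequence_high_species_confidence(self, sim_db):
        params = ClassifierParams(k=8, n_bootstrap=100, rng_seed=5)
        model = train(sim_db, params)
        sid, seq, lin = sim_db.records[0]
        res = classify(seq, model, params, read_id=sid)
        assert res.leaf_key == lin.key()
        assert res.confidences[RANKS.index("species")] >= 0.95

    def test_short_read_rejected(self, toy_db):
        params = ClassifierParams(k=8)
        model = train(ReferenceDB([("a", "ACGTACGTAC", make_lineage())]), params)
        with pytest.raises(ValueError, match="shorter than k"):
            classify("ACGT", model, params)

    def test_confidences_monotone_nonincreasing(self, sim_db):
        params = ClassifierParams(k=8, n_bootstrap=50, rng_seed=1)
        model = train(sim_db, params)
        for sid, seq, _ in sim_db.records[:5]:
            res = classify(seq, model, params, read_id=sid)
            assert all(a >= b for a, b in zip(res.confidences, res.confidences[1:]))


class TestCutoff:
    def _result(self, confs, raw_score=0.0):
        from pollenpipe.classify import ClassificationResult

        return ClassificationResult(
            "r", "key", make_lineage(), tuple(confs), raw_score, 10
        )

    def test_low_species_confidence_truncated(self):
        lin = apply_cutoff(self._result([1, 1, 1, 1, 1, 0.9, 0.4]))
        assert lin["genus"] == "g1"
        assert lin["species"] == "unclassified_g1"

    def test_full_confidence_identity(self):
        lin = apply_cutoff(self._result([1.0] * 7))
        assert lin.names == make_lineage().names

    def test_low_raw_score_keeps_kingdom_only(self):
        lin = apply_cutoff(self._result([1.0] * 7, raw_score=-100.0))
        assert lin["kingdom"] == "Plantae"
        assert lin["phylum"] == "unclassified_Plantae"


class TestClassifySample:
    def test_error_free_single_species_reads(self, sim_db):
        from pollenpipe.oligos import synthetic_index_set
        from pollenpipe.readprep import merge_sample
        from pollenpipe.simulate import SimParams, simulate_run

        key = sim_db.records[0][2].key()
        params = SimParams(rng_seed=21, error_rate=0.0)
        run = simulate_run(
            sim_db, {"s1": {key: 100}},
            synthetic_index_set(1, "forward", 2), synthetic_index_set(1, "reverse", 2), params,
        )
        merged, _ = merge_sample(
            (p.id, p.r1_seq, p.r1_qual, p.r2_seq, p.r2_qual) for p in run.pairs
        )
        cparams = ClassifierParams(rng_seed=21)
        model = train(sim_db, cparams)
        table = classify_sample([(m.id, m.seq) for m in merged], model, cparams, with_cutoff=False)
        correct = (table[list(RANKS)].agg(";".join, axis=1) == key).mean()
        assert correct >= 0.95

    def test_empty_read_set(self, toy_db):
        params = ClassifierParams(k=4)
        table = classify_sample([], train(toy_db, params), params)
        assert len(table) == 0
        assert list(table.columns[:8]) == ["read_id"] + list(RANKS)

    def test_seed_determinism_and_order_invariance(self, toy_db):
        params = ClassifierParams(k=4, n_bootstrap=25, rng_seed=9)
        model = train(toy_db, params)
        reads = [("r1", "ACGTACGTACGTACGT"), ("r2", "GGGGCCCCGGGGCC"), ("r3", "ACGTACGTTTTT")]
        t1 = classify_sample(reads, model, params)
        t2 = classify_sample(reads, model, params)
        assert t1.to_csv() == t2.to_csv()
        t3 = classify_sample(reads[::-1], model, params).sort_values("read_id").reset_index(drop=True)
        assert t1.to_csv() == t3.to_csv()


class TestModelSerialization:
    def test_save_load_roundtrip(self, tmp_path, toy_db):
        params = ClassifierParams(k=4, n_bootstrap=10, rng_seed=2)
        model = train(toy_db, params)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = KmerModel.load(path)
        assert loaded.k == model.k
        assert loaded.leaf_keys == model.leaf_keys
        assert np.array_equal(loaded.log_cond, model.log_cond)
        r_a = classify("ACGTACGTACGT", model, params)
        r_b = classify("ACGTACGTACGT", loaded, params)
        assert r_a == r_b
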