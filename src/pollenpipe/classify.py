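"""Naive-Bayes k-mer taxonomic classifier with bootstrap confidence.

The model follows the classic rRNA-classifier scheme.  Training sequences
are grouped by their full seven-rank lineage ("leaf"; usually a species).
For every k-mer *w* seen anywhere in training, a word prior

    P(w) = (n(w) + 0.5) / (N + 1)

is computed, where n(w) counts training sequences containing *w* and N is
the total number of training sequences.  The per-leaf conditional uses the
prior as a pseudocount:

    P(w | leaf) = (m(w) + P(w)) / (M + 1)

with m(w) the number of the leaf's sequences containing *w* and M the
leaf's sequence count.  A query is scored against every leaf by the sum of
log P(w|leaf) over the query's *distinct* k-mers (presence, not
multiplicity); the highest-scoring leaf wins, ties broken by
lexicographically smallest leaf key.

Confidence is estimated by bootstrap: each trial draws ⌊W/8⌋ of the
query's W distinct words with replacement and re-runs the vote; the
confidence at a rank is the fraction of trials whose winner agrees with
the full-word winner at that rank.  A cumulative-minimum pass from kingdom
down makes the reported confidences non-increasing.

The reported ``raw_score`` is the winner's mean log-likelihood per scored
word.  It supports a minimum-score cutoff with the same semantics as the
raw-score floors used by other amplicon classifiers (a read scoring below
the floor keeps only its kingdom); the numeric scale is this model's own
and is not interchangeable with other tools' scores.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refdb import RANKS, Lineage, ReferenceDB, UNCLASSIFIED_PREFIX

__all__ = [
    "ClassifierParams",
    "KmerModel",
    "ClassificationResult",
    "train",
    "classify",
    "apply_cutoff",
    "classify_sample",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierParams:
    k: int = 8
    n_bootstrap: int = 100
    word_subsample_divisor: int = 8
    min_confidence: float = 0.80
    #: Floor on the winner's mean log-likelihood per word; reads below it
    #: keep only their kingdom.  -20 effectively disables the floor for
    #: in-domain reads while catching pathological no-signal queries.
    min_raw_score: float = -20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.word_subsample_divisor < 1:
            raise ValueError("word_subsample_divisor must be >= 1")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0, 1]")


@dataclass
class KmerModel:
    """Trained word statistics: leaves sorted by lineage key, a word index,
    and the dense matrix of log P(w|leaf)."""

    k: int
    leaf_keys: list[str]  # sorted lexicographically (tie-break order)
    leaf_lineages: list[Lineage]
    word_index: dict[str, int]
    log_cond: np.ndarray  # (n_leaves, n_words)
    word_prior: np.ndarray  # (n_words,)
    leaf_seq_counts: np.ndarray  # (n_leaves,) M values
    rank_codes: np.ndarray = field(init=False)  # (n_leaves, 7) ints

    def __post_init__(self) -> None:
        codes = np.empty((len(self.leaf_keys), len(RANKS)), dtype=np.int64)
        for j in range(len(RANKS)):
            names = [lin.names[j] for lin in self.leaf_lineages]
            uniq = {n: i for i, n in enumerate(dict.fromkeys(names))}
            codes[:, j] = [uniq[n] for n in names]
        self.rank_codes = codes

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_keys)

    def save(self, path: str | Path) -> None:
        """Serialise to a single .npz archive with embedded k and version."""
        meta = {
            "format_version": _FORMAT_VERSION,
            "k": self.k,
            "leaf_keys": self.leaf_keys,
            "lineages": [list(l.names) for l in self.leaf_lineages],
            "words": sorted(self.word_index, key=self.word_index.get),
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            log_cond=self.log_cond,
            word_prior=self.word_prior,
            leaf_seq_counts=self.leaf_seq_counts,
        )

    @classmethod
    def load(cls, path: str | Path) -> "KmerModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta["format_version"] != _FORMAT_VERSION:
                raise ValueError(f"unsupported model format version {meta['format_version']}")
            return cls(
                k=meta["k"],
                leaf_keys=meta["leaf_keys"],
                leaf_lineages=[Lineage(tuple(n)) for n in meta["lineages"]],
                word_index={w: i for i, w in enumerate(meta["words"])},
                log_cond=z["log_cond"],
                word_prior=z["word_prior"],
                leaf_seq_counts=z["leaf_seq_counts"],
            )


@dataclass(frozen=True)
class ClassificationResult:
    read_id: str
    leaf_key: str
    lineage: Lineage
    confidences: tuple[float, ...]  # per rank, kingdom -> species, monotone
    raw_score: float
    n_words: int


def _distinct_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def train(db: ReferenceDB, params: ClassifierParams = ClassifierParams()) -> KmerModel:
    """Train word statistics from a reference database.

    Records shorter than k are dropped with a warning; the model is
    independent of record order.
    """
    import logging

    k = params.k
    usable: list[tuple[str, str, Lineage]] = []
    for sid, seq, lin in db.records:
        if len(seq) < k:
            logging.getLogger(__name__).warning(
                "record %s shorter than k=%d; dropped from training", sid, k
            )
            continue
        usable.append((sid, seq, lin))
    if not usable:
        raise ValueError("reference database has no records of length >= k")

    by_leaf: dict[str, list[set[str]]] = {}
    leaf_lineage: dict[str, Lineage] = {}
    for _, seq, lin in usable:
        key = lin.key()
        by_leaf.setdefault(key, []).append(_distinct_kmers(seq, k))
        leaf_lineage[key] = lin

    leaf_keys = sorted(by_leaf)
    all_words = sorted(set().union(*(ws for sets in by_leaf.values() for ws in sets)))
    word_index = {w: i for i, w in enumerate(all_words)}
    n_words = len(all_words)
    n_total = len(usable)

    # n(w): sequences containing w, across all leaves
    n_w = np.zeros(n_words, dtype=np.float64)
    for sets in by_leaf.values():
        for ws in sets:
            for w in ws:
                n_w[word_index[w]] += 1
    prior = (n_w + 0.5) / (n_total + 1)

    log_cond = np.empty((len(leaf_keys), n_words), dtype=np.float64)
    seq_counts = np.empty(len(leaf_keys), dtype=np.int64)
    for i, key in enumerate(leaf_keys):
        sets = by_leaf[key]
        m_w = np.zeros(n_words, dtype=np.float64)
        for ws in sets:
            for w in ws:
                m_w[word_index[w]] += 1
        M = len(sets)
        seq_counts[i] = M
        log_cond[i] = np.log((m_w + prior) / (M + 1))

    return KmerModel(
        k=k,
        leaf_keys=leaf_keys,
        leaf_lineages=[leaf_lineage[key] for key in leaf_keys],
        word_index=word_index,
        log_cond=log_cond,
        word_prior=prior,
        leaf_seq_counts=seq_counts,
    )


def _read_rng(params: ClassifierParams, read_id: str) -> np.random.Generator:
    """Per-read generator keyed on (seed, read id) so results do not depend
    on read order."""
    return np.random.default_rng(
        (params.rng_seed & 0x7FFFFFFF, zlib.crc32(read_id.encode()))
    )


def classify(
    seq: str,
    model: KmerModel,
    params: ClassifierParams = ClassifierParams(),
    read_id: str = "read",
) -> ClassificationResult:
    """Classify one sequence; see the module docstring for the scoring model."""
    if len(seq) < model.k:
        raise ValueError(f"read {read_id}: shorter than k={model.k}")
    words = _distinct_kmers(seq.upper(), model.k)
    idx = np.array(
        sorted(model.word_index[w] for w in words if w in model.word_index), dtype=np.int64
    )
    if idx.size == 0:
        # no training word occurs in the read: no signal at all
        lin = model.leaf_lineages[0]
        return ClassificationResult(read_id, model.leaf_keys[0], lin, (0.0,) * len(RANKS), float("-inf"), 0)

    sub = model.log_cond[:, idx]  # (L, W)
    totals = sub.sum(axis=1)
    winner = int(np.argmax(totals))  # first max = lexicographically smallest key
    raw_score = float(totals[winner]) / idx.size

    W = idx.size
    n_draw = max(1, W // params.word_subsample_divisor)
    rng = _read_rng(params, read_id)
    draws = rng.integers(0, W, size=(params.n_bootstrap, n_draw))
    trial_scores = sub[:, draws.ravel()].reshape(model.n_leaves, params.n_bootstrap, n_draw).sum(axis=2)
    trial_winners = np.argmax(trial_scores, axis=0)  # (n_bootstrap,)

    conf = np.empty(len(RANKS))
    for j in range(len(RANKS)):
        conf[j] = float(
            np.mean(model.rank_codes[trial_winners, j] == model.rank_codes[winner, j])
        )
    conf = np.minimum.accumulate(conf)  # monotone non-increasing kingdom -> species

    return ClassificationResult(
        read_id=read_id,
        leaf_key=model.leaf_keys[winner],
        lineage=model.leaf_lineages[winner],
        confidences=tuple(conf),
        raw_score=raw_score,
        n_words=int(W),
    )


def apply_cutoff(
    result: ClassificationResult, params: ClassifierParams = ClassifierParams()
) -> Lineage:
    """Truncate a lineage by confidence and raw-score floors.

    Ranks whose confidence falls below ``min_confidence`` become
    placeholders (the deepest surviving named rank is retained as their
    anchor); a read scoring below ``min_raw_score`` keeps only its kingdom.
    """
    names = list(result.lineage.names)
    if result.raw_score < params.min_raw_score:
        keep_until = 1
    else:
        keep_until = 0
        for j, c in enumerate(result.confidences):
            if c >= params.min_confidence:
                keep_until = j + 1
            else:
                break
        keep_until = max(keep_until, 1)
    return Lineage.from_partial(names[:keep_until] + [None] * (len(RANKS) - keep_until))


def classify_sample(
    reads: list[tuple[str, str]],
    model: KmerModel,
    params: ClassifierParams = ClassifierParams(),
    with_cutoff: bool = True,
) -> pd.DataFrame:
    """Classify a list of (read_id, sequence) pairs into a tidy table.

    One row per read: read_id, the seven rank names (cutoff-truncated when
    ``with_cutoff``), per-rank confidences, raw_score.  Deterministic for a
    given ``params.rng_seed`` and independent of read order.
    """
    rows = []
    for rid, seq in reads:
        res = classify(seq, model, params, read_id=rid)
        lineage = apply_cutoff(res, params) if with_cutoff else res.lineage
        row: dict[str, object] = {"read_id": rid}
        for j, rank in enumerate(RANKS):
            row[rank] = lineage.names[j]
        for j, rank in enumerate(RANKS):
            row[f"conf_{rank}"] = res.confidences[j]
        row["raw_score"] = res.raw_score
        rows.append(row)
    cols = (
        ["read_id"]
        + list(RANKS)
        + [f"conf_{r}" for r in RANKS]
        + ["raw_score"]
    )
    return pd.DataFrame(rows, columns=cols)
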