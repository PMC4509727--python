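"""Community-matrix aggregation and the standard sample/taxon filters.

Per-read assignment tables are collapsed into a taxa × samples count
matrix plus a lineage side-table — the terminal product of the pipeline,
directly importable into community-ecology software.  Taxa are identified
by their *full* lineage, not the bare deepest name, so homonyms in
different families never collide.

Two filters mirror common meta-barcoding practice: per sample, taxa
holding less than ``rare_frac`` (default 0.1%) of the sample's reads are
zeroed (strict inequality — exactly 0.1% is kept), evaluated in a single
pass against the original column totals; and samples with fewer than
``min_sample_reads`` (default 2,000) total reads are dropped as
under-sequenced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .refdb import RANKS, UNCLASSIFIED_PREFIX

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "AggregateParams",
    "aggregate",
    "filter_rare",
    "drop_low_depth_samples",
    "relative_abundance",
    "rank_summary",
]


@dataclass(frozen=True)
class AggregateParams:
    rare_frac: float = 0.001
    min_sample_reads: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.rare_frac < 1.0:
            raise ValueError("rare_frac must be in [0, 1)")
        if self.min_sample_reads < 0:
            raise ValueError("min_sample_reads must be >= 0")


@dataclass
class CommunityMatrix:
    """Taxa × samples integer counts plus a per-taxon lineage table.

    ``counts`` is indexed by the lineage key (all seven ranks joined with
    ';'); ``lineages`` shares that index and has one column per rank plus
    a human-readable ``taxon`` column (deepest assigned name).
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("community matrix cannot contain negative counts")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon keys in community matrix")
        missing = self.counts.index.difference(self.lineages.index)
        if len(missing):
            raise ValueError(f"lineage table missing taxa: {list(missing)[:3]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, matrix_path: str | Path, lineage_path: str | Path) -> None:
        named = self.counts.copy()
        named.insert(0, "taxon", self.lineages.loc[named.index, "taxon"])
        named.to_csv(matrix_path, sep="\t", index_label="lineage_key")
        self.lineages.to_csv(lineage_path, sep="\t", index_label="lineage_key")


def aggregate(tables: Mapping[str, pd.DataFrame]) -> CommunityMatrix:
    """Collapse per-sample per-read assignment tables into a community matrix.

    ``tables`` maps sample_id → a DataFrame carrying the seven rank
    columns (one row per read, as produced by
    :func:`pollenpipe.classify.classify_sample`).  Cell (t, s) counts the
    reads of sample *s* assigned to taxon *t*; column sums therefore equal
    the per-sample assigned read counts.
    """
    lineage_rows: dict[str, tuple[str, ...]] = {}
    per_sample_counts: dict[str, pd.Series] = {}
    for sample_id, table in tables.items():
        missing = [r for r in RANKS if r not in table.columns]
        if missing:
            raise ValueError(f"sample {sample_id}: assignment table lacks rank column(s) {missing}")
        keys = table[list(RANKS)].agg(";".join, axis=1)
        for key, row in zip(keys, table[list(RANKS)].itertuples(index=False, name=None)):
            prev = lineage_rows.get(key)
            if prev is not None and prev != row:
                raise ValueError(f"conflicting lineages for taxon key {key}: {prev} vs {row}")
            lineage_rows[key] = row
        per_sample_counts[sample_id] = keys.value_counts()

    counts = pd.DataFrame(per_sample_counts).fillna(0).astype(np.int64)
    counts = counts.sort_index()
    counts = counts[list(tables.keys())]

    lin = pd.DataFrame.from_dict(lineage_rows, orient="index", columns=list(RANKS))
    lin = lin.loc[counts.index]

    def deepest(row: pd.Series) -> str:
        for rank in reversed(RANKS):
            if not row[rank].startswith(UNCLASSIFIED_PREFIX):
                return row[rank]
        return row[RANKS[0]]

    lin.insert(0, "taxon", lin.apply(deepest, axis=1))
    return CommunityMatrix(counts=counts, lineages=lin)


def filter_rare(m: CommunityMatrix, params: AggregateParams = AggregateParams()) -> CommunityMatrix:
    """Zero per-sample counts below ``rare_frac`` of the sample total.

    Thresholds are evaluated against the *original* column sums in a
    single pass (the rule is not iterated after zeroing); rows left
    all-zero are dropped.  Strict inequality: a taxon at exactly the
    threshold is kept.
    """
    counts = m.counts.copy()
    colsums = counts.sum(axis=0)
    for s in counts.columns:
        total = colsums[s]
        if total == 0:
            logger.warning("sample %s has zero reads; rare-taxon filter left it unchanged", s)
            continue
        frac = counts[s] / total
        counts.loc[frac < params.rare_frac, s] = 0
    keep = counts.sum(axis=1) > 0
    counts = counts.loc[keep]
    return CommunityMatrix(counts=counts, lineages=m.lineages.loc[counts.index])


def drop_low_depth_samples(
    m: CommunityMatrix, params: AggregateParams = AggregateParams()
) -> tuple[CommunityMatrix, list[str]]:
    """Remove samples whose column sum is below ``min_sample_reads``."""
    colsums = m.counts.sum(axis=0)
    dropped = [s for s in m.counts.columns if colsums[s] < params.min_sample_reads]
    counts = m.counts.drop(columns=dropped)
    return CommunityMatrix(counts=counts, lineages=m.lineages), dropped


def relative_abundance(m: CommunityMatrix) -> pd.DataFrame:
    """Counts divided by the per-sample total; every column sums to 1."""
    colsums = m.counts.sum(axis=0)
    zero = [s for s in m.counts.columns if colsums[s] == 0]
    if zero:
        raise ValueError(f"cannot normalise zero-read sample(s): {zero}")
    return m.counts / colsums


def rank_summary(
    m: CommunityMatrix,
    rank: str,
    group: Sequence[str] | None = None,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Most abundant taxa at *rank* across a group of samples.

    Counts are summed within the rank across the group and converted to
    shares of the group total, sorted descending (ties lexicographic).
    With ``top_n``, the remainder is folded into an "other" row; shares
    always sum to 1.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    cols = list(m.counts.columns) if group is None else list(group)
    if not cols:
        raise ValueError("empty sample group")
    missing = [c for c in cols if c not in m.counts.columns]
    if missing:
        raise ValueError(f"unknown sample(s): {missing}")
    sub = m.counts[cols]
    names = m.lineages.loc[sub.index, rank]
    totals = sub.sum(axis=1).groupby(names).sum()
    grand = totals.sum()
    if grand == 0:
        raise ValueError("group has zero reads")
    shares = (totals / grand).reset_index()
    shares.columns = ["name", "share"]
    shares = shares.sort_values(["share", "name"], ascending=[False, True], kind="stable")
    shares = shares.reset_index(drop=True)
    if top_n is not None and len(shares) > top_n:
        head = shares.iloc[:top_n]
        other = shares.iloc[top_n:]["share"].sum()
        shares = pd.concat(
            [head, pd.DataFrame([{"name": "other", "share": other}])], ignore_index=True
        )
    return shares
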