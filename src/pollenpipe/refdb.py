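"""Classifier-ready reference databases.

A reference record is a barcode sequence bound to a seven-rank lineage
(kingdom, phylum, class, order, family, genus, species).  Lineages are
derived by walking a rooted taxonomy tree from a record's taxon id up to
the root and picking the seven canonical ranks; intermediate ranks
(subfamily, tribe, …) and unranked nodes are skipped.  Ranks missing from
the path are filled with ``unclassified_<nearest named ancestor>``
placeholders, so no named rank ever sits below an unnamed one.

Two serialisation dialects are supported:

* UTAX-annotated FASTA — ``>seq_id;tax=d:K,p:P,c:C,o:O,f:F,g:G,s:S;``
* RDP training files — a ``*``-delimited taxonomy file
  (``taxid*name*parent_taxid*depth*rank``) plus a training FASTA whose
  headers carry the full ``Root;K;...;S`` lineage after a tab.

Names are sanitised (``; , : * <tab>`` → ``_``) because those characters
are dialect delimiters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RANKS",
    "Lineage",
    "TaxTree",
    "ReferenceDB",
    "assign_lineages",
    "write_utax_fasta",
    "read_utax_fasta",
    "write_rdp_training",
    "parse_rdp_taxonomy",
    "coverage_report",
]

RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_UTAX_CODES = ("d", "p", "c", "o", "f", "g", "s")
_SANITIZE_RE = re.compile(r"[;,:\t*]")
UNCLASSIFIED_PREFIX = "unclassified_"


def sanitize_name(name: str) -> str:
    return _SANITIZE_RE.sub("_", name.strip())


@dataclass(frozen=True)
class Lineage:
    """Exactly seven rank names, kingdom → species.

    Missing ranks hold ``unclassified_<nearest named ancestor>``.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} ranks, got {len(self.names)}")
        if not self.names[0] or self.names[0].startswith(UNCLASSIFIED_PREFIX):
            raise ValueError("kingdom must be a named rank")

    @classmethod
    def from_partial(cls, partial: dict[str, str | None] | Sequence[str | None]) -> "Lineage":
        """Build a normalized lineage from possibly-missing rank names.

        Accepts a rank→name dict or a 7-sequence; empty/None/placeholder
        entries are refilled from the nearest named ancestor, making
        normalization idempotent.
        """
        if isinstance(partial, dict):
            raw = [partial.get(r) for r in RANKS]
        else:
            raw = list(partial)
            if len(raw) != len(RANKS):
                raise ValueError(f"lineage needs {len(RANKS)} ranks, got {len(raw)}")
        names: list[str] = []
        nearest = None
        for rank, value in zip(RANKS, raw):
            if value and not value.startswith(UNCLASSIFIED_PREFIX):
                name = sanitize_name(value)
                names.append(name)
                nearest = name
            else:
                if nearest is None:
                    raise ValueError("kingdom must be a named rank")
                names.append(f"{UNCLASSIFIED_PREFIX}{nearest}")
        return cls(tuple(names))

    def __getitem__(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    @property
    def deepest_named(self) -> tuple[str, str]:
        """(rank, name) of the deepest non-placeholder rank."""
        for rank, name in zip(reversed(RANKS), reversed(self.names)):
            if not name.startswith(UNCLASSIFIED_PREFIX):
                return rank, name
        return RANKS[0], self.names[0]

    def key(self) -> str:
        """Stable identity string (full lineage, avoids homonym collisions)."""
        return ";".join(self.names)


@dataclass
class TaxTree:
    """Rooted taxonomy: node id → (name, parent id, rank, depth); root self-parented."""

    nodes: dict[int, tuple[str, int, str, int]]

    def __post_init__(self) -> None:
        roots = [i for i, (_, p, _, _) in self.nodes.items() if p == i]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one self-parented root, found {len(roots)}")
        self.root = roots[0]
        for nid, (name, parent, rank, depth) in self.nodes.items():
            if parent not in self.nodes:
                raise ValueError(f"node {nid} ({name}): parent {parent} missing")
            if nid != self.root:
                pdepth = self.nodes[parent][3]
                if depth != pdepth + 1:
                    raise ValueError(f"node {nid}: depth {depth} != parent depth {pdepth} + 1")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxTree":
        """Read a nodes-style TSV: taxon_id, name, parent_id, rank (depth derived)."""
        raw: dict[int, tuple[str, int, str]] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                tid, name, parent, rank = line.rstrip("\n").split("\t")[:4]
                raw[int(tid)] = (name, int(parent), rank)
        depths: dict[int, int] = {}

        def depth_of(nid: int, seen: frozenset[int] = frozenset()) -> int:
            if nid in depths:
                return depths[nid]
            if nid in seen:
                raise ValueError(f"cycle detected at node {nid}")
            name, parent, rank = raw[nid]
            d = 0 if parent == nid else depth_of(parent, seen | {nid}) + 1
            depths[nid] = d
            return d

        nodes = {
            nid: (name, parent, rank, depth_of(nid)) for nid, (name, parent, rank) in raw.items()
        }
        return cls(nodes)

    def path_to_root(self, taxid: int) -> list[int]:
        if taxid not in self.nodes:
            raise KeyError(f"taxon id {taxid} not in tree")
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]][1])
        return path

    def lineage_of(self, taxid: int) -> Lineage:
        """Seven-rank lineage of a taxon: named ranks picked off the
        root-ward path, everything else placeholder-filled."""
        by_rank: dict[str, str] = {}
        for nid in self.path_to_root(taxid):
            name, _, rank, _ = self.nodes[nid]
            if rank in RANKS and rank not in by_rank:
                by_rank[rank] = name
        return Lineage.from_partial(by_rank)


@dataclass
class ReferenceDB:
    """Barcode sequences with lineages; seq_ids unique, sequences non-empty."""

    records: list[tuple[str, str, Lineage]]  # (seq_id, sequence, lineage)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate seq_id in reference database")
        for sid, seq, _ in self.records:
            if not seq:
                raise ValueError(f"record {sid}: empty sequence")

    def __len__(self) -> int:
        return len(self.records)

    def names_at_rank(self, rank: str) -> set[str]:
        i = RANKS.index(rank)
        return {
            lin.names[i]
            for _, _, lin in self.records
            if not lin.names[i].startswith(UNCLASSIFIED_PREFIX)
        }


def assign_lineages(
    seqs: dict[str, str], id2tax: dict[str, int], tree: TaxTree
) -> tuple[ReferenceDB, int]:
    """Attach seven-rank lineages to sequences via an id→taxid map.

    Sequences whose id is missing from the map (or whose taxid is missing
    from the tree) are dropped with a logged warning; the second return
    value is the drop count.
    """
    records: list[tuple[str, str, Lineage]] = []
    dropped = 0
    for sid, seq in seqs.items():
        tid = id2tax.get(sid)
        if tid is None or tid not in tree.nodes:
            logger.warning("sequence %s: no taxid mapping; dropped", sid)
            dropped += 1
            continue
        records.append((sid, seq, tree.lineage_of(tid)))
    return ReferenceDB(records), dropped


def write_utax_fasta(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq, lin in db.records:
            tax = ",".join(f"{c}:{sanitize_name(n)}" for c, n in zip(_UTAX_CODES, lin.names))
            fh.write(f">{sanitize_name(sid)};tax={tax};\n{seq}\n")


def read_utax_fasta(path: str | Path) -> ReferenceDB:
    records: list[tuple[str, str, Lineage]] = []
    sid = None
    lin = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if sid is not None:
                    records.append((sid, "".join(chunks), lin))
                m = re.match(r">([^;]+);tax=([^;]*);?$", line)
                if not m:
                    raise ValueError(f"{path}:{lineno}: malformed UTAX header: {line!r}")
                sid = m.group(1)
                fields = m.group(2).split(",")
                by_code = dict(f.split(":", 1) for f in fields if ":" in f)
                if set(by_code) != set(_UTAX_CODES):
                    raise ValueError(
                        f"{path}:{lineno}: expected ranks {','.join(_UTAX_CODES)}, got {sorted(by_code)}"
                    )
                lin = Lineage.from_partial([by_code[c] for c in _UTAX_CODES])
                chunks = []
            elif line:
                chunks.append(line)
        if sid is not None:
            records.append((sid, "".join(chunks), lin))
    return ReferenceDB(records)


def write_rdp_training(db: ReferenceDB, outdir: str | Path) -> tuple[Path, Path]:
    """Write RDP-style training files: taxonomy tree + annotated FASTA.

    Every distinct lineage prefix becomes one taxonomy node; ids are
    assigned in first-seen order with Root = 0.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tax_path = outdir / "taxonomy.txt"
    fasta_path = outdir / "training.fasta"

    node_ids: dict[tuple[str, ...], int] = {(): 0}
    lines = ["0*Root*-1*0*rootrank"]
    for _, _, lin in db.records:
        for depth in range(1, len(RANKS) + 1):
            prefix = tuple(sanitize_name(n) for n in lin.names[:depth])
            if prefix not in node_ids:
                nid = len(node_ids)
                node_ids[prefix] = nid
                parent = node_ids[prefix[:-1]]
                lines.append(f"{nid}*{prefix[-1]}*{parent}*{depth}*{RANKS[depth - 1]}")
    tax_path.write_text("\n".join(lines) + "\n")

    with open(fasta_path, "w") as fh:
        for sid, seq, lin in db.records:
            lineage_str = ";".join(["Root", *(sanitize_name(n) for n in lin.names)])
            fh.write(f">{sanitize_name(sid)}\t{lineage_str}\n{seq}\n")
    return tax_path, fasta_path


def parse_rdp_taxonomy(path: str | Path) -> TaxTree:
    """Parse the ``*``-delimited RDP taxonomy file back into a TaxTree."""
    nodes: dict[int, tuple[str, int, str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("*")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 '*'-delimited fields")
            nid, name, parent, depth, rank = parts
            nid_i, parent_i = int(nid), int(parent)
            if parent_i == -1:  # Root is serialized with parent -1; self-parent it
                parent_i = nid_i
            nodes[nid_i] = (name, parent_i, rank, int(depth))
    return TaxTree(nodes)


def coverage_report(
    db: ReferenceDB, checklist: Iterable[str], rank: str = "species"
) -> float:
    """Fraction of checklist names present in the database at *rank*
    (case-insensitive exact match on sanitized names)."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    names = [sanitize_name(n).lower() for n in checklist]
    if not names:
        raise ValueError("checklist is empty")
    have = {n.lower() for n in db.names_at_rank(rank)}
    covered = sum(1 for n in names if n in have)
    return covered / len(names)
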