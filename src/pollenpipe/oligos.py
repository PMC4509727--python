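"""Dual-indexed amplification oligos and sequencing primers.

The amplification oligo for each sample is a pure concatenation of five
parts: a platform adapter, an 8-nt sample index, a 10-nt pad, a 2-nt
linker and the locus-specific amplifying primer.  The pad and linker are
spacers chosen so that the combined pad+linker+primer "read region" melts
near 65 °C — that region doubles as the custom sequencing primer (Read1 on
the forward side, Read2 on the reverse side), and the index-read primer is
the reverse complement of Read2.

This module builds the oligos, derives the sequencing primers, and computes
the QC metrics reported for such designs: length, GC fraction, melting
temperature under three models, and the longest contiguous antiparallel
Watson–Crick complementary stretch between two oligos (dimer check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from ._util import revcomp, validate_dna

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldSpec",
    "IndexSet",
    "SequencingPrimerSet",
    "OligoQCReport",
    "ITS2_SCAFFOLD",
    "build_sample_oligos",
    "derive_sequencing_primers",
    "gc_fraction",
    "melting_temperature",
    "longest_complementary_run",
    "qc_report",
    "enumerate_combinations",
]


@dataclass(frozen=True)
class ScaffoldSpec:
    """Component parts of the dual-index oligo scaffold.

    Pads are exactly 10 nt and linkers exactly 2 nt; all parts are plain
    ACGT strings (the 8-nt index is supplied per sample, not stored here).
    """

    fwd_adapter: str
    rev_adapter: str
    fwd_pad: str
    fwd_linker: str
    rev_pad: str
    rev_linker: str
    fwd_amp_primer: str
    rev_amp_primer: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd_adapter", validate_dna(self.fwd_adapter, "fwd_adapter"))
        object.__setattr__(self, "rev_adapter", validate_dna(self.rev_adapter, "rev_adapter"))
        object.__setattr__(self, "fwd_pad", validate_dna(self.fwd_pad, "fwd_pad", length=10))
        object.__setattr__(self, "rev_pad", validate_dna(self.rev_pad, "rev_pad", length=10))
        object.__setattr__(self, "fwd_linker", validate_dna(self.fwd_linker, "fwd_linker", length=2))
        object.__setattr__(self, "rev_linker", validate_dna(self.rev_linker, "rev_linker", length=2))
        object.__setattr__(self, "fwd_amp_primer", validate_dna(self.fwd_amp_primer, "fwd_amp_primer"))
        object.__setattr__(self, "rev_amp_primer", validate_dna(self.rev_amp_primer, "rev_amp_primer"))

    @property
    def read1_region(self) -> str:
        """Forward pad+linker+primer: the Read1 sequencing primer."""
        return self.fwd_pad + self.fwd_linker + self.fwd_amp_primer

    @property
    def read2_region(self) -> str:
        """Reverse pad+linker+primer: the Read2 sequencing primer."""
        return self.rev_pad + self.rev_linker + self.rev_amp_primer


#: The published ITS2 dual-indexing scaffold: Illumina P5/P7 adapters, the
#: modified forward pad CCTGGTGCTG, pads/linkers and the ITS-S2F / ITS4R
#: amplifying primers.  Both read regions are 32 nt with 50% GC.
ITS2_SCAFFOLD = ScaffoldSpec(
    fwd_adapter="AATGATACGGCGACCACCGAGATCTACAC",
    rev_adapter="CAAGCAGAAGACGGCATACGAGAT",
    fwd_pad="CCTGGTGCTG",
    fwd_linker="GT",
    rev_pad="AGTCAGTCAG",
    rev_linker="CC",
    fwd_amp_primer="ATGCGATACTTGGTGTGAAT",
    rev_amp_primer="TCCTCCGCTTATTGATATGC",
)


@dataclass(frozen=True)
class IndexSet:
    """An ordered, named collection of unique 8-nt sample indices."""

    entries: dict[str, str]
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if not self.entries:
            raise ValueError("IndexSet needs at least one index")
        clean = {}
        for name, seq in self.entries.items():
            clean[name] = validate_dna(seq, f"index {name}", length=8)
        if len(set(clean.values())) != len(clean):
            raise ValueError("index sequences must be unique within a set")
        object.__setattr__(self, "entries", clean)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SequencingPrimerSet:
    """Custom sequencing primers derived from a scaffold."""

    read1: str
    read2: str
    index_primer: str


@dataclass(frozen=True)
class OligoQCReport:
    length: int
    gc_fraction: float
    tm_celsius: float
    max_self_dimer: int
    max_cross_dimer: int


def build_sample_oligos(spec: ScaffoldSpec, fwd_index: str, rev_index: str) -> tuple[str, str]:
    """Assemble the forward and reverse amplification oligos for one sample.

    Pure concatenation: adapter ∥ index ∥ pad ∥ linker ∥ amplifying primer.
    """
    fwd_index = validate_dna(fwd_index, "fwd_index", length=8)
    rev_index = validate_dna(rev_index, "rev_index", length=8)
    fwd = spec.fwd_adapter + fwd_index + spec.fwd_pad + spec.fwd_linker + spec.fwd_amp_primer
    rev = spec.rev_adapter + rev_index + spec.rev_pad + spec.rev_linker + spec.rev_amp_primer
    return fwd, rev


def derive_sequencing_primers(spec: ScaffoldSpec) -> SequencingPrimerSet:
    """Read1/Read2 primers are the pad+linker+primer regions; the index-read
    primer is the base-wise reverse complement of Read2."""
    read1 = spec.read1_region
    read2 = spec.read2_region
    return SequencingPrimerSet(read1=read1, read2=read2, index_primer=revcomp(read2))


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length for a non-empty ACGT string."""
    seq = validate_dna(seq, "sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str,
    model: str = "marmur_doty",
    salt_molar: float = 0.05,
    oligo_molar: float = 250e-9,
) -> float:
    """Melting temperature in °C under one of three models.

    wallace
        2(#A+#T) + 4(#G+#C); a rule of thumb for primers ≤ 14 nt
        (a warning is logged for longer inputs).
    marmur_doty
        64.9 + 41·(#G+#C − 16.4)/length; the GC-content approximation
        for longer oligos.
    nearest_neighbor
        Unified nearest-neighbor thermodynamics (SantaLucia's unified
        parameter table as shipped with Biopython) with a monovalent-salt
        correction at ``salt_molar`` (mol/L Na+) and total strand
        concentration ``oligo_molar`` (mol/L).
    """
    seq = validate_dna(seq, "sequence")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    if model == "wallace":
        if len(seq) > 14:
            logger.warning(
                "wallace rule requested for a %d-mer; intended for <=14 nt", len(seq)
            )
        return float(2 * at + 4 * gc)
    if model == "marmur_doty":
        return 64.9 + 41.0 * (gc - 16.4) / len(seq)
    if model == "nearest_neighbor":
        return float(
            _mt.Tm_NN(seq, Na=salt_molar * 1000, dnac1=oligo_molar * 1e9 / 2, dnac2=oligo_molar * 1e9 / 2)
        )
    raise ValueError(f"unknown Tm model: {model!r}")


def longest_complementary_run(seq_a: str, seq_b: str) -> int:
    """Longest contiguous antiparallel Watson–Crick complementary stretch.

    Computed as the longest common substring between ``seq_a`` and the
    reverse complement of ``seq_b`` (G·T wobble pairs not counted).  Call
    with ``seq_a == seq_b`` for a self-dimer check.
    """
    a = validate_dna(seq_a, "seq_a")
    b = revcomp(validate_dna(seq_b, "seq_b"))
    # classic O(n·m) longest-common-substring DP, rolling row
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def qc_report(
    spec: ScaffoldSpec, tm_model: str = "marmur_doty"
) -> dict[str, OligoQCReport]:
    """QC metrics for both read regions, plus the read1×read2 cross-dimer."""
    r1 = spec.read1_region
    r2 = spec.read2_region
    cross = longest_complementary_run(r1, r2)
    reports = {}
    for name, seq in (("read1", r1), ("read2", r2)):
        reports[name] = OligoQCReport(
            length=len(seq),
            gc_fraction=gc_fraction(seq),
            tm_celsius=melting_temperature(seq, model=tm_model),
            max_self_dimer=longest_complementary_run(seq, seq),
            max_cross_dimer=cross,
        )
    return reports


def enumerate_combinations(fwd: IndexSet, rev: IndexSet) -> pd.DataFrame:
    """Full Cartesian product of forward × reverse indices as sample-sheet rows.

    Returns a DataFrame with columns combo_id, fwd_name, fwd_seq, rev_name,
    rev_seq; row count is ``len(fwd) * len(rev)``.
    """
    rows = []
    i = 1
    for fname, fseq in fwd.entries.items():
        for rname, rseq in rev.entries.items():
            rows.append(
                {
                    "combo_id": f"combo{i:03d}",
                    "fwd_name": fname,
                    "fwd_seq": fseq,
                    "rev_name": rname,
                    "rev_seq": rseq,
                }
            )
            i += 1
    return pd.DataFrame(rows, columns=["combo_id", "fwd_name", "fwd_seq", "rev_name", "rev_seq"])


def synthetic_index_set(n: int, orientation: str, seed: int = 0) -> IndexSet:
    """Generate *n* synthetic 8-nt indices (named fwd01…/rev01…).

    The published index sequences live in an instrument-vendor supplement;
    for design checks and simulations only the set sizes matter, so unique
    random 8-mers are drawn instead.
    """
    import numpy as np

    rng = np.random.default_rng(seed + (0 if orientation == "forward" else 10_000))
    prefix = "fwd" if orientation == "forward" else "rev"
    seqs: dict[str, str] = {}
    seen: set[str] = set()
    while len(seqs) < n:
        s = "".join(rng.choice(list("ACGT"), size=8))
        if s not in seen:
            seen.add(s)
            seqs[f"{prefix}{len(seqs) + 1:02d}"] = s
    return IndexSet(entries=seqs, orientation=orientation)
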