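"""Shared sequence primitives: alphabet checks, reverse complement, Phred codecs."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGT")
AMBIGUOUS_OK = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PHRED_OFFSET = 33
#: Highest quality written to FASTQ output; keeps characters printable.
MAX_PHRED = 41


def is_dna(seq: str) -> bool:
    """True if *seq* is a non-empty string over {A,C,G,T}."""
    return bool(seq) and set(seq) <= DNA_ALPHABET


def validate_dna(seq: str, name: str = "sequence", length: int | None = None) -> str:
    """Return *seq* uppercased, or raise ValueError naming the offending component."""
    if not isinstance(seq, str) or not seq:
        raise ValueError(f"{name} must be a non-empty DNA string")
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{name} contains non-ACGT character(s): {''.join(sorted(bad))}"
        )
    if length is not None and len(seq) != length:
        raise ValueError(f"{name} must be exactly {length} nt, got {len(seq)} nt")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def phred_to_ascii(quals) -> str:
    """Encode an iterable of integer Phred scores as a Phred+33 string."""
    return "".join(chr(min(int(q), MAX_PHRED) + PHRED_OFFSET) for q in quals)


def ascii_to_phred(qual: str) -> np.ndarray:
    """Decode a Phred+33 quality string into an int array."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - PHRED_OFFSET


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a sequence, for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
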