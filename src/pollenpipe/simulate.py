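"""Synthetic reference databases, mock communities and dual-indexed runs.

The simulator produces everything a multi-sample amplicon sequencing run
delivers — paired 250-nt reads, two 8-nt index reads per pair, a sample
sheet — together with the ground truth, so the whole pipeline can be
exercised and scored with no external data.

The reference set is generated hierarchically: a random root sequence is
mutated down a four-level tree (order → family → genus → species), each
descent applying a rank-specific substitution fraction at random
positions, so sequence similarity mirrors taxonomic relatedness the way a
real barcode database's does.  Species sequences are truncated to lengths
drawn from the amplicon-length range so reads overlap by a varying amount
when merged.

Mock communities draw species without replacement and give them
log-normal abundances (skewed, like real pollen samples); reads copy the
species sequence from both ends, with independent per-base substitution
errors and a linearly decaying quality profile.  Everything flows from a
single seed and reruns are bit-identical.

What this does *not* emulate: indels, chimeras, PCR bias, position- or
motif-dependent MiSeq error profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import phred_to_ascii
from .demux import IndexedReadPair
from .oligos import IndexSet
from .refdb import RANKS, Lineage, ReferenceDB

__all__ = [
    "SimParams",
    "SimTruth",
    "SimulatedRun",
    "simulate_refdb",
    "simulate_community",
    "simulate_run",
    "PRESETS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study-condition knobs for the simulator.

    Defaults give 5×2×2 = 20 genera with 2 species each, ~250-nt paired
    reads at 1% substitution error, and skewed (log-normal, σ=1)
    per-sample abundances over 5,000 reads — the scale at which real runs
    of this design saturate per-sample diversity.
    """

    n_orders: int = 5
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    seq_len_range: tuple[int, int] = (350, 480)
    divergence: Mapping[str, float] = field(
        default_factory=lambda: {"order": 0.15, "family": 0.08, "genus": 0.05, "species": 0.02}
    )
    read_len: int = 250
    error_rate: float = 0.01
    q_start: int = 38
    q_end: int = 25
    abundance_sigma: float = 1.0
    reads_per_sample: int = 5000
    index_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rank, d in self.divergence.items():
            if not 0.0 < d < 0.5:
                raise ValueError(f"divergence[{rank}] must be in (0, 0.5)")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")
        if min(
            self.n_orders, self.families_per_order, self.genera_per_family, self.species_per_genus
        ) < 1:
            raise ValueError("tree sizes must all be >= 1")


#: Named parameter bundles for quick runs.
PRESETS: dict[str, SimParams] = {
    "tiny": SimParams(
        n_orders=2,
        families_per_order=1,
        genera_per_family=2,
        species_per_genus=2,
        reads_per_sample=200,
    ),
    "default": SimParams(),
    "deep": SimParams(reads_per_sample=20000),
}


@dataclass
class SimTruth:
    """Ground truth of a simulated run."""

    counts: dict[str, dict[str, int]]  # sample_id -> lineage key -> reads
    reads: pd.DataFrame  # read_id, sample_id, lineage_key

    def check_against(self, reads_per_sample: Mapping[str, int]) -> None:
        for sid, taxa in self.counts.items():
            if sum(taxa.values()) != reads_per_sample[sid]:
                raise AssertionError(f"truth counts for {sid} do not sum to reads_per_sample")


def _mutate(rng: np.random.Generator, seq: np.ndarray, fraction: float) -> np.ndarray:
    """Substitute *fraction* of positions (chosen without replacement) to a
    different base."""
    n = max(1, round(fraction * seq.size))
    pos = rng.choice(seq.size, size=n, replace=False)
    out = seq.copy()
    out[pos] = (out[pos] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_refdb(params: SimParams = SimParams()) -> ReferenceDB:
    """Generate a hierarchically structured reference database.

    Lineage names are systematic (o1, o1_f2, o1_f2_g1, o1_f2_g1_s2 …)
    under a fixed kingdom/phylum/class; identical seeds give identical
    databases.
    """
    rng = np.random.default_rng(params.rng_seed)
    lo, hi = params.seq_len_range
    root = rng.integers(0, 4, size=hi)
    records = []
    for o in range(1, params.n_orders + 1):
        o_seq = _mutate(rng, root, params.divergence["order"])
        o_name = f"o{o}"
        for f in range(1, params.families_per_order + 1):
            f_seq = _mutate(rng, o_seq, params.divergence["family"])
            f_name = f"{o_name}_f{f}"
            for g in range(1, params.genera_per_family + 1):
                g_seq = _mutate(rng, f_seq, params.divergence["genus"])
                g_name = f"{f_name}_g{g}"
                for s in range(1, params.species_per_genus + 1):
                    s_seq = _mutate(rng, g_seq, params.divergence["species"])
                    s_name = f"{g_name}_s{s}"
                    length = int(rng.integers(lo, hi + 1))
                    seq = _BASES[s_seq[:length]].tobytes().decode("ascii")
                    lin = Lineage(
                        ("Simulantae", "Simuphyta", "Simulopsida", o_name, f_name, g_name, s_name)
                    )
                    records.append((s_name, seq, lin))
    return ReferenceDB(records)


def _integer_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of *total* reads to weights."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(np.int64)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def simulate_community(
    db: ReferenceDB,
    n_taxa: int,
    sigma: float = 1.0,
    seed: int = 0,
    reads_per_sample: int = 5000,
) -> dict[str, int]:
    """Draw a skewed mock community: lineage key → true read count.

    ``n_taxa`` species are sampled without replacement; abundances are
    proportional to exp(N(0, σ²)) and apportioned into integer counts
    summing exactly to ``reads_per_sample``.
    """
    species = [lin.key() for _, _, lin in db.records]
    if n_taxa > len(species):
        raise ValueError(f"n_taxa={n_taxa} exceeds the {len(species)} species in the database")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(species), size=n_taxa, replace=False)
    weights = np.exp(rng.normal(0.0, sigma, size=n_taxa))
    counts = _integer_counts(weights, reads_per_sample)
    return {species[i]: int(c) for i, c in zip(chosen, counts)}


@dataclass
class SimulatedRun:
    pairs: list[IndexedReadPair]
    truth: SimTruth
    samplesheet: pd.DataFrame  # sample_id, fwd_index, rev_index
    reference: ReferenceDB

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit R1/R2/I1/I2 FASTQ, the sample sheet CSV, truth TSVs and the
        reference as UTAX-annotated FASTA."""
        from .readprep import write_fastq
        from .refdb import write_utax_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1": outdir / "run_R1.fastq",
            "r2": outdir / "run_R2.fastq",
            "i1": outdir / "run_I1.fastq",
            "i2": outdir / "run_I2.fastq",
            "sheet": outdir / "samplesheet.csv",
            "truth_reads": outdir / "truth_reads.tsv",
            "truth_counts": outdir / "truth_counts.tsv",
            "reference": outdir / "reference_utax.fasta",
        }
        qdummy = "I" * 8
        write_fastq(paths["r1"], ((p.id, p.r1_seq, p.r1_qual) for p in self.pairs))
        write_fastq(paths["r2"], ((p.id, p.r2_seq, p.r2_qual) for p in self.pairs))
        write_fastq(paths["i1"], ((p.id, p.i1_seq, qdummy) for p in self.pairs))
        write_fastq(paths["i2"], ((p.id, p.i2_seq, qdummy) for p in self.pairs))
        self.samplesheet.to_csv(paths["sheet"], index=False)
        self.truth.reads.to_csv(paths["truth_reads"], sep="\t", index=False)
        rows = [
            {"sample_id": sid, "lineage_key": key, "reads": n}
            for sid, taxa in self.truth.counts.items()
            for key, n in taxa.items()
        ]
        pd.DataFrame(rows).to_csv(paths["truth_counts"], sep="\t", index=False)
        write_utax_fasta(self.reference, paths["reference"])
        return paths


def _quality_profile(params: SimParams, length: int) -> str:
    if length == 1:
        return phred_to_ascii([params.q_start])
    qs = np.round(
        np.linspace(params.q_start, params.q_end, length)
    ).astype(int)
    return phred_to_ascii(qs)


def _seq_batch_to_strings(batch: np.ndarray) -> list[str]:
    return [_BASES[row].tobytes().decode("ascii") for row in batch]


def simulate_run(
    db: ReferenceDB,
    communities: Mapping[str, Mapping[str, int]],
    fwd_indices: IndexSet,
    rev_indices: IndexSet,
    params: SimParams = SimParams(),
) -> SimulatedRun:
    """Generate the pooled dual-indexed run for a set of mock communities.

    ``communities`` maps sample_id → (lineage key → read count); samples
    are assigned index pairs from the Cartesian product of the two index
    sets in order.  Forward reads copy the template 5'-end, reverse reads
    the reverse complement of the 3'-end; substitution errors are injected
    per base at ``error_rate`` and index reads are perturbed at
    ``index_error_rate``.  The pooled read order is shuffled.
    """
    rng = np.random.default_rng(params.rng_seed + 1)
    by_key = {lin.key(): seq for _, seq, lin in db.records}
    n_samples = len(communities)
    index_pairs = [
        (fname, fseq, rname, rseq)
        for fname, fseq in fwd_indices.entries.items()
        for rname, rseq in rev_indices.entries.items()
    ]
    if n_samples > len(index_pairs):
        raise ValueError(
            f"{n_samples} samples but only {len(index_pairs)} index combinations"
        )

    sheet_rows = []
    pairs: list[IndexedReadPair] = []
    truth_rows = []
    read_no = 0
    for (sample_id, taxa), (fname, fseq, rname, rseq) in zip(communities.items(), index_pairs):
        sheet_rows.append({"sample_id": sample_id, "fwd_index": fseq, "rev_index": rseq})
        for key, n_reads in taxa.items():
            if n_reads == 0:
                continue
            template = by_key.get(key)
            if template is None:
                raise KeyError(f"community taxon {key} not in reference database")
            if len(template) > 2 * params.read_len:
                raise ValueError(
                    f"reference for {key} is {len(template)} nt; paired {params.read_len}-nt "
                    "reads cannot overlap"
                )
            rlen = min(params.read_len, len(template))
            tpl = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
            code = np.empty(tpl.size, dtype=np.int64)
            for b, byte in enumerate(_BASES):
                code[tpl == byte] = b
            fwd_tpl = code[:rlen]
            rev_tpl = (3 - code[::-1])[:rlen]  # revcomp of the 3' end
            qual = _quality_profile(params, rlen)

            for name, tpl_codes in (("r1", fwd_tpl), ("r2", rev_tpl)):
                batch = np.tile(tpl_codes, (n_reads, 1))
                if params.error_rate > 0:
                    mask = rng.random(batch.shape) < params.error_rate
                    batch[mask] = (batch[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
                if name == "r1":
                    r1_seqs = _seq_batch_to_strings(batch)
                else:
                    r2_seqs = _seq_batch_to_strings(batch)

            i1_seqs = [fseq] * n_reads
            i2_seqs = [rseq] * n_reads
            if params.index_error_rate > 0:
                for seq_list in (i1_seqs, i2_seqs):
                    arr = np.frombuffer("".join(seq_list).encode(), dtype=np.uint8).copy()
                    codes = np.empty(arr.size, dtype=np.int64)
                    for b, byte in enumerate(_BASES):
                        codes[arr == byte] = b
                    mask = rng.random(arr.size) < params.index_error_rate
                    codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
                    joined = _BASES[codes].tobytes().decode("ascii")
                    seq_list[:] = [joined[i * 8 : (i + 1) * 8] for i in range(n_reads)]

            for i in range(n_reads):
                rid = f"r{read_no:07d}"
                read_no += 1
                pairs.append(
                    IndexedReadPair(rid, r1_seqs[i], qual, r2_seqs[i], qual, i1_seqs[i], i2_seqs[i])
                )
                truth_rows.append({"read_id": rid, "sample_id": sample_id, "lineage_key": key})

    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    truth_reads = pd.DataFrame(truth_rows).iloc[order].reset_index(drop=True)
    truth = SimTruth(
        counts={sid: dict(taxa) for sid, taxa in communities.items()}, reads=truth_reads
    )
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "fwd_index", "rev_index"])
    return SimulatedRun(pairs=pairs, truth=truth, samplesheet=sheet, reference=db)
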