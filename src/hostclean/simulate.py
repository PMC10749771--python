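"""Synthetic fixture generators: genomes, Illumina-like pairs, nanopore-like
long reads, and contamination mixtures with truth labels.

Deliberately simple error models (documented, seeded, bit-reproducible):
short reads get i.i.d. substitutions; long reads get gamma-distributed
lengths and an error budget split 40% substitution / 30% insertion /
30% deletion.  Every read id encodes its provenance losslessly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import UsageError, ValidationError
from .fastq import FastqWriter, ReadRecord, read_fastq, split_read_id
from .refdb import read_fasta

BASES = np.array(list("ACGT"))
SHORT_QUAL_CHAR = chr(25 + 33)  # constant Q25
LONG_QUAL_CHAR = chr(12 + 33)  # constant Q12
TRUTH_LABELS = ("host", "microbe", "viral")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimParams:
    seed: int
    read_len: int = 150
    frag_mean: float = 400.0
    frag_sd: float = 50.0
    err_rate: float = 0.0
    long_len_mean: float = 3000.0
    long_len_shape: float = 2.0
    depth: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.err_rate < 1:
            raise ValidationError("err_rate must be in [0, 1)")
        if self.read_len < 1:
            raise ValidationError("read_len must be >= 1")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")


@dataclass
class Provenance:
    """Truth metadata encoded into each simulated read id."""

    source_id: str
    start: int
    strand: str  # "+" | "-"
    truth: str  # host | microbe | viral

    def encode(self, serial: int) -> str:
        strand = "f" if self.strand == "+" else "r"
        return f"{self.source_id}|{self.start}|{strand}|{self.truth}|{serial}"

    @classmethod
    def parse(cls, read_id: str) -> "Provenance":
        base, _ = split_read_id(read_id)
        parts = base.split("|")
        if len(parts) != 5 or parts[3] not in TRUTH_LABELS or parts[2] not in "fr":
            raise ValidationError(f"read id {read_id!r} carries no provenance")
        return cls(parts[0], int(parts[1]), "+" if parts[2] == "f" else "-", parts[3])


def synth_genome(length: int, gc: float, seed: int, name: str = "synth") -> Dict[str, str]:
    """Deterministic random genome with the requested GC fraction."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValidationError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    idx = rng.choice(4, size=length, p=probs)
    seq = np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode()
    return {name: seq}


def _load_sequences(genome: os.PathLike | str | Dict[str, str]) -> List[Tuple[str, str]]:
    if isinstance(genome, dict):
        seqs = genome
    else:
        seqs = read_fasta(genome)
    items = [(n, s.upper()) for n, s in seqs.items() if s]
    if not items:
        raise ValidationError("genome has no non-empty sequences")
    return items


def _pick_sources(
    items: List[Tuple[str, str]], n: int, rng: np.random.Generator
) -> np.ndarray:
    lengths = np.array([len(s) for _, s in items], dtype=float)
    return rng.choice(len(items), size=n, p=lengths / lengths.sum())


def _substitute(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    if err_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < err_rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def simulate_illumina_pairs(
    genome: os.PathLike | str | Dict[str, str],
    n_pairs: int,
    params: SimParams,
    out1: os.PathLike | str,
    out2: os.PathLike | str,
    truth: str = "microbe",
) -> Tuple[int, int]:
    """Write n_pairs Illumina-like read pairs sampled from the genome.

    Mate 1 comes from one end of a fragment, mate 2 from the opposite
    strand of the other end; with err_rate=0 every read is an exact
    substring of the genome or its reverse complement.
    """
    items = _load_sequences(genome)
    min_len = params.frag_mean + 6 * params.frag_sd
    usable = [(n, s) for n, s in items if len(s) >= min_len]
    if not usable:
        raise ValidationError(
            f"genome too short for fragment model (need >= {min_len:.0f} bp)"
        )
    rng = np.random.default_rng(params.seed)
    picks = _pick_sources(usable, n_pairs, rng)
    with FastqWriter(out1) as w1, FastqWriter(out2) as w2:
        for serial, src_i in enumerate(picks):
            name, seq = usable[src_i]
            L = len(seq)
            frag = int(round(rng.normal(params.frag_mean, params.frag_sd)))
            frag = max(params.read_len, min(frag, L))
            start = int(rng.integers(0, L - frag + 1))
            fwd = seq[start : start + params.read_len]
            rev = revcomp(seq[start + frag - params.read_len : start + frag])
            if rng.random() < 0.5:
                strand, r1_seq, r2_seq = "+", fwd, rev
            else:
                strand, r1_seq, r2_seq = "-", rev, fwd
            r1_seq = _substitute(r1_seq, params.err_rate, rng)
            r2_seq = _substitute(r2_seq, params.err_rate, rng)
            rid = Provenance(name, start, strand, truth).encode(serial)
            qual = SHORT_QUAL_CHAR * params.read_len
            w1.write(ReadRecord(rid, r1_seq, qual, 1))
            w2.write(ReadRecord(rid, r2_seq, qual, 2))
    return n_pairs, n_pairs


def _long_read_errors(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    """Apply 40/30/30 substitution/insertion/deletion errors."""
    if err_rate <= 0:
        return seq
    out: List[str] = []
    for ch in seq:
        r = rng.random()
        if r >= err_rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.4:  # substitution
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        elif kind < 0.7:  # insertion (keep base, add a random one)
            out.append(ch)
            out.append(str(rng.choice(BASES)))
        # else deletion: drop the base
    return "".join(out)


def simulate_long_reads(
    genome: os.PathLike | str | Dict[str, str],
    n: int,
    params: SimParams,
    out: os.PathLike | str,
    truth: str = "microbe",
) -> int:
    """Write n nanopore-like reads with gamma-distributed lengths."""
    items = _load_sequences(genome)
    rng = np.random.default_rng(params.seed)
    picks = _pick_sources(items, n, rng) if n else np.array([], dtype=int)
    with FastqWriter(out) as w:
        for serial, src_i in enumerate(picks):
            name, seq = items[src_i]
            L = len(seq)
            scale = params.long_len_mean / params.long_len_shape
            rlen = int(rng.gamma(params.long_len_shape, scale))
            rlen = max(200, min(rlen, L))
            start = int(rng.integers(0, L - rlen + 1))
            fragment = seq[start : start + rlen]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                fragment = revcomp(fragment)
            read_seq = _long_read_errors(fragment, params.err_rate, rng)
            if not read_seq:
                read_seq = fragment  # degenerate: all bases deleted
            rid = Provenance(name, start, strand, truth).encode(serial)
            w.write(ReadRecord(rid, read_seq, LONG_QUAL_CHAR * len(read_seq), None))
    return n


def mix_contamination(
    host_fastqs: Sequence[os.PathLike | str],
    microbe_fastqs: Sequence[os.PathLike | str],
    seed: int,
    out_fastqs: Sequence[os.PathLike | str],
    truth_tsv: os.PathLike | str,
) -> Dict[str, int]:
    """Shuffle host and microbe reads together deterministically.

    Inputs must share layout (both paired = two files, or both single).
    The truth table has one row per read/pair: read_id <TAB> truth, with
    truth decoded from each read's provenance id.
    """
    if len(host_fastqs) != len(microbe_fastqs) or len(host_fastqs) not in (1, 2):
        raise UsageError("host and microbe inputs must both be single or both paired")
    if len(out_fastqs) != len(host_fastqs):
        raise UsageError("output layout must match input layout")
    paired = len(host_fastqs) == 2

    units: List[Tuple[ReadRecord, ...]] = []
    for group in (host_fastqs, microbe_fastqs):
        if paired:
            r1 = list(read_fastq(group[0], mate=1))
            r2 = list(read_fastq(group[1], mate=2))
            if len(r1) != len(r2):
                raise UsageError(f"paired inputs {group} have unequal counts")
            units.extend(zip(r1, r2))
        else:
            units.extend((rec,) for rec in read_fastq(group[0]))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))

    label_counts = {label: 0 for label in TRUTH_LABELS}
    with open(truth_tsv, "wt") as truth_out:
        truth_out.write("read_id\ttruth\n")
        writers = [FastqWriter(p).__enter__() for p in out_fastqs]
        try:
            for i in order:
                unit = units[i]
                base, _ = split_read_id(unit[0].read_id)
                label = Provenance.parse(base).truth
                label_counts[label] += 1
                truth_out.write(f"{base}\t{label}\n")
                for w, rec in zip(writers, unit):
                    w.write(rec)
        finally:
            for w in writers:
                w.__exit__(None, None, None)
    return label_counts
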