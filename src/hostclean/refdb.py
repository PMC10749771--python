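"""Host reference databases: naming, microbe-masking, and aligner indexes.

A reference database is a FASTA plus a short filesystem-safe name.  Masking
finds host regions locally similar to a panel of microbe genomes and
replaces them with N, writing the interval set as 3-column BED (0-based,
half-open).  Two similarity searches are provided: genome-to-genome
alignment with minimap2 (default when the binary is available) and a pure
exact-substring fallback that needs no external binary.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .errors import EnvError, PipelineError, StaleIndexError, ValidationError

FASTA_WRAP = 60
DEFAULT_MIN_MATCH_LEN = 100
DEFAULT_MIN_IDENTITY = 0.80

_NAME_RE = re.compile(r"^[A-Za-z0-9._-]+$")


@dataclass
class MaskInterval:
    """0-based half-open interval on a host sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceDb:
    """A named host reference FASTA, optionally microbe-masked."""

    name: str
    fasta_path: Path
    masked: bool = False
    mask_bed_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.name or not _NAME_RE.match(self.name):
            raise ValidationError(
                f"reference name {self.name!r} must be non-empty and contain "
                "only [A-Za-z0-9._-]"
            )
        self.fasta_path = Path(self.fasta_path)
        if self.masked and self.mask_bed_path is None:
            raise ValidationError("masked=True requires mask_bed_path")


def merge_intervals(intervals: Iterable[MaskInterval]) -> List[MaskInterval]:
    """Sort by (seq_id, start) and merge overlapping/adjacent intervals.

    The union of covered bases is preserved exactly.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.seq_id, iv.start, iv.end))
    merged: List[MaskInterval] = []
    for iv in ordered:
        if merged and merged[-1].seq_id == iv.seq_id and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = MaskInterval(iv.seq_id, merged[-1].start, iv.end)
        else:
            merged.append(MaskInterval(iv.seq_id, iv.start, iv.end))
    return merged


def read_fasta(path: os.PathLike | str) -> Dict[str, str]:
    """Read a (plain or gzip) FASTA into an ordered {name: sequence} dict."""
    from .fastq import open_text

    path = os.fspath(path)
    if not os.path.exists(path):
        raise EnvError(f"FASTA not found: {path}")
    with open_text(path) as handle:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    return seqs


def write_fasta(seqs: Dict[str, str], path: os.PathLike | str) -> None:
    with open(path, "wt") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                out.write(seq[i : i + FASTA_WRAP] + "\n")


def write_bed(intervals: Sequence[MaskInterval], path: os.PathLike | str) -> None:
    with open(path, "wt") as out:
        for iv in intervals:
            out.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def read_bed(path: os.PathLike | str) -> List[MaskInterval]:
    intervals = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            seq_id, start, end = line.split("\t")[:3]
            intervals.append(MaskInterval(seq_id, int(start), int(end)))
    return intervals


# ---------------------------------------------------------------------------
# similarity search


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def find_intervals_kmer(
    host_seqs: Dict[str, str],
    microbe_seqs: Dict[str, str],
    min_match_length: int = DEFAULT_MIN_MATCH_LEN,
) -> List[MaskInterval]:
    """Exact-substring similarity search (binary-free fallback).

    Seeds 31-mers of the host, extends maximal exact matches against each
    microbe genome (both strands), keeps matches >= min_match_length.
    """
    k = min(31, min_match_length)
    index: Dict[str, List[Tuple[str, int]]] = {}
    for name, seq in host_seqs.items():
        up = seq.upper()
        for i in range(0, len(up) - k + 1):
            kmer = up[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((name, i))

    intervals: List[MaskInterval] = []
    for mseq in microbe_seqs.values():
        for strand_seq in (mseq.upper(), _revcomp(mseq.upper())):
            j = 0
            L = len(strand_seq)
            while j <= L - k:
                hits = index.get(strand_seq[j : j + k])
                if not hits:
                    j += 1
                    continue
                best_ext = 0
                for hname, hpos in hits:
                    hseq = host_seqs[hname].upper()
                    # extend right
                    e = k
                    while j + e < L and hpos + e < len(hseq) and strand_seq[j + e] == hseq[hpos + e]:
                        e += 1
                    # extend left
                    s = 0
                    while j - s - 1 >= 0 and hpos - s - 1 >= 0 and strand_seq[j - s - 1] == hseq[hpos - s - 1]:
                        s += 1
                    total = s + e
                    if total >= min_match_length:
                        intervals.append(MaskInterval(hname, hpos - s, hpos + e))
                    best_ext = max(best_ext, e)
                j += max(1, best_ext - k + 1)
    return merge_intervals(intervals)


def find_intervals_minimap2(
    host_fasta: os.PathLike | str,
    microbe_fastas: Sequence[os.PathLike | str],
    min_match_length: int = DEFAULT_MIN_MATCH_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    threads: int = 1,
) -> List[MaskInterval]:
    """Map microbe genomes onto the host with minimap2 (asm20 preset) and
    convert PAF hits to host-coordinate intervals filtered by length and
    identity (matching bases / alignment block length)."""
    if shutil.which("minimap2") is None:
        raise EnvError("minimap2 not found on PATH; install it or use method='kmer'")
    intervals: List[MaskInterval] = []
    for microbe in microbe_fastas:
        argv = [
            "minimap2",
            "-x",
            "asm20",
            "-t",
            str(threads),
            os.fspath(host_fasta),
            os.fspath(microbe),
        ]
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            raise PipelineError(
                f"minimap2 failed ({proc.returncode}): {proc.stderr[-500:]}"
            )
        for line in proc.stdout.splitlines():
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                continue
            tname, tstart, tend = cols[5], int(cols[7]), int(cols[8])
            matches, block = int(cols[9]), int(cols[10])
            if block == 0 or tend - tstart < min_match_length:
                continue
            if matches / block < min_identity:
                continue
            intervals.append(MaskInterval(tname, tstart, tend))
    return merge_intervals(intervals)


def mask_reference(
    host_fasta: os.PathLike | str,
    microbe_fastas: Sequence[os.PathLike | str],
    out_fasta: os.PathLike | str,
    out_bed: os.PathLike | str,
    min_match_length: int = DEFAULT_MIN_MATCH_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    method: str = "auto",
    threads: int = 1,
) -> Tuple[Path, List[MaskInterval]]:
    """Hard-mask host regions similar to any microbe genome with N.

    Sequence names, order and lengths are preserved; only masked positions
    change.  Returns the output FASTA path and the merged interval set.
    """
    host_seqs = read_fasta(host_fasta)
    if not host_seqs or any(len(s) == 0 for s in host_seqs.values()):
        raise ValidationError(f"host FASTA {host_fasta} is empty or has empty sequences")

    if method == "auto":
        method = "minimap2" if shutil.which("minimap2") else "kmer"
    if not microbe_fastas:
        intervals: List[MaskInterval] = []
    elif method == "minimap2":
        intervals = find_intervals_minimap2(
            host_fasta, microbe_fastas, min_match_length, min_identity, threads
        )
    elif method == "kmer":
        microbe_seqs: Dict[str, str] = {}
        for path in microbe_fastas:
            microbe_seqs.update(read_fasta(path))
        intervals = find_intervals_kmer(host_seqs, microbe_seqs, min_match_length)
    else:
        raise ValidationError(f"unknown masking method {method!r}")

    for iv in intervals:
        if iv.seq_id not in host_seqs or iv.end > len(host_seqs[iv.seq_id]):
            raise ValidationError(f"interval {iv} outside host sequence bounds")

    masked = dict(host_seqs)
    for iv in intervals:
        seq = masked[iv.seq_id]
        masked[iv.seq_id] = seq[: iv.start] + "N" * len(iv) + seq[iv.end :]

    write_fasta(masked, out_fasta)
    write_bed(intervals, out_bed)
    return Path(out_fasta), intervals


# ---------------------------------------------------------------------------
# index building

INDEX_PRESETS = {"short": "sr", "long": "map-ont"}


def _sha256(path: os.PathLike | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def index_path_for(db: ReferenceDb, backend: str, out_dir: Optional[os.PathLike | str] = None) -> Path:
    directory = Path(out_dir) if out_dir else db.fasta_path.parent
    return directory / f"{db.name}.{backend}.mmi"


def build_index(
    db: ReferenceDb,
    backend: str,
    out_dir: Optional[os.PathLike | str] = None,
    threads: int = 1,
) -> Path:
    """Build (or reuse) a minimap2 index for ``db`` under a deterministic name.

    A sidecar JSON records the source FASTA checksum; a rebuild is skipped
    when the checksum still matches (idempotence).
    """
    if backend not in INDEX_PRESETS:
        raise ValidationError(f"backend must be 'short' or 'long', got {backend!r}")
    if not db.fasta_path.exists():
        raise EnvError(f"FASTA not found: {db.fasta_path}")
    if shutil.which("minimap2") is None:
        raise EnvError(
            "minimap2 not found on PATH (install via conda/bioconda: minimap2)"
        )
    idx = index_path_for(db, backend, out_dir)
    sidecar = idx.with_suffix(idx.suffix + ".json")
    checksum = _sha256(db.fasta_path)
    if idx.exists() and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("fasta_sha256") == checksum:
            return idx
    argv = [
        "minimap2",
        "-x",
        INDEX_PRESETS[backend],
        "-t",
        str(threads),
        "-d",
        os.fspath(idx),
        os.fspath(db.fasta_path),
    ]
    proc = subprocess.run(argv, capture_output=True, text=True)
    if proc.returncode != 0:
        raise PipelineError(f"minimap2 indexing failed: {proc.stderr[-500:]}")
    sidecar.write_text(
        json.dumps(
            {
                "name": db.name,
                "backend": backend,
                "fasta": os.fspath(db.fasta_path),
                "fasta_sha256": checksum,
            },
            indent=2,
        )
    )
    return idx


def validate_index(db: ReferenceDb, index: os.PathLike | str) -> None:
    """Raise StaleIndexError if the index no longer matches its FASTA."""
    idx = Path(index)
    sidecar = idx.with_suffix(idx.suffix + ".json")
    if not idx.exists():
        raise EnvError(f"index not found: {idx}")
    if not sidecar.exists():
        return
    meta = json.loads(sidecar.read_text())
    if not db.fasta_path.exists():
        raise StaleIndexError(f"source FASTA {db.fasta_path} no longer exists")
    if _sha256(db.fasta_path) != meta.get("fasta_sha256"):
        raise StaleIndexError(f"index {idx} is stale: FASTA checksum changed")
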