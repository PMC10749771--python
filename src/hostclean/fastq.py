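"""Streaming FASTQ I/O with reproducible gzip output.

Reads plain or gzip-compressed 4-line FASTQ; writes gzip with a zeroed
mtime and no embedded filename so repeated runs produce identical bytes.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError

GZIP_LEVEL = 6


@dataclass
class ReadRecord:
    """One FASTQ read. ``mate`` is None for single-end data, else 1 or 2."""

    read_id: str
    sequence: str
    quality: str
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality) or not self.sequence:
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)} (both must be > 0)"
            )


def split_read_id(raw: str) -> Tuple[str, Optional[int]]:
    """Return (base_id, mate) for a raw FASTQ/SAM id.

    Text after the first whitespace is dropped; a trailing ``/1`` or ``/2``
    is stripped and reported as the mate number.
    """
    base = raw.split(None, 1)[0] if raw else raw
    if base.endswith("/1"):
        return base[:-2], 1
    if base.endswith("/2"):
        return base[:-2], 2
    return base, None


def open_text(path: os.PathLike | str, mode: str = "rt") -> IO[str]:
    """Open plain or gzip text transparently (by suffix for writing,
    by magic bytes for reading)."""
    path = os.fspath(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt")
        return open(path, "rt")
    if path.endswith(".gz"):
        return _deterministic_gzip_writer(path)
    return open(path, "wt")


def _deterministic_gzip_writer(path: str) -> IO[str]:
    raw = open(path, "wb")
    gz = gzip.GzipFile(
        filename="", fileobj=raw, mode="wb", compresslevel=GZIP_LEVEL, mtime=0
    )
    text = io.TextIOWrapper(gz, encoding="ascii", newline="\n")
    # closing the TextIOWrapper closes gz but not the underlying raw handle
    orig_close = text.close

    def close() -> None:
        orig_close()
        raw.close()

    text.close = close  # type: ignore[method-assign]
    return text


def read_fastq(path: os.PathLike | str, mate: Optional[int] = None) -> Iterator[ReadRecord]:
    """Yield ReadRecords from a plain or gzipped FASTQ file."""
    with open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield ReadRecord(title, seq, qual, mate)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


class FastqWriter:
    """Context manager writing ReadRecords to a (gzip) FASTQ file."""

    def __init__(self, path: os.PathLike | str):
        self.path = os.fspath(path)
        self._handle: Optional[IO[str]] = None
        self.n_written = 0

    def __enter__(self) -> "FastqWriter":
        self._handle = open_text(self.path, "wt")
        return self

    def write(self, rec: ReadRecord) -> None:
        assert self._handle is not None
        self._handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
        self.n_written += 1

    def __exit__(self, *exc) -> None:
        assert self._handle is not None
        self._handle.close()


def write_fastq(records: Iterable[ReadRecord], path: os.PathLike | str) -> int:
    """Write records to ``path``; returns number written."""
    with FastqWriter(path) as out:
        for rec in records:
            out.write(rec)
        return out.n_written


def count_reads(path: os.PathLike | str) -> int:
    return sum(1 for _ in read_fastq(path))
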