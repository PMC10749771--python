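"""Aligner invocation planning and streaming SAM consumption.

Both backends are minimap2: the ``sr`` preset for short reads and the
``map-ont`` preset for long reads, each with a minimum chaining score
enforced at invocation (``-m``, default 40) and secondary alignments
suppressed so a single high-quality match per read suffices.  The plan/run
split keeps the exact argv in one place, pinned by a golden test.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Optional, Tuple

from .errors import EnvError, FormatError, PipelineError, UsageError

DEFAULT_MIN_CHAIN_SCORE = 40
PRESETS = {"short": "sr", "long": "map-ont"}

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignerSpec:
    """How to invoke a backend: index, preset, threads, chain-score floor."""

    backend: str  # "short" | "long"
    index_path: Optional[os.PathLike | str] = None
    threads: int = 1
    preset: Optional[str] = None
    min_chain_score: int = DEFAULT_MIN_CHAIN_SCORE
    extra_args: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.backend not in PRESETS:
            raise UsageError(f"backend must be 'short' or 'long', got {self.backend!r}")
        if self.min_chain_score < 0:
            raise UsageError("min_chain_score must be >= 0")
        if self.threads < 1:
            raise UsageError("threads must be >= 1")
        if self.preset is None:
            self.preset = PRESETS[self.backend]


@dataclass
class CommandPlan:
    argv: List[str]
    stdout_contract: str = "SAM stream"


@dataclass
class AlignmentRecord:
    """A SAM line reduced to the fields the removal decision needs."""

    query_name: str
    is_mapped: bool
    is_paired: bool = False
    is_first_mate: bool = False
    is_second_mate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    chain_score: Optional[int] = None
    target: Optional[str] = None


def plan_alignment(
    spec: AlignerSpec,
    fastq1: os.PathLike | str,
    fastq2: Optional[os.PathLike | str] = None,
) -> CommandPlan:
    """Build the minimap2 argv streaming SAM to stdout.

    Paired input is only valid with the short backend.
    """
    if fastq2 is not None and spec.backend == "long":
        raise UsageError("paired FASTQ input requires the short-read backend")
    if spec.index_path is None:
        raise EnvError("no index configured for alignment")
    argv = [
        "minimap2",
        "-a",
        "-x",
        spec.preset,
        "-m",
        str(spec.min_chain_score),
        "--secondary=no",
        "-t",
        str(spec.threads),
        *spec.extra_args,
        os.fspath(spec.index_path),
        os.fspath(fastq1),
    ]
    if fastq2 is not None:
        argv.append(os.fspath(fastq2))
    return CommandPlan(argv=argv)


def parse_sam_line(line: str, lineno: int) -> Optional[AlignmentRecord]:
    """Parse one SAM body line; returns None for header lines.

    The chaining score is taken from the ``s1`` tag when present, falling
    back to ``ms`` then ``AS``.
    """
    if line.startswith("@"):
        return None
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 11:
        raise FormatError(f"malformed SAM line {lineno}: expected >=11 fields, got {len(cols)}")
    try:
        flag = int(cols[1])
    except ValueError as exc:
        raise FormatError(f"malformed SAM line {lineno}: non-integer FLAG {cols[1]!r}") from exc
    chain_score: Optional[int] = None
    for tag_prefix in ("s1:i:", "ms:i:", "AS:i:"):
        for tag in cols[11:]:
            if tag.startswith(tag_prefix):
                chain_score = int(tag[5:])
                break
        if chain_score is not None:
            break
    mapped = not flag & FLAG_UNMAPPED
    return AlignmentRecord(
        query_name=cols[0],
        is_mapped=mapped,
        is_paired=bool(flag & FLAG_PAIRED),
        is_first_mate=bool(flag & FLAG_FIRST),
        is_second_mate=bool(flag & FLAG_SECOND),
        is_secondary=bool(flag & FLAG_SECONDARY),
        is_supplementary=bool(flag & FLAG_SUPPLEMENTARY),
        chain_score=chain_score,
        target=cols[2] if mapped and cols[2] != "*" else None,
    )


def iter_sam(lines: Iterable[str]) -> Iterator[AlignmentRecord]:
    """Parse an iterable of SAM lines, skipping headers."""
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        rec = parse_sam_line(line, lineno)
        if rec is not None:
            yield rec


def read_sam_file(path: os.PathLike | str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM file (the --offline-sam path)."""
    from .fastq import open_text

    with open_text(path) as handle:
        yield from iter_sam(handle)


def run_alignment(plan: CommandPlan) -> Iterator[AlignmentRecord]:
    """Run the planned aligner, yielding parsed records in stream order.

    Memory stays bounded: records are parsed line by line off the pipe.
    The subprocess exit status is checked when the stream is exhausted; a
    nonzero exit raises PipelineError carrying the stderr tail.
    """
    if shutil.which(plan.argv[0]) is None:
        raise EnvError(
            f"aligner binary {plan.argv[0]!r} not found on PATH "
            "(install via conda/bioconda)"
        )
    with tempfile.TemporaryFile(mode="w+b") as err:
        proc = subprocess.Popen(plan.argv, stdout=subprocess.PIPE, stderr=err, text=True)
        assert proc.stdout is not None
        try:
            yield from iter_sam(proc.stdout)
        finally:
            proc.stdout.close()
            returncode = proc.wait()
        if returncode != 0:
            err.seek(0)
            tail = err.read().decode(errors="replace")[-1000:]
            raise PipelineError(
                f"aligner exited with status {returncode}: {tail}"
            )


def minimap2_version() -> str:
    if shutil.which("minimap2") is None:
        return "unavailable"
    out = subprocess.run(["minimap2", "--version"], capture_output=True, text=True)
    return out.stdout.strip() or "unknown"
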