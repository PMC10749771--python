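"""The decision core: keep/remove per read with pair-aware semantics.

Subtractive semantics: only positive host evidence removes a read.  Reads
present in the FASTQ but absent from the alignment stream are kept.  In
paired mode, if either mate aligns to the host both mates are removed
(the non-aligned mate with reason ``mate_aligned``).

Decision keys: single-end decisions are keyed by the base read id; paired
decisions by ``<base>/1`` and ``<base>/2`` so the two mates can carry
different reasons.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import zip_longest
from typing import Dict, Iterable, Iterator, Optional, Tuple

from .align import AlignerSpec, AlignmentRecord
from .errors import FormatError
from .fastq import FastqWriter, ReadRecord, read_fastq, split_read_id

REASON_NONE = "none"
REASON_SELF = "self_aligned"
REASON_MATE = "mate_aligned"


@dataclass
class RemovalDecision:
    read_id: str
    remove: bool
    reason: str = REASON_NONE

    def __post_init__(self) -> None:
        if (self.reason == REASON_NONE) != (not self.remove):
            raise ValueError("reason must be 'none' iff remove is False")


def classify_alignment(aln: AlignmentRecord, spec: AlignerSpec) -> bool:
    """True iff this record is host-removal evidence for its read.

    Short backend: any reported alignment.  Long backend: mapped with a
    chaining score at or above the spec threshold; a mapped record with no
    score tag is treated as removal evidence (fail-safe — the threshold is
    also enforced at the aligner invocation).
    """
    if not aln.is_mapped:
        return False
    if spec.backend == "short":
        return True
    if aln.chain_score is None:
        return True
    return aln.chain_score >= spec.min_chain_score


def decide_reads(
    alns: Iterable[AlignmentRecord],
    spec: AlignerSpec,
    paired: bool,
) -> Tuple[Dict[str, RemovalDecision], int]:
    """Reduce an alignment stream to one decision per distinct read.

    Returns (decisions, n_distinct) where n_distinct counts distinct
    (read id, mate) units observed in the stream.  Secondary and
    supplementary records contribute to their read's decision by OR.
    """
    # base id -> [seen_mate1, seen_mate2_or_single, removed1, removed2]
    state: Dict[str, list] = {}
    for aln in alns:
        base, suffix_mate = split_read_id(aln.query_name)
        if paired:
            if aln.is_first_mate:
                mate = 1
            elif aln.is_second_mate:
                mate = 2
            elif suffix_mate is not None:
                mate = suffix_mate
            else:
                raise FormatError(
                    f"paired mode: record {aln.query_name!r} carries neither mate flag"
                )
        else:
            mate = 1
        slot = state.setdefault(base, [False, False, False, False])
        slot[mate - 1] = True
        if classify_alignment(aln, spec):
            slot[mate + 1] = True

    decisions: Dict[str, RemovalDecision] = {}
    n_distinct = 0
    for base, (seen1, seen2, rm1, rm2) in state.items():
        n_distinct += int(seen1) + int(seen2)
        if paired:
            pair_remove = rm1 or rm2
            for mate, self_rm in ((1, rm1), (2, rm2)):
                key = f"{base}/{mate}"
                if pair_remove:
                    reason = REASON_SELF if self_rm else REASON_MATE
                    decisions[key] = RemovalDecision(key, True, reason)
                else:
                    decisions[key] = RemovalDecision(key, False)
        else:
            if rm1:
                decisions[base] = RemovalDecision(base, True, REASON_SELF)
            else:
                decisions[base] = RemovalDecision(base, False)
    return decisions, n_distinct


def rename_reads(stream: Iterable[ReadRecord], start: int = 1) -> Iterator[ReadRecord]:
    """Replace read ids with incrementing integers; mates of a pair share
    the integer (consecutive records with the same base id)."""
    counter = start - 1
    prev_base: Optional[str] = None
    for rec in stream:
        base, _ = split_read_id(rec.read_id)
        if base != prev_base:
            counter += 1
            prev_base = base
        yield ReadRecord(str(counter), rec.sequence, rec.quality, rec.mate)


def _decision_for(
    decisions: Dict[str, RemovalDecision], base: str, mate: Optional[int]
) -> Optional[RemovalDecision]:
    if mate is not None:
        hit = decisions.get(f"{base}/{mate}")
        if hit is not None:
            return hit
    return decisions.get(base)


def apply_decisions(
    in1: os.PathLike | str,
    in2: Optional[os.PathLike | str],
    decisions: Dict[str, RemovalDecision],
    out1: os.PathLike | str,
    out2: Optional[os.PathLike | str] = None,
    rename: bool = False,
    rename_start: int = 1,
    id_map_path: Optional[os.PathLike | str] = None,
) -> Dict[str, object]:
    """Stream FASTQ input(s) to gzip FASTQ output(s), dropping removed reads.

    Input order is preserved among kept reads; paired outputs always have
    equal record counts with positionally matching ids.  Returns per-file
    and total counts satisfying reads_in = reads_out + reads_removed.
    """
    paired = in2 is not None
    if paired and out2 is None:
        raise FormatError("paired input requires two output paths")

    counts = {
        "reads_in": 0,
        "reads_out": 0,
        "reads_removed": 0,
        "per_file": [],
    }
    n_in1 = n_in2 = n_out1 = n_out2 = 0
    next_int = rename_start
    id_map: list[Tuple[str, str]] = []

    with FastqWriter(out1) as w1:
        if paired:
            w2 = FastqWriter(out2).__enter__()
        try:
            reads1 = read_fastq(in1, mate=1 if paired else None)
            reads2 = read_fastq(in2, mate=2) if paired else iter(())
            for pos, (r1, r2) in enumerate(zip_longest(reads1, reads2), start=1):
                if paired:
                    if r1 is None or r2 is None:
                        shorter = in1 if r1 is None else in2
                        raise FormatError(
                            f"paired inputs have unequal length; {shorter} is shorter"
                        )
                    b1, m1 = split_read_id(r1.read_id)
                    b2, m2 = split_read_id(r2.read_id)
                    if b1 != b2:
                        raise FormatError(
                            f"read id mismatch at record {pos}: {b1!r} vs {b2!r}"
                        )
                    n_in1 += 1
                    n_in2 += 1
                    d = _decision_for(decisions, b1, 1)
                    remove = bool(d and d.remove)
                    if not remove:
                        if rename:
                            new_id = str(next_int)
                            id_map.append((b1, new_id))
                            next_int += 1
                            r1 = ReadRecord(new_id, r1.sequence, r1.quality, 1)
                            r2 = ReadRecord(new_id, r2.sequence, r2.quality, 2)
                        w1.write(r1)
                        w2.write(r2)
                        n_out1 += 1
                        n_out2 += 1
                else:
                    n_in1 += 1
                    base, mate = split_read_id(r1.read_id)
                    d = _decision_for(decisions, base, mate)
                    if not (d and d.remove):
                        if rename:
                            new_id = str(next_int)
                            id_map.append((base, new_id))
                            next_int += 1
                            r1 = ReadRecord(new_id, r1.sequence, r1.quality, None)
                        w1.write(r1)
                        n_out1 += 1
        finally:
            if paired:
                w2.__exit__(None, None, None)

    counts["per_file"] = [
        {"path": os.fspath(in1), "reads_in": n_in1, "reads_out": n_out1,
         "reads_removed": n_in1 - n_out1},
    ]
    if paired:
        counts["per_file"].append(
            {"path": os.fspath(in2), "reads_in": n_in2, "reads_out": n_out2,
             "reads_removed": n_in2 - n_out2}
        )
    counts["reads_in"] = n_in1 + n_in2
    counts["reads_out"] = n_out1 + n_out2
    counts["reads_removed"] = counts["reads_in"] - counts["reads_out"]

    if id_map_path is not None:
        with open(id_map_path, "wt") as handle:
            handle.write("original_id\tnew_id\n")
            for old, new in id_map:
                handle.write(f"{old}\t{new}\n")
    return counts
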