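"""JSON run reports with conservation-checked read accounting."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .errors import ConservationError

TOOL_VERSION = "0.1.0"


def _sig10(x: float) -> float:
    """Round to 10 significant digits for stable serialization."""
    return float(f"{x:.10g}")


@dataclass
class DecontamReport:
    """Per-sample accounting and run metadata.

    Invariant (checked at construction and again on write):
    reads_in = reads_out + reads_removed.
    """

    aligner: str
    aligner_version: str
    index_name: str
    fastq1: str
    reads_in: int
    reads_out: int
    reads_removed: int
    fastq2: Optional[str] = None
    rename: bool = False
    threads: int = 1
    min_chain_score: int = 40
    tool_version: str = TOOL_VERSION
    per_file: List[Dict[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        if self.reads_in != self.reads_out + self.reads_removed:
            raise ConservationError(
                f"reads_in ({self.reads_in}) != reads_out ({self.reads_out}) "
                f"+ reads_removed ({self.reads_removed})"
            )
        for entry in self.per_file:
            if entry["reads_in"] != entry["reads_out"] + entry["reads_removed"]:
                raise ConservationError(f"per-file conservation violated: {entry}")

    @property
    def reads_removed_proportion(self) -> float:
        if self.reads_in == 0:
            return 0.0
        return self.reads_removed / self.reads_in

    def to_dict(self) -> Dict[str, object]:
        self.check()
        return {
            "tool_version": self.tool_version,
            "aligner": self.aligner,
            "aligner_version": self.aligner_version,
            "index_name": self.index_name,
            "options": {
                "rename": self.rename,
                "threads": self.threads,
                "min_chain_score": self.min_chain_score,
            },
            "fastq1": self.fastq1,
            "fastq2": self.fastq2,
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "reads_removed": self.reads_removed,
            "reads_removed_proportion": _sig10(self.reads_removed_proportion),
            "per_file": self.per_file,
        }


def render_report(reports: Sequence[DecontamReport]) -> str:
    """Serialize one report list (always a list, even for one sample)."""
    return json.dumps([r.to_dict() for r in reports], indent=2) + "\n"


def write_report(
    reports: Sequence[DecontamReport], path: Optional[os.PathLike | str] = None
) -> str:
    text = render_report(reports)
    if path is not None:
        with open(path, "wt") as out:
            out.write(text)
    return text
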