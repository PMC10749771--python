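"""End-to-end decontamination: align -> decide -> filter -> report.

One streaming pass: the SAM stream from the aligner (or an offline SAM
file) is reduced to a decision map, then the FASTQ input is streamed once
to gzip-compressed output.  No uncompressed intermediate FASTQ is written
at any point.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

from .align import (
    AlignerSpec,
    minimap2_version,
    plan_alignment,
    read_sam_file,
    run_alignment,
)
from .errors import EnvError, UsageError
from .filtering import apply_decisions, decide_reads
from .report import DecontamReport


def _stem(path: os.PathLike | str) -> str:
    name = Path(path).name
    for suffix in (".fastq.gz", ".fq.gz", ".fastq", ".fq"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


@dataclass
class CleanResult:
    report: DecontamReport
    out1: Path
    out2: Optional[Path]
    id_map: Optional[Path]


def run_clean(
    fastq1: os.PathLike | str,
    fastq2: Optional[os.PathLike | str] = None,
    index: Optional[os.PathLike | str] = None,
    backend: str = "short",
    out_dir: os.PathLike | str = ".",
    rename: bool = False,
    threads: int = 1,
    min_chain_score: int = 40,
    offline_sam: Optional[os.PathLike | str] = None,
    index_name: Optional[str] = None,
) -> CleanResult:
    """Decontaminate FASTQ input against a host index.

    ``offline_sam`` substitutes a pre-computed SAM file for the aligner
    invocation (hermetic testing escape hatch).
    """
    paired = fastq2 is not None
    if not Path(fastq1).exists():
        raise UsageError(f"FASTQ not found: {fastq1}")
    if paired and not Path(fastq2).exists():
        raise UsageError(f"FASTQ not found: {fastq2}")
    if offline_sam is None and index is None:
        raise EnvError("an index is required unless --offline-sam is given")
    if offline_sam is None and not Path(index).exists():
        raise EnvError(f"index not found: {index}")

    spec = AlignerSpec(
        backend=backend,
        index_path=index,
        threads=threads,
        min_chain_score=min_chain_score,
    )
    if offline_sam is not None:
        alns = read_sam_file(offline_sam)
        aligner_version = "offline-sam"
    else:
        plan = plan_alignment(spec, fastq1, fastq2)
        alns = run_alignment(plan)
        aligner_version = f"minimap2 {minimap2_version()}"

    decisions, _n_distinct = decide_reads(alns, spec, paired)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if paired:
        out1 = out_dir / f"{_stem(fastq1)}.clean_1.fastq.gz"
        out2 = out_dir / f"{_stem(fastq2)}.clean_2.fastq.gz"
    else:
        out1 = out_dir / f"{_stem(fastq1)}.clean.fastq.gz"
        out2 = None
    id_map = out_dir / f"{_stem(fastq1)}.rename_map.tsv" if rename else None

    counts = apply_decisions(
        fastq1, fastq2, decisions, out1, out2, rename=rename, id_map_path=id_map
    )

    report = DecontamReport(
        aligner=backend,
        aligner_version=aligner_version,
        index_name=index_name or (Path(index).name if index else "offline"),
        fastq1=os.fspath(fastq1),
        fastq2=os.fspath(fastq2) if paired else None,
        reads_in=counts["reads_in"],
        reads_out=counts["reads_out"],
        reads_removed=counts["reads_removed"],
        rename=rename,
        threads=threads,
        min_chain_score=min_chain_score,
        per_file=counts["per_file"],
    )
    return CleanResult(report=report, out1=out1, out2=out2, id_map=id_map)
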