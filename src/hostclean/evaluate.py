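"""Truth-based accuracy metrics: retention by class, run deltas, and
viral-subtraction adjustment of host-retention figures.

Percentages are kept as exact ratios internally and only rounded to six
significant figures for display; multi-sample aggregation sums numerators
and denominators before dividing (never mean-of-means).
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import FormatError, UsageError, ValidationError
from .fastq import read_fastq, split_read_id
from .pipeline import run_clean
from .refdb import ReferenceDb, build_index

TRUTH_CLASSES = ("host", "microbe", "viral")


def _pct(numerator: int, denominator: int) -> float:
    return 100.0 * numerator / denominator if denominator else 0.0


def fmt_pct(value: float) -> str:
    """Render a percentage to 6 significant figures (display only)."""
    return f"{value:.6g}"


@dataclass
class RetentionMetrics:
    n_host_in: int = 0
    n_host_retained: int = 0
    n_microbe_in: int = 0
    n_microbe_retained: int = 0
    n_viral_in: int = 0
    n_viral_retained: int = 0

    def __post_init__(self) -> None:
        for cls in ("host", "microbe", "viral"):
            n_in = getattr(self, f"n_{cls}_in")
            n_ret = getattr(self, f"n_{cls}_retained")
            if not 0 <= n_ret <= n_in:
                raise ValidationError(
                    f"{cls}: retained count {n_ret} outside [0, {n_in}]"
                )

    @property
    def host_retention(self) -> float:
        return _pct(self.n_host_retained, self.n_host_in)

    @property
    def microbe_retention(self) -> float:
        return _pct(self.n_microbe_retained, self.n_microbe_in)

    @property
    def host_removal(self) -> float:
        return 100.0 - self.host_retention if self.n_host_in else 0.0

    @property
    def n_microbe_removed(self) -> int:
        return self.n_microbe_in - self.n_microbe_retained

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_host_in": self.n_host_in,
            "n_host_retained": self.n_host_retained,
            "n_microbe_in": self.n_microbe_in,
            "n_microbe_retained": self.n_microbe_retained,
            "n_viral_in": self.n_viral_in,
            "n_viral_retained": self.n_viral_retained,
            "host_retention_pct": float(fmt_pct(self.host_retention)),
            "microbe_retention_pct": float(fmt_pct(self.microbe_retention)),
        }


def read_truth(path: os.PathLike | str) -> Dict[str, str]:
    truth: Dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("read_id\t"):
                continue
            try:
                read_id, label = line.split("\t")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: expected 2 columns") from exc
            if label not in TRUTH_CLASSES:
                raise FormatError(f"{path}:{lineno}: unknown truth label {label!r}")
            truth[read_id] = label
    return truth


def _load_id_map(path: os.PathLike | str) -> Dict[str, str]:
    """new_id -> original_id from the rename sidecar TSV."""
    mapping: Dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("original_id\t"):
                continue
            old, new = line.split("\t")
            mapping[new] = old
    return mapping


def score_retention(
    truth_path: os.PathLike | str,
    fastq1: os.PathLike | str,
    fastq2: Optional[os.PathLike | str] = None,
    id_map: Optional[os.PathLike | str] = None,
) -> RetentionMetrics:
    """Score decontaminated output against a truth table.

    The truth table is keyed by read/pair base id; paired outputs count
    once per pair.  For renamed outputs, pass the rename sidecar TSV.
    """
    truth = read_truth(truth_path)
    rename_map = _load_id_map(id_map) if id_map else None

    retained: Dict[str, int] = {c: 0 for c in TRUTH_CLASSES}
    unknown: List[str] = []
    for rec in read_fastq(fastq1):
        base, _ = split_read_id(rec.read_id)
        if rename_map is not None:
            base = rename_map.get(base, base)
        label = truth.get(base)
        if label is None:
            if len(unknown) < 10:
                unknown.append(base)
            continue
        retained[label] += 1
    if unknown:
        raise FormatError(
            f"{len(unknown)}+ output reads absent from truth table, e.g. {unknown}"
        )
    if fastq2 is not None:
        n2 = sum(1 for _ in read_fastq(fastq2))
        n1 = sum(retained.values())
        if n1 != n2:
            raise FormatError(
                f"paired outputs disagree: {n1} vs {n2} records"
            )

    totals = {c: 0 for c in TRUTH_CLASSES}
    for label in truth.values():
        totals[label] += 1
    return RetentionMetrics(
        n_host_in=totals["host"],
        n_host_retained=retained["host"],
        n_microbe_in=totals["microbe"],
        n_microbe_retained=retained["microbe"],
        n_viral_in=totals["viral"],
        n_viral_retained=retained["viral"],
    )


def aggregate_metrics(samples: Iterable[RetentionMetrics]) -> RetentionMetrics:
    """Sum numerators and denominators across samples before dividing."""
    total = RetentionMetrics()
    for m in samples:
        total.n_host_in += m.n_host_in
        total.n_host_retained += m.n_host_retained
        total.n_microbe_in += m.n_microbe_in
        total.n_microbe_retained += m.n_microbe_retained
        total.n_viral_in += m.n_viral_in
        total.n_viral_retained += m.n_viral_retained
    return total


@dataclass
class EbvAdjustment:
    viral_index_accessions: List[str]
    n_input: int
    n_retained_before: int
    n_viral_removed: int
    adjusted_host_retention: float

    @property
    def unadjusted_host_retention(self) -> float:
        return _pct(self.n_retained_before, self.n_input)


def ebv_adjust(
    retained_fastq1: os.PathLike | str,
    viral_ref: os.PathLike | str,
    n_original_input: int,
    retained_fastq2: Optional[os.PathLike | str] = None,
    work_dir: Optional[os.PathLike | str] = None,
    backend: str = "short",
    threads: int = 1,
) -> EbvAdjustment:
    """Subtract viral reads from retained output and recompute retention.

    Builds a fresh index from ``viral_ref`` and reruns the decontamination
    pipeline against it; adjusted retention = survivors / original input.
    """
    from .refdb import read_fasta

    viral_seqs = read_fasta(viral_ref)
    if not viral_seqs or all(len(s) == 0 for s in viral_seqs.values()):
        raise ValidationError(f"viral reference {viral_ref} is empty")

    n_before = sum(1 for _ in read_fastq(retained_fastq1))
    if retained_fastq2 is not None:
        n_before += sum(1 for _ in read_fastq(retained_fastq2))

    ctx = (
        tempfile.TemporaryDirectory() if work_dir is None else _nullcontext(work_dir)
    )
    with ctx as tmp:
        Path(tmp).mkdir(parents=True, exist_ok=True)
        db = ReferenceDb(name="viral-subtraction", fasta_path=Path(viral_ref))
        index = build_index(db, backend, out_dir=tmp, threads=threads)
        result = run_clean(
            retained_fastq1,
            retained_fastq2,
            index=index,
            backend=backend,
            out_dir=Path(tmp) / "adjusted",
            threads=threads,
        )
    n_after = result.report.reads_out
    return EbvAdjustment(
        viral_index_accessions=list(viral_seqs),
        n_input=n_original_input,
        n_retained_before=n_before,
        n_viral_removed=n_before - n_after,
        adjusted_host_retention=_pct(n_after, n_original_input),
    )


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def compare_runs(a: RetentionMetrics, b: RetentionMetrics) -> Dict[str, float]:
    """Percentage-point deltas and removed-read fold changes between runs.

    Fold change is removed_b / removed_a; a zero denominator with nonzero
    numerator reports infinity (never a division crash).
    """
    if (a.n_host_in, a.n_microbe_in) != (b.n_host_in, b.n_microbe_in):
        raise UsageError("compare_runs requires the same truth universe")
    removed_a = a.n_microbe_removed
    removed_b = b.n_microbe_removed
    if removed_a == 0:
        fold = 1.0 if removed_b == 0 else math.inf
    else:
        fold = removed_b / removed_a
    return {
        "host_retention_delta_pp": b.host_retention - a.host_retention,
        "microbe_retention_delta_pp": b.microbe_retention - a.microbe_retention,
        "removed_a": float(removed_a),
        "removed_b": float(removed_b),
        "removed_fold_change": fold,
    }


def bootstrap_fold_ci(
    removed_a: Sequence[int],
    removed_b: Sequence[int],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for the mean per-sample removed-read fold
    change (samples with removed_a == 0 are excluded from each resample)."""
    if len(removed_a) != len(removed_b) or not removed_a:
        raise UsageError("need equal-length, non-empty per-sample counts")
    a = np.asarray(removed_a, dtype=float)
    b = np.asarray(removed_b, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(a)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        aa, bb = a[idx], b[idx]
        ok = aa > 0
        stats[i] = np.mean(bb[ok] / aa[ok]) if ok.any() else np.nan
    stats = stats[~np.isnan(stats)]
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
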