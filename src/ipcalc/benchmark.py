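"""Scoring of pI predictions: RMSD, percent difference, outlier counts,
per-record consensus predictions and a table builder.

The percent difference between two methods exploits the log10 pH scale:
``100 * (10**(rmsd_method - rmsd_reference) - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import charge, pka
from .datasets import SequenceRecord
from .errors import DatasetError, EmptyPanelError

AVG_METHOD_NAME = "Avg_pI"


@dataclass(frozen=True)
class BenchmarkResult:
    method_name: str
    rmsd: float
    percent_vs_reference: float
    n_outliers: int
    n_records: int
    r2: Optional[float] = None


def rmsd(predicted: Sequence[float], experimental: Sequence[float]) -> float:
    """Root-mean-square deviation in pH units."""
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise DatasetError(
            f"length mismatch: {predicted.shape} vs {experimental.shape}"
        )
    if predicted.size == 0:
        raise DatasetError("empty input")
    return float(np.sqrt(np.mean((predicted - experimental) ** 2)))


def percent_difference(rmsd_method: float, rmsd_reference: float) -> float:
    """Percent penalty of a method vs a reference on the log10 pH scale."""
    if rmsd_method < 0 or rmsd_reference < 0:
        raise ValueError("RMSD values must be non-negative")
    return 100.0 * (10.0 ** (rmsd_method - rmsd_reference) - 1.0)


def count_outliers(
    predicted: Sequence[float],
    experimental: Sequence[float],
    mse_threshold: float,
) -> int:
    """Number of records with squared error strictly above the threshold."""
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise DatasetError(
            f"length mismatch: {predicted.shape} vs {experimental.shape}"
        )
    return int(np.sum((predicted - experimental) ** 2 > mse_threshold))


def avg_pi_consensus(record, pka_panel=None) -> float:
    """Per-record mean pI over a panel of pKa sets.

    ``record`` may be a SequenceRecord, a sequence string or
    IonizableCounts.  The default panel excludes simplified and
    optimized sets.
    """
    if pka_panel is None:
        pka_panel = pka.consensus_panel()
    pka_panel = list(pka_panel)
    if not pka_panel:
        raise EmptyPanelError("consensus panel is empty")
    target = record.sequence if isinstance(record, SequenceRecord) else record
    counts = target if isinstance(target, charge.IonizableCounts) else (
        charge.count_ionizable(target)
    )
    return float(
        np.mean([charge.isoelectric_point(counts, s).pi for s in pka_panel])
    )


def pearson_r2(predicted: Sequence[float], experimental: Sequence[float]) -> float:
    """Squared Pearson correlation — a diagnostic, not a performance score."""
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise DatasetError("length mismatch")
    if predicted.size < 3:
        raise DatasetError("need at least 3 points for a correlation")
    if np.std(predicted) == 0.0 or np.std(experimental) == 0.0:
        raise DatasetError("degenerate variance: one input is constant")
    r = float(np.corrcoef(predicted, experimental)[0, 1])
    return r * r


def _predictions(records, pka_set) -> List[float]:
    cache: Dict[str, float] = {}
    out = []
    for rec in records:
        if rec.sequence not in cache:
            counts = charge.count_ionizable(rec.sequence)
            cache[rec.sequence] = charge.isoelectric_point(counts, pka_set).pi
        out.append(cache[rec.sequence])
    return out


def benchmark_table(
    records: Sequence[SequenceRecord],
    pka_sets=None,
    mse_threshold: float = 3.0,
    consensus: bool = True,
    consensus_panel=None,
) -> List[BenchmarkResult]:
    """One result row per method, sorted ascending by RMSD, plus a final
    per-record consensus (Avg_pI) row.

    The percent column is relative to the best (lowest-RMSD) method.
    Ties keep registry order, which is the iteration order of the default
    set list.
    """
    records = list(records)
    if not records:
        raise DatasetError("empty dataset")
    experimental = []
    for rec in records:
        if rec.consensus_pi is None:
            raise DatasetError(
                f"record {rec.record_id!r} has no consensus_pi; curate first"
            )
        experimental.append(rec.consensus_pi)
    if pka_sets is None:
        pka_sets = [pka.get_pka_set(name) for name in pka.list_pka_sets()]
    rows = []
    for pset in pka_sets:
        predicted = _predictions(records, pset)
        rows.append((pset.name, predicted))
    if consensus:
        panel = list(consensus_panel) if consensus_panel is not None else (
            pka.consensus_panel()
        )
        cache: Dict[str, float] = {}
        predicted = []
        for rec in records:
            if rec.sequence not in cache:
                cache[rec.sequence] = avg_pi_consensus(rec, panel)
            predicted.append(cache[rec.sequence])
        avg_row = (AVG_METHOD_NAME, predicted)
    scored = []
    for name, predicted in rows:
        scored.append((name, predicted, rmsd(predicted, experimental)))
    scored.sort(key=lambda item: item[2])  # stable: ties keep input order
    best_rmsd = scored[0][2]
    if consensus:
        scored.append((avg_row[0], avg_row[1], rmsd(avg_row[1], experimental)))
    results = []
    for name, predicted, method_rmsd in scored:
        try:
            r2 = pearson_r2(predicted, experimental)
        except DatasetError:
            r2 = None
        results.append(
            BenchmarkResult(
                method_name=name,
                rmsd=method_rmsd,
                percent_vs_reference=percent_difference(method_rmsd, best_rmsd),
                n_outliers=count_outliers(predicted, experimental, mse_threshold),
                n_records=len(records),
                r2=r2,
            )
        )
    return results


def format_table(results: Sequence[BenchmarkResult]) -> str:
    """Render results as a TSV with the columns Method, RMSD, %, Outliers."""
    lines = ["Method\tRMSD\t%\tOutliers"]
    for row in results:
        lines.append(
            f"{row.method_name}\t{row.rmsd:.4f}\t"
            f"{row.percent_vs_reference:.1f}\t{row.n_outliers}"
        )
    return "\n".join(lines) + "\n"
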