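"""pI-annotated FASTA I/O and the dataset curation pipeline.

Headers may carry experimental pI measurements in a bracketed list after
the first ``|``.  Two dialects are accepted::

    >P04807-1|['5.17/55102', '5.27/54793']   (legacy pI/mass tokens)
    >P04807-1|[5.17, 5.27]                   (canonical writer output)

Curation follows a merge -> average -> outlier-filter -> redundancy-cluster
-> train/test-split pipeline.  A record is an outlier when the squared
difference between its consensus (experimental) pI and the mean pI
predicted by a panel of pKa sets exceeds a threshold (3 for proteins,
i.e. |delta| > sqrt(3) ~ 1.73 pH; 0.25 for peptides, i.e. |delta| > 0.5).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from . import charge, pka
from .errors import DatasetError, EmptyPanelError, MalformedFastaError

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.99
DEFAULT_TRAIN_FRACTION = 0.75
#: squared-error outlier thresholds (proteins / peptides)
PROTEIN_MSE_THRESHOLD = 3.0
PEPTIDE_MSE_THRESHOLD = 0.25


@dataclass
class SequenceRecord:
    """One sequence with zero or more experimental pI measurements."""

    record_id: str
    sequence: str
    experimental_pis: List[float] = field(default_factory=list)
    source_tag: str = ""
    consensus_pi: Optional[float] = None

    def __post_init__(self):
        self.sequence = charge.clean_sequence(self.sequence)
        for value in self.experimental_pis:
            if not 0.0 < value < 14.0:
                raise DatasetError(
                    f"record {self.record_id!r}: experimental pI {value} "
                    f"outside (0, 14)"
                )


@dataclass
class CurationReport:
    """Bookkeeping of a full curation run; counts always reconcile."""

    n_input: int = 0
    dropped_no_pi: List[SequenceRecord] = field(default_factory=list)
    merged_away: List[SequenceRecord] = field(default_factory=list)
    removed_outliers: List[Tuple[SequenceRecord, float]] = field(default_factory=list)
    removed_redundant: List[Tuple[SequenceRecord, str]] = field(default_factory=list)

    def rows(self):
        """TSV-ready (record_id, action, delta) rows."""
        out = []
        for rec in self.dropped_no_pi:
            out.append((rec.record_id, "dropped_no_pi", ""))
        for rec in self.merged_away:
            out.append((rec.record_id, "merged_duplicate", ""))
        for rec, delta in self.removed_outliers:
            out.append((rec.record_id, "removed_outlier", f"{delta:.4f}"))
        for rec, rep_id in self.removed_redundant:
            out.append((rec.record_id, "removed_redundant", rep_id))
        return out


@dataclass
class CuratedDataset:
    records: List[SequenceRecord]
    report: CurationReport
    split_labels: Optional[Dict[str, str]] = None


# --- FASTA dialect ---------------------------------------------------------

_PI_TOKEN = re.compile(r"^([0-9]+(?:\.[0-9]+)?)(?:\s*/\s*\S+)?$")
_QUOTES = "'\"′’“”"


def _parse_header(description: str) -> Tuple[str, List[float]]:
    description = description.strip()
    if "|" not in description:
        return description.split()[0] if description else "", []
    record_id, _, rest = description.partition("|")
    record_id = record_id.strip()
    bracket = re.search(r"\[(.*?)\]", rest)
    if bracket is None:
        warnings.warn(
            f"header {description!r}: no bracketed pI list after '|'",
            stacklevel=3,
        )
        return record_id, []
    pis: List[float] = []
    for token in bracket.group(1).split(","):
        token = token.strip().strip(_QUOTES).strip()
        if not token:
            continue
        match = _PI_TOKEN.match(token)
        if match is None:
            warnings.warn(
                f"header {description!r}: unparseable pI token {token!r}",
                stacklevel=3,
            )
            continue
        value = float(match.group(1))
        if 0.0 < value < 14.0:
            pis.append(value)
        else:
            warnings.warn(
                f"header {description!r}: pI {value} outside (0, 14); skipped",
                stacklevel=3,
            )
    return record_id, pis


def read_pi_fasta(path) -> List[SequenceRecord]:
    """Read (optionally pI-annotated) FASTA into SequenceRecords."""
    path = Path(path)
    with path.open() as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise MalformedFastaError(
                        f"{path}: sequence data before the first '>' header"
                    )
                break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        record_id, pis = _parse_header(entry.description)
        records.append(
            SequenceRecord(
                record_id=record_id or entry.id,
                sequence=str(entry.seq),
                experimental_pis=pis,
                source_tag=str(path.name),
            )
        )
    return records


def write_pi_fasta(records: Sequence[SequenceRecord], path, width: int = 60) -> None:
    """Write records in the canonical ``>id|[pi1, pi2]`` dialect."""
    lines = []
    for rec in records:
        if rec.experimental_pis:
            annotated = ", ".join(repr(v) for v in rec.experimental_pis)
            lines.append(f">{rec.record_id}|[{annotated}]")
        else:
            lines.append(f">{rec.record_id}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


# --- curation steps --------------------------------------------------------

def merge_and_average(
    records: Sequence[SequenceRecord],
) -> Tuple[List[SequenceRecord], CurationReport]:
    """Merge byte-identical sequences; consensus_pi = mean of pooled pIs.

    Records without any experimental pI are dropped (counted in the
    report).  Idempotent: running it twice changes nothing.
    """
    report = CurationReport(n_input=len(records))
    by_sequence: Dict[str, SequenceRecord] = {}
    pooled: Dict[str, List[float]] = {}
    for rec in records:
        if not rec.experimental_pis:
            report.dropped_no_pi.append(rec)
            continue
        if rec.sequence in by_sequence:
            pooled[rec.sequence].extend(rec.experimental_pis)
            report.merged_away.append(rec)
        else:
            by_sequence[rec.sequence] = rec
            pooled[rec.sequence] = list(rec.experimental_pis)
    merged = []
    for seq, rec in by_sequence.items():
        values = pooled[seq]
        merged.append(
            SequenceRecord(
                record_id=rec.record_id,
                sequence=seq,
                experimental_pis=values,
                source_tag=rec.source_tag,
                consensus_pi=float(np.mean(values)),
            )
        )
    if report.dropped_no_pi:
        logger.info("dropped %d records without pI", len(report.dropped_no_pi))
    return merged, report


def _panel_prediction(sequence: str, panel) -> float:
    counts = charge.count_ionizable(sequence)
    return float(
        np.mean([charge.isoelectric_point(counts, s).pi for s in panel])
    )


def remove_outliers(
    records: Sequence[SequenceRecord],
    panel=None,
    mse_threshold: float = PROTEIN_MSE_THRESHOLD,
) -> Tuple[List[SequenceRecord], List[Tuple[SequenceRecord, float]]]:
    """Drop records whose squared error vs the panel-average pI exceeds
    ``mse_threshold`` (strict inequality).

    ``panel`` defaults to the fourteen complete literature sets
    (simplified and optimized sets excluded).
    """
    if panel is None:
        panel = pka.consensus_panel()
    panel = list(panel)
    if not panel:
        raise EmptyPanelError("outlier panel is empty")
    kept: List[SequenceRecord] = []
    removed: List[Tuple[SequenceRecord, float]] = []
    cache: Dict[str, float] = {}
    for rec in records:
        if rec.consensus_pi is None:
            raise DatasetError(
                f"record {rec.record_id!r} has no consensus_pi; "
                "run merge_and_average first"
            )
        if rec.sequence not in cache:
            cache[rec.sequence] = _panel_prediction(rec.sequence, panel)
        delta = rec.consensus_pi - cache[rec.sequence]
        if delta * delta > mse_threshold:
            removed.append((rec, delta))
        else:
            kept.append(rec)
    return kept, removed


def sequence_identity(a: str, b: str) -> float:
    """Ungapped end-anchored identity: matching prefix positions over the
    longer length.

    At the 0.99 threshold real redundancy is near-identity, where this
    matches alignment-based identity; the longer-length denominator makes
    identity 1.0 occur only for byte-identical pairs.
    """
    if not a or not b:
        return 0.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def _shares_kmer(a: str, b: str, k: int = 8) -> bool:
    if len(a) < k or len(b) < k:
        return True
    kmers = {a[i : i + k] for i in range(0, len(a) - k + 1, k)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def cluster_redundant(
    records: Sequence[SequenceRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> Tuple[List[SequenceRecord], List[Tuple[SequenceRecord, str]]]:
    """Greedy longest-first clustering; returns (representatives, removed).

    A record joins an existing cluster when its identity to the cluster
    representative is at least ``identity_threshold``; the longest member
    (processed first) stays as representative.
    """
    ordered = sorted(records, key=lambda r: -len(r.sequence))
    representatives: List[SequenceRecord] = []
    removed: List[Tuple[SequenceRecord, str]] = []
    for rec in ordered:
        home = None
        for rep in representatives:
            # cheap length bound: identity can never reach the threshold
            if len(rec.sequence) < identity_threshold * len(rep.sequence):
                continue
            if not _shares_kmer(rep.sequence, rec.sequence):
                continue
            if sequence_identity(rec.sequence, rep.sequence) >= identity_threshold:
                home = rep
                break
        if home is None:
            representatives.append(rec)
        else:
            removed.append((rec, home.record_id))
    # restore input order for the kept records
    kept_ids = {id(r) for r in representatives}
    representatives = [r for r in records if id(r) in kept_ids]
    return representatives, removed


def split_train_test(
    records: Sequence[SequenceRecord],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: Optional[int] = None,
) -> Tuple[List[SequenceRecord], List[SequenceRecord]]:
    """Random split; |train| = round(train_fraction * N), reproducible."""
    records = list(records)
    if len(records) < 2:
        raise DatasetError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(np.floor(train_fraction * len(records) + 0.5))
    train_idx = set(order[:n_train].tolist())
    train = [r for i, r in enumerate(records) if i in train_idx]
    test = [r for i, r in enumerate(records) if i not in train_idx]
    return train, test


def curate(
    records: Sequence[SequenceRecord],
    panel=None,
    mse_threshold: float = PROTEIN_MSE_THRESHOLD,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    split_seed: Optional[int] = None,
    train_fraction: Optional[float] = None,
) -> CuratedDataset:
    """Run the full pipeline: merge, average, outlier filter, cluster,
    and (optionally) label a train/test split."""
    merged, report = merge_and_average(records)
    kept, outliers = remove_outliers(merged, panel=panel, mse_threshold=mse_threshold)
    report.removed_outliers = outliers
    representatives, redundant = cluster_redundant(kept, identity_threshold)
    report.removed_redundant = redundant
    split_labels = None
    if train_fraction is not None:
        train, test = split_train_test(representatives, train_fraction, split_seed)
        split_labels = {r.record_id: "train" for r in train}
        split_labels.update({r.record_id: "test" for r in test})
    n_accounted = (
        len(representatives)
        + len(report.dropped_no_pi)
        + len(report.merged_away)
        + len(report.removed_outliers)
        + len(report.removed_redundant)
    )
    assert n_accounted == report.n_input, "curation bookkeeping out of balance"
    return CuratedDataset(records=representatives, report=report, split_labels=split_labels)
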