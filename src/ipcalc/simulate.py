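"""Synthetic pI-labeled sequence sets for testing and optimizer exercises.

Records are labeled with the solver pI under a chosen pKa set, with
optional Gaussian measurement noise, replicate measurements, planted
annotation-error outliers (label shifted by 2-4 pH units, enough to trip
the squared-error-over-3 filter) and planted byte-identical duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import charge
from .datasets import SequenceRecord
from .errors import DatasetError
from .pka import PkaSet, get_pka_set

BACKGROUND_RESIDUES = "AGLSTVPFWMNQI"
CHARGED_RESIDUES = "CDEHKRY"

#: length presets
PEPTIDE_LENGTHS = (7, 30)
PROTEIN_LENGTHS = (100, 1000)

_OUTLIER_SHIFT = (2.0, 4.0)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_records: int = 100
    length_range: Tuple[int, int] = PEPTIDE_LENGTHS
    charged_fraction: float = 0.3
    label_pka_set: Optional[PkaSet] = None  # default: IPC_peptide
    noise_sigma: float = 0.0
    replicate_probability: float = 0.0
    outlier_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    rng_seed: Optional[int] = None

    def __post_init__(self):
        low, high = self.length_range
        if low < 1 or high < low:
            raise DatasetError(f"infeasible length_range {self.length_range}")
        if self.n_records < 1:
            raise DatasetError("n_records must be positive")
        for name in (
            "charged_fraction",
            "replicate_probability",
            "outlier_fraction",
            "duplicate_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise DatasetError(f"{name}={value} outside [0, 1]")
        if self.noise_sigma < 0:
            raise DatasetError("noise_sigma must be non-negative")
        if self.outlier_fraction + self.duplicate_fraction >= 1.0:
            raise DatasetError("outliers plus duplicates must leave clean records")
        if self.label_pka_set is None:
            self.label_pka_set = get_pka_set("IPC_peptide")


def _random_sequence(spec: FixtureSpec, rng: np.random.Generator) -> str:
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    charged = rng.random(length) < spec.charged_fraction
    letters = [
        CHARGED_RESIDUES[rng.integers(len(CHARGED_RESIDUES))]
        if is_charged
        else BACKGROUND_RESIDUES[rng.integers(len(BACKGROUND_RESIDUES))]
        for is_charged in charged
    ]
    return "".join(letters)


def _measurements(
    true_pi: float, spec: FixtureSpec, rng: np.random.Generator
) -> List[float]:
    k = 2 if rng.random() < spec.replicate_probability else 1
    values = []
    for _ in range(k):
        value = true_pi + (rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma else 0.0)
        values.append(float(np.clip(value, 0.01, 13.99)))
    return values


def generate(spec: FixtureSpec) -> List[SequenceRecord]:
    """Generate a pI-annotated record list; reproducible given rng_seed.

    Planted outliers are tagged ``outlier`` in ``source_tag`` and their
    labels shifted toward the middle of the pH scale by 2-4 units (never
    clamped, so the squared-error-over-3 filter always finds them);
    duplicates are tagged ``duplicate:<original id>`` and copy the
    sequence of a clean record.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_duplicates = int(round(spec.duplicate_fraction * spec.n_records))
    n_base = spec.n_records - n_duplicates
    n_outliers = int(round(spec.outlier_fraction * spec.n_records))
    if n_outliers > n_base:
        raise DatasetError("outlier_fraction too high for the record count")

    sequences: List[str] = []
    seen = set()
    while len(sequences) < n_base:
        seq = _random_sequence(spec, rng)
        if seq not in seen:
            seen.add(seq)
            sequences.append(seq)

    outlier_idx = set(
        rng.choice(n_base, size=n_outliers, replace=False).tolist()
    ) if n_outliers else set()

    records: List[SequenceRecord] = []
    for i, seq in enumerate(sequences):
        true_pi = charge.isoelectric_point(seq, spec.label_pka_set).pi
        tag = "clean"
        if i in outlier_idx:
            shift = float(rng.uniform(*_OUTLIER_SHIFT))
            true_pi = true_pi - shift if true_pi > 7.0 else true_pi + shift
            tag = "outlier"
        records.append(
            SequenceRecord(
                record_id=f"SYN{i:05d}",
                sequence=seq,
                experimental_pis=_measurements(true_pi, spec, rng),
                source_tag=tag,
            )
        )

    clean_indices = [i for i in range(n_base) if i not in outlier_idx]
    for j in range(n_duplicates):
        source = records[int(rng.choice(clean_indices))]
        true_pi = charge.isoelectric_point(source.sequence, spec.label_pka_set).pi
        records.append(
            SequenceRecord(
                record_id=f"SYN{n_base + j:05d}",
                sequence=source.sequence,
                experimental_pis=_measurements(true_pi, spec, rng),
                source_tag=f"duplicate:{source.record_id}",
            )
        )
    return records


def generate_peptide_like(
    n_records: int = 100, rng_seed: Optional[int] = None, **overrides
) -> List[SequenceRecord]:
    """Peptide-length preset (7-30 residues, IPC_peptide labels)."""
    overrides.setdefault("length_range", PEPTIDE_LENGTHS)
    spec = FixtureSpec(n_records=n_records, rng_seed=rng_seed, **overrides)
    return generate(spec)


def generate_protein_like(
    n_records: int = 100, rng_seed: Optional[int] = None, **overrides
) -> List[SequenceRecord]:
    """Protein-length preset (100-1000 residues, IPC_protein labels)."""
    overrides.setdefault("length_range", PROTEIN_LENGTHS)
    overrides.setdefault("label_pka_set", get_pka_set("IPC_protein"))
    spec = FixtureSpec(n_records=n_records, rng_seed=rng_seed, **overrides)
    return generate(spec)
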