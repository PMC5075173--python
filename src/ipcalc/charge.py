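"""Net charge of a polypeptide as a function of pH, and the pI solver.

The fractional charge of each ionizable group follows the
Henderson-Hasselbalch logistic form: an acidic group contributes
``-1 / (1 + 10**(pKa - pH))`` and a basic group ``+1 / (1 + 10**(pH - pKa))``.
The total is strictly decreasing in pH, so the isoelectric point (the
unique zero, when one exists) is found by bisection on [0, 14].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Union

from .errors import (
    EmptySequenceError,
    NoIonizableGroupsError,
    NoRootError,
)
from .pka import PkaSet

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: residues whose side chain ionizes, in the order used by IonizableCounts
IONIZABLE_RESIDUES = "CDEHKRY"

# Average (isotope-abundance-weighted) residue masses in Da; a free chain
# additionally carries one water.
_AVG_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.01524

#: default bisection precision in pH units
DEFAULT_PRECISION = 1e-3
#: warm-start pH: mean proteome pI, used for the first bracket split
DEFAULT_START = 6.68


@dataclass(frozen=True)
class IonizableCounts:
    """Counts of the seven ionizable side chains plus free-termini flags."""

    n_C: int = 0
    n_D: int = 0
    n_E: int = 0
    n_H: int = 0
    n_K: int = 0
    n_R: int = 0
    n_Y: int = 0
    has_nterm: bool = True
    has_cterm: bool = True

    def __post_init__(self):
        for letter in IONIZABLE_RESIDUES:
            n = getattr(self, f"n_{letter}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"n_{letter} must be a non-negative integer")

    def total_groups(self) -> int:
        side = sum(getattr(self, f"n_{c}") for c in IONIZABLE_RESIDUES)
        return side + int(self.has_nterm) + int(self.has_cterm)


@dataclass(frozen=True)
class PiPrediction:
    """Result of one pI computation."""

    pi: float
    pka_set_name: str
    iterations: int
    precision: float
    record_id: Optional[str] = None


def clean_sequence(sequence: str) -> str:
    """Upper-case and strip all whitespace; reject empty input."""
    if sequence is None:
        raise EmptySequenceError("sequence is None")
    cleaned = "".join(sequence.split()).upper()
    if not cleaned:
        raise EmptySequenceError("sequence is empty after stripping whitespace")
    return cleaned


def _warn_unknown(sequence: str, context: str) -> str:
    """Return the sequence with non-standard letters removed, warning once.

    B, Z, J, X, U, O and gap/stop symbols carry no modelled charge; U
    (selenocysteine) is deliberately not treated as C.
    """
    unknown = sorted({c for c in sequence if c not in STANDARD_AA})
    if unknown:
        warnings.warn(
            f"{context}: skipping non-standard characters {''.join(unknown)!r}",
            stacklevel=3,
        )
        sequence = "".join(c for c in sequence if c in STANDARD_AA)
    return sequence


def count_ionizable(
    sequence: str, *, has_nterm: bool = True, has_cterm: bool = True
) -> IonizableCounts:
    """Count the ionizable side chains of a sequence.

    Termini default to free (ionizable); pass ``has_nterm=False`` /
    ``has_cterm=False`` for chemically blocked termini.
    """
    cleaned = clean_sequence(sequence)
    cleaned = _warn_unknown(cleaned, "count_ionizable")
    kwargs = {f"n_{c}": cleaned.count(c) for c in IONIZABLE_RESIDUES}
    return IonizableCounts(has_nterm=has_nterm, has_cterm=has_cterm, **kwargs)


def _as_counts(seq_or_counts) -> IonizableCounts:
    if isinstance(seq_or_counts, IonizableCounts):
        return seq_or_counts
    return count_ionizable(seq_or_counts)


def net_charge(counts: Union[IonizableCounts, str], pH: float, pka: PkaSet) -> float:
    """Net charge in elementary-charge units at the given pH.

    Absent groups of simplified pKa sets contribute zero.
    """
    counts = _as_counts(counts)
    negative = (
        (int(counts.has_cterm), pka.pk_cterm),
        (counts.n_C, pka.pk_C),
        (counts.n_D, pka.pk_D),
        (counts.n_E, pka.pk_E),
        (counts.n_Y, pka.pk_Y),
    )
    positive = (
        (int(counts.has_nterm), pka.pk_nterm),
        (counts.n_H, pka.pk_H),
        (counts.n_K, pka.pk_K),
        (counts.n_R, pka.pk_R),
    )
    charge = 0.0
    for n, pk in positive:
        if n and pk is not None:
            charge += n / (1.0 + 10.0 ** (pH - pk))
    for n, pk in negative:
        if n and pk is not None:
            charge -= n / (1.0 + 10.0 ** (pk - pH))
    return charge


def _active_group_signs(counts: IonizableCounts, pka: PkaSet):
    n_pos = sum(
        n
        for n, pk in (
            (int(counts.has_nterm), pka.pk_nterm),
            (counts.n_H, pka.pk_H),
            (counts.n_K, pka.pk_K),
            (counts.n_R, pka.pk_R),
        )
        if pk is not None
    )
    n_neg = sum(
        n
        for n, pk in (
            (int(counts.has_cterm), pka.pk_cterm),
            (counts.n_C, pka.pk_C),
            (counts.n_D, pka.pk_D),
            (counts.n_E, pka.pk_E),
            (counts.n_Y, pka.pk_Y),
        )
        if pk is not None
    )
    return n_pos, n_neg


def isoelectric_point(
    seq_or_counts,
    pka: PkaSet,
    precision: float = DEFAULT_PRECISION,
    start: float = DEFAULT_START,
    record_id: Optional[str] = None,
) -> PiPrediction:
    """Solve net_charge(pH) = 0 by bisection on [0, 14].

    The warm start selects the initial sub-bracket with a single sign
    test; the bracket is then halved until its width is at most
    ``precision`` and the midpoint is returned.  Convergence takes at
    most ``ceil(log2(14 / precision))`` charge evaluations.
    """
    if not precision > 0:
        raise ValueError("precision must be positive")
    counts = _as_counts(seq_or_counts)
    n_pos, n_neg = _active_group_signs(counts, pka)
    if n_pos + n_neg == 0:
        raise NoIonizableGroupsError(
            "no ionizable group is present under this pKa set; "
            "net charge is identically zero"
        )
    if n_pos == 0 or n_neg == 0:
        raise NoRootError(
            "net charge has constant sign on [0, 14] "
            f"({n_pos} positive vs {n_neg} negative groups)"
        )
    # Pathological custom sets can still push the root outside [0, 14].
    if not (net_charge(counts, 0.0, pka) > 0.0 > net_charge(counts, 14.0, pka)):
        raise NoRootError("net charge does not change sign on [0, 14]")
    lo, hi = 0.0, 14.0
    iterations = 0
    if lo < start < hi:
        iterations += 1
        if net_charge(counts, start, pka) > 0.0:
            lo = start
        else:
            hi = start
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        iterations += 1
        if net_charge(counts, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
        if iterations > 200:  # cannot happen with sane precision; safety net
            raise RuntimeError("bisection failed to converge")
    pi = 0.5 * (lo + hi)
    return PiPrediction(
        pi=pi,
        pka_set_name=pka.name,
        iterations=iterations,
        precision=precision,
        record_id=record_id,
    )


def molecular_weight(sequence: str) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    cleaned = clean_sequence(sequence)
    cleaned = _warn_unknown(cleaned, "molecular_weight")
    if not cleaned:
        raise EmptySequenceError("no standard residues left in sequence")
    return sum(_AVG_RESIDUE_MASS[c] for c in cleaned) + _WATER_MASS


def aa_composition(sequence: str) -> Dict[str, float]:
    """Fraction of each standard residue letter; fractions sum to 1."""
    cleaned = clean_sequence(sequence)
    cleaned = _warn_unknown(cleaned, "aa_composition")
    if not cleaned:
        raise EmptySequenceError("no standard residues left in sequence")
    total = len(cleaned)
    return {c: cleaned.count(c) / total for c in sorted(set(cleaned))}
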