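"""Named pKa parameter sets for the nine ionizable groups of a polypeptide.

The model covers the two free termini plus the side chains of Cys, Asp,
Glu, His, Lys, Arg and Tyr.  Acidic groups (C-terminus, C, D, E, Y) are
neutral below their pKa and carry -1 above it; basic groups (N-terminus,
H, K, R) carry +1 below their pKa and are neutral above it.

Seventeen literature sets are built in.  A set may also be loaded from a
flat config file (one ``GROUP<TAB>value`` line per group).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .errors import PkaConfigError, UnknownPkaSetError

#: canonical group order used everywhere (config files, parameter vectors)
GROUP_KEYS = ("NTERM", "CTERM", "C", "D", "E", "H", "K", "R", "Y")

#: groups that ionize negatively (grouped with the C-terminus)
NEGATIVE_GROUPS = ("CTERM", "C", "D", "E", "Y")
#: groups that ionize positively (grouped with the N-terminus)
POSITIVE_GROUPS = ("NTERM", "H", "K", "R")

_FIELD_BY_GROUP = {
    "NTERM": "pk_nterm",
    "CTERM": "pk_cterm",
    "C": "pk_C",
    "D": "pk_D",
    "E": "pk_E",
    "H": "pk_H",
    "K": "pk_K",
    "R": "pk_R",
    "Y": "pk_Y",
}


@dataclass(frozen=True)
class PkaSet:
    """An immutable named vector of nine dissociation constants.

    A value of ``None`` marks a group that the set does not model at all
    (its charge contribution is zero); such incomplete sets must be
    flagged ``simplified=True`` and are excluded from consensus panels.
    """

    name: str
    pk_nterm: Optional[float]
    pk_cterm: Optional[float]
    pk_C: Optional[float]
    pk_D: Optional[float]
    pk_E: Optional[float]
    pk_H: Optional[float]
    pk_K: Optional[float]
    pk_R: Optional[float]
    pk_Y: Optional[float]
    simplified: bool = False
    provenance_note: str = ""

    def __post_init__(self) -> None:
        for group in GROUP_KEYS:
            value = self[group]
            if value is None:
                if not self.simplified:
                    raise PkaConfigError(
                        f"pKa set {self.name!r}: group {group} is absent but the "
                        f"set is not flagged simplified"
                    )
                continue
            if not np.isfinite(value) or not 0.0 < value < 14.0:
                raise PkaConfigError(
                    f"pKa set {self.name!r}: {group}={value!r} outside (0, 14)"
                )

    def __getitem__(self, group: str) -> Optional[float]:
        try:
            return getattr(self, _FIELD_BY_GROUP[group.upper()])
        except KeyError:
            raise KeyError(f"unknown ionizable group {group!r}") from None

    def as_dict(self) -> dict:
        return {group: self[group] for group in GROUP_KEYS}

    def to_vector(self) -> np.ndarray:
        """Return the nine values in :data:`GROUP_KEYS` order.

        Raises :class:`PkaConfigError` for simplified sets with absent
        groups (they have no complete vector representation).
        """
        values = [self[group] for group in GROUP_KEYS]
        if any(v is None for v in values):
            raise PkaConfigError(
                f"pKa set {self.name!r} has absent groups; no full vector exists"
            )
        return np.asarray(values, dtype=float)

    @classmethod
    def from_vector(cls, vector, name: str = "custom", **kwargs) -> "PkaSet":
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (9,):
            raise PkaConfigError(f"expected 9 values, got shape {vector.shape}")
        fields = {
            _FIELD_BY_GROUP[group]: float(v) for group, v in zip(GROUP_KEYS, vector)
        }
        return cls(name=name, **fields, **kwargs)


def _make(name, values, note="", simplified=False):
    fields = {
        _FIELD_BY_GROUP[g]: v for g, v in zip(GROUP_KEYS, values)
    }
    return PkaSet(name=name, **fields, simplified=simplified, provenance_note=note)


# Values are kept exactly as published; imputed entries carry a note.
_BUILTIN_SETS = (
    _make("EMBOSS", (8.6, 3.6, 8.5, 3.9, 4.1, 6.5, 10.8, 12.5, 10.1)),
    _make("DTASelect", (8.0, 3.1, 8.5, 4.4, 4.4, 6.5, 10.0, 12.0, 10.0)),
    _make("Solomons", (9.6, 2.4, 8.3, 3.9, 4.3, 6.0, 10.5, 12.5, 10.1)),
    _make("Sillero", (8.2, 3.2, 9.0, 4.0, 4.5, 6.4, 10.4, 12.0, 10.0)),
    _make("Rodwell", (8.0, 3.1, 8.33, 3.68, 4.25, 6.0, 11.5, 11.5, 10.07)),
    _make(
        "Patrickios",
        (11.2, 4.2, None, 4.2, 4.2, None, 11.2, 11.2, None),
        note="six-parameter model: C, H and Y are not modelled (zero contribution)",
        simplified=True,
    ),
    _make(
        "Wikipedia",
        (8.2, 3.65, 8.18, 3.9, 4.07, 6.04, 10.54, 12.48, 10.46),
        note="community-compiled values without a primary literature reference",
    ),
    _make("Lehninger", (9.69, 2.34, 8.33, 3.86, 4.25, 6.0, 10.5, 12.4, 10.0)),
    _make(
        "Grimsley",
        (7.7, 3.3, 6.8, 3.5, 4.2, 6.6, 10.5, 12.04, 10.3),
        note="Arg was not measured in the source study; 12.04 is the average "
        "over the other sets",
    ),
    _make("Toseland", (8.71, 3.19, 6.87, 3.6, 4.29, 6.33, 10.45, 12.0, 9.61)),
    _make("Thurlkill", (8.0, 3.67, 8.55, 3.67, 4.25, 6.54, 10.4, 12.0, 9.84)),
    _make("Nozaki", (7.5, 3.8, 9.5, 4.0, 4.4, 6.3, 10.4, 12.0, 9.6)),
    _make(
        "Dawson",
        (8.2, 3.2, 8.3, 3.9, 4.3, 6.0, 10.5, 12.0, 10.1),
        note="terminal groups were not included in the source study; 8.2/3.2 "
        "taken from the Sillero set",
    ),
    _make("Bjellqvist", (7.5, 3.55, 9.0, 4.05, 4.45, 5.98, 10.0, 12.0, 10.0)),
    _make("ProMoST", (7.26, 3.57, 8.28, 4.07, 4.45, 6.08, 9.8, 12.5, 9.84)),
    _make("IPC_protein", (9.094, 2.869, 7.555, 3.872, 4.412, 5.637, 9.052, 11.84, 10.85)),
    _make("IPC_peptide", (9.564, 2.383, 8.297, 3.887, 4.317, 6.018, 10.517, 12.503, 10.071)),
)

_REGISTRY = {s.name: s for s in _BUILTIN_SETS}
_LOWER_INDEX = {s.name.lower(): s.name for s in _BUILTIN_SETS}

#: optimized sets; excluded (with simplified sets) from consensus panels
OPTIMIZED_SET_NAMES = ("IPC_protein", "IPC_peptide")


def list_pka_sets() -> list:
    """Canonical names of the built-in sets, in registry order."""
    return [s.name for s in _BUILTIN_SETS]


def get_pka_set(name: str) -> PkaSet:
    """Look up a built-in pKa set by name (case-insensitive)."""
    canonical = _LOWER_INDEX.get(str(name).lower())
    if canonical is None:
        available = ", ".join(list_pka_sets())
        raise UnknownPkaSetError(
            f"unknown pKa set {name!r}; available sets: {available}"
        )
    return _REGISTRY[canonical]


def iter_pka_sets() -> Iterator[PkaSet]:
    return iter(_BUILTIN_SETS)


def consensus_panel() -> list:
    """Built-in sets used for consensus (Avg_pI) predictions.

    Simplified sets and the computationally optimized IPC sets are
    excluded, leaving the fourteen complete literature sets.
    """
    return [
        s
        for s in _BUILTIN_SETS
        if not s.simplified and s.name not in OPTIMIZED_SET_NAMES
    ]


def registry_order(name: str) -> int:
    """Position of a built-in set in the registry; large for custom sets."""
    try:
        return list_pka_sets().index(get_pka_set(name).name)
    except UnknownPkaSetError:
        return len(_BUILTIN_SETS)


def load_pka_set(path, name: Optional[str] = None) -> PkaSet:
    """Read a pKa set from a flat ``GROUP<TAB>value`` config file.

    All nine groups must be present.  The literal value ``NA`` marks an
    absent group (the resulting set is flagged simplified).  The loaded
    set is not added to the built-in registry.
    """
    path = Path(path)
    values: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PkaConfigError(f"{path}:{lineno}: expected 'GROUP<TAB>value'")
        group, text = parts[0].upper(), parts[1]
        if group not in _FIELD_BY_GROUP:
            raise PkaConfigError(f"{path}:{lineno}: unknown group {group!r}")
        if text.upper() in ("NA", "NONE", "-"):
            values[group] = None
            continue
        try:
            values[group] = float(text)
        except ValueError:
            raise PkaConfigError(
                f"{path}:{lineno}: cannot parse value {text!r}"
            ) from None
    missing = [g for g in GROUP_KEYS if g not in values]
    if missing:
        raise PkaConfigError(
            f"{path}: missing groups: {', '.join(missing)}"
        )
    simplified = any(values[g] is None for g in GROUP_KEYS)
    fields = {_FIELD_BY_GROUP[g]: values[g] for g in GROUP_KEYS}
    return PkaSet(name=name or path.stem, simplified=simplified, **fields)


def write_pka_set(pka: PkaSet, path) -> None:
    """Write a pKa set in the flat config format (round-trips losslessly)."""
    lines = []
    for group in GROUP_KEYS:
        value = pka[group]
        lines.append(f"{group}\t{'NA' if value is None else repr(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def replace(pka: PkaSet, **changes) -> PkaSet:
    """Return a copy of ``pka`` with the given fields changed."""
    return dataclasses.replace(pka, **changes)
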