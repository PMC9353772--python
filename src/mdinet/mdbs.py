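"""Mass-difference-based building blocks (MDBs).

An MDB is a named elemental-composition change (e.g. +CH2 for methylation)
with its exact monoisotopic mass difference. MDBs define which pairs of
neutral masses get connected in a mass-difference network: two features are
linked when their mass difference matches an MDB's delta mass within a ppm
tolerance.

The registry ships the default table of small, ubiquitous biochemical
transformations (all below 80 Da, covering C, H, N, O, P and S), plus two
optional glycation-related blocks (carboxymethylation, carboxyethylation)
used for systems where methylglyoxal chemistry matters.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ElementDelta",
    "MDB",
    "monoisotopic_mass",
    "formula_mass",
    "mz_minus_h",
    "default_mdb_table",
    "load_mdb_table",
    "save_mdb_table",
]

ELEMENTS = ("C", "H", "N", "O", "P", "S")

# IUPAC/CODATA monoisotopic atomic masses (Da), most abundant isotope.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.000548579909  # Da

_MAX_COUNT = 100  # sanity bound to catch parse errors


@dataclass(frozen=True)
class ElementDelta:
    """Signed per-element count change over CHNOPS.

    Positive counts are atoms gained, negative counts atoms lost. At least
    one count must be nonzero and |count| <= 100.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = (), **kw: int):
        merged: dict[str, int] = dict(counts)
        for el, c in kw.items():
            merged[el] = merged.get(el, 0) + c
        for el, c in merged.items():
            if el not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if abs(c) > _MAX_COUNT:
                raise ValueError(f"implausible count for {el}: {c}")
        merged = {el: c for el, c in merged.items() if c != 0}
        if not merged:
            raise ValueError("element delta must have at least one nonzero count")
        object.__setattr__(
            self, "counts", tuple((el, merged[el]) for el in ELEMENTS if el in merged)
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __add__(self, other: "ElementDelta") -> "ElementDelta":
        d = dict(self.counts)
        for el, c in other.counts:
            d[el] = d.get(el, 0) + c
        return ElementDelta(d)

    def __neg__(self) -> "ElementDelta":
        return ElementDelta({el: -c for el, c in self.counts})

    def __str__(self) -> str:
        return "".join(f"{el}{c:+d}" for el, c in self.counts)


def monoisotopic_mass(delta: ElementDelta | Mapping[str, int]) -> float:
    """Signed monoisotopic mass (Da) of an elemental composition change.

    Negative for net-loss deltas; the MDB registry stores the absolute value
    because the network is undirected (a gain one way is a loss the other).
    """
    if not isinstance(delta, ElementDelta):
        delta = ElementDelta(delta)
    return sum(MONOISOTOPIC_MASS[el] * c for el, c in delta.counts)


def formula_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of a CHNOPS formula given as counts."""
    m = 0.0
    for el, c in formula.items():
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {el!r}")
        if c < 0:
            raise ValueError(f"negative count for {el} in formula")
        m += MONOISOTOPIC_MASS[el] * c
    return m


def mz_minus_h(formula: Mapping[str, int]) -> float:
    """Theoretical [M-H]- m/z of a neutral formula.

    Removes one hydrogen atom and adds one electron; e.g. leucine enkephalin
    (C28H37N5O7) gives the common ESI- lock-mass reference 554.262022.
    """
    return formula_mass(formula) - MONOISOTOPIC_MASS["H"] + ELECTRON_MASS


@dataclass(frozen=True)
class MDB:
    """A named chemical transformation with its exact mass change.

    ``delta_mass`` is the absolute monoisotopic mass of ``delta`` and is
    always positive; direction is handled by the undirected network.
    """

    label: str
    delta: ElementDelta
    delta_mass: float = field(init=False)

    def __post_init__(self) -> None:
        m = abs(monoisotopic_mass(self.delta))
        if m <= 0:
            raise ValueError(f"MDB {self.label!r} has zero mass change")
        object.__setattr__(self, "delta_mass", m)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MDB({self.label!r}, {self.delta_mass:.6f} Da)"


def _d(**kw: int) -> ElementDelta:
    return ElementDelta(kw)


# Default transformation list: small ubiquitous reactions (< 80 Da), chosen
# so every common metabolite element (CHNOPS) appears in at least one block.
# Note on "CHOH": the conventional label for this hydroxymethylation-related
# block in published transformation lists, with mass 29.002740 Da, i.e. the
# composition CHO; see docs/methods.md.
_DEFAULT_ROWS: tuple[tuple[str, ElementDelta, str], ...] = (
    ("O(-NH)", _d(O=1, N=-1, H=-1), "Deamination"),
    ("NH3(-O)", _d(N=1, H=3, O=-1), "Transamination"),
    ("H2", _d(H=2), "Hydrogenation/Dehydrogenation"),
    ("CH2", _d(C=1, H=2), "Methylation"),
    ("O", _d(O=1), "Oxygenation/Hydroxylation"),
    ("H2O", _d(H=2, O=1), "Condensation/Dehydration/Cyclization"),
    ("NCH", _d(N=1, C=1, H=1), "Transfer of a formidoyl group"),
    ("CO", _d(C=1, O=1), "Formylation"),
    ("CHOH", _d(C=1, H=1, O=1), "Hydroxymethylation"),
    ("S", _d(S=1), "Transfer of a -SH group"),
    ("C2H2O", _d(C=2, H=2, O=1), "Acetylation"),
    ("CONH", _d(C=1, O=1, N=1, H=1), "Transfer of a carbamoyl group"),
    ("CO2", _d(C=1, O=2), "Carboxylation/Decarboxylation"),
    ("SO3", _d(S=1, O=3), "Sulfation"),
    ("PO3H", _d(P=1, O=3, H=1), "Phosphorylation"),
)

_GLYCATION_ROWS: tuple[tuple[str, ElementDelta, str], ...] = (
    ("CHCOOH", _d(C=2, H=2, O=2), "Carboxymethylation"),
    ("CCH3COOH", _d(C=3, H=4, O=2), "Carboxyethylation"),
)


def default_mdb_table(include_glycation: bool = False) -> list[MDB]:
    """The default MDB list: 15 blocks, or 17 with the glycation extension."""
    rows = _DEFAULT_ROWS + (_GLYCATION_ROWS if include_glycation else ())
    return [MDB(label, delta) for label, delta, _ in rows]


def mdb_reaction_types() -> dict[str, str]:
    """Label -> example reaction type, for display only."""
    return {label: rt for label, _, rt in _DEFAULT_ROWS + _GLYCATION_ROWS}


def load_mdb_table(path: str | Path) -> list[MDB]:
    """Read an MDB table from CSV with columns label,C,H,N,O,P,S[,mass].

    ``delta_mass`` is always recomputed from the composition; if a ``mass``
    column is present it is cross-checked and a mismatch above 1e-5 Da is an
    error (guards against stale hand-edited tables).
    """
    path = Path(path)
    mdbs: list[MDB] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty MDB table", stacklevel=2)
            return []
        for i, row in enumerate(reader, start=2):
            label = (row.get("label") or "").strip()
            if not label:
                raise ValueError(f"{path}:{i}: missing MDB label")
            if label in seen:
                raise ValueError(f"{path}:{i}: duplicate MDB label {label!r}")
            seen.add(label)
            counts = {el: int(row[el] or 0) for el in ELEMENTS if el in row and row[el]}
            mdb = MDB(label, ElementDelta(counts))
            stated = (row.get("mass") or "").strip()
            if stated:
                if abs(float(stated) - mdb.delta_mass) > 1e-5:
                    raise ValueError(
                        f"{path}:{i}: stated mass {stated} differs from computed "
                        f"{mdb.delta_mass:.6f} by more than 1e-5 Da"
                    )
            mdbs.append(mdb)
    if not mdbs:
        warnings.warn(f"{path}: empty MDB table", stacklevel=2)
    return mdbs


def save_mdb_table(mdbs: Iterable[MDB], path: str | Path) -> None:
    """Write an MDB table as CSV (label, CHNOPS counts, mass at 6 decimals)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", *ELEMENTS, "mass"])
        for mdb in mdbs:
            d = mdb.delta.as_dict()
            writer.writerow(
                [mdb.label, *[d.get(el, 0) for el in ELEMENTS], f"{mdb.delta_mass:.6f}"]
            )
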