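"""Bond-energy lookup tables.

A bond-energy table maps a bond — two element symbols plus an integer bond
order (1 = single, 2 = double, 3 = triple) — to an average bond enthalpy in
kJ/mol. The package ships a default table of standard textbook average bond
enthalpies at 298 K; users may supply their own table file in the same
delimited-text format (see :func:`load_bond_table`).

Lookup is symmetric in the two elements: ``lookup(C, H, 1)`` and
``lookup(H, C, 1)`` address the same entry. Keys are canonicalized on
construction so a table can never hold conflicting mirror-image rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from rdkit import Chem

from .errors import ArgumentError, TableFormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_ORDERS = (1, 2, 3)

_HEADER = ("element_a", "element_b", "order", "energy_kj_mol")

_PERIODIC_TABLE = Chem.GetPeriodicTable()


def normalize_element(symbol: str) -> str:
    """Case-normalize an element symbol ("CL" -> "Cl") and validate it.

    Raises :class:`ArgumentError` if the normalized symbol is not a
    periodic-table element.
    """
    sym = str(symbol).strip()
    if not sym or not sym.isalpha() or len(sym) > 2:
        raise ArgumentError(f"invalid element symbol: {symbol!r}")
    sym = sym[0].upper() + sym[1:].lower()
    try:
        _PERIODIC_TABLE.GetAtomicNumber(sym)  # raises for unknown symbols
    except Exception as exc:
        raise ArgumentError(f"unknown element symbol: {symbol!r}") from exc
    return sym


def _checked_order(order: int) -> int:
    try:
        if isinstance(order, float) and not order.is_integer():
            raise ValueError(order)
        o = int(order)
    except (TypeError, ValueError) as exc:
        raise ArgumentError(f"bond order must be an integer, got {order!r}") from exc
    if o not in VALID_ORDERS:
        raise ArgumentError(f"bond order must be one of {VALID_ORDERS}, got {order!r}")
    return o


@dataclass(frozen=True, order=True)
class BondKey:
    """A canonical (element, element, order) bond identity.

    The two element symbols are stored in sorted order, so
    ``BondKey("C", "H", 1) == BondKey("H", "C", 1)``.
    """

    element_a: str
    element_b: str
    order: int

    def __init__(self, element_a: str, element_b: str, order: int):
        a = normalize_element(element_a)
        b = normalize_element(element_b)
        if a > b:
            a, b = b, a
        object.__setattr__(self, "element_a", a)
        object.__setattr__(self, "element_b", b)
        object.__setattr__(self, "order", _checked_order(order))

    def __str__(self) -> str:
        glyph = {1: "-", 2: "=", 3: "#"}[self.order]
        return f"{self.element_a}{glyph}{self.element_b}"


class BondEnergyTable(Mapping[BondKey, float]):
    """Validated mapping from :class:`BondKey` to a positive energy in kJ/mol."""

    def __init__(self, entries: Mapping[BondKey, float], source_name: str = "user table"):
        canonical: dict[BondKey, float] = {}
        for key, energy in entries.items():
            if not isinstance(key, BondKey):
                key = BondKey(*key)
            e = float(energy)
            if not e > 0:
                raise ValidationError(f"bond energy must be positive: {key} -> {energy!r}")
            canonical[key] = e
        self._entries = canonical
        self.source_name = str(source_name)

    def __getitem__(self, key: BondKey) -> float:
        return self._entries[key]

    def __iter__(self) -> Iterator[BondKey]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, element_a: str, element_b: str, order: int) -> float | None:
        """Energy in kJ/mol for the bond, or ``None`` when the key is absent.

        The not-found marker is ``None``, never 0: a zero would be an
        (invalid) energy, not an absence.
        """
        return self._entries.get(BondKey(element_a, element_b, order))

    def __repr__(self) -> str:
        return f"BondEnergyTable({len(self)} entries, source={self.source_name!r})"


def lookup_energy(table: BondEnergyTable, element_a: str, element_b: str, order: int) -> float | None:
    """Functional alias for :meth:`BondEnergyTable.lookup`."""
    return table.lookup(element_a, element_b, order)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_bond_table(path: str | Path, strict: bool = False) -> BondEnergyTable:
    """Load a bond-energy table from delimited text.

    Format: a header line ``element_a,element_b,order,energy_kj_mol``
    (comma- or tab-delimited, auto-detected from the header), one bond per
    row, ``#``-prefixed comment lines ignored. Mirror-image rows (C,H and
    H,C) collapse to one canonical entry; if they disagree on the energy,
    ``strict=True`` raises and ``strict=False`` keeps the last value with a
    logged warning.
    """
    path = Path(path)
    try:
        raw_lines = path.read_text().splitlines()
    except OSError as exc:
        raise TableFormatError(f"cannot read bond table {path}: {exc}") from exc

    lines = [
        (lineno, line)
        for lineno, line in enumerate(raw_lines, start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise TableFormatError(f"{path}: no header line found")

    header_lineno, header_line = lines[0]
    delim = _detect_delimiter(header_line)
    header = tuple(col.strip().lower() for col in header_line.split(delim))
    if header != _HEADER:
        raise TableFormatError(
            f"{path}:{header_lineno}: expected header {','.join(_HEADER)!r}, got {header_line!r}"
        )

    entries: dict[BondKey, float] = {}
    for lineno, line in lines[1:]:
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != 4:
            raise TableFormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}: {line!r}")
        el_a, el_b, order_s, energy_s = fields
        try:
            order = int(order_s)
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: bond order is not an integer: {order_s!r}") from exc
        try:
            energy = float(energy_s)
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: energy is not a number: {energy_s!r}") from exc
        try:
            key = BondKey(el_a, el_b, order)
        except ArgumentError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if not energy > 0:
            raise ValidationError(f"{path}:{lineno}: bond energy must be positive, got {energy}")
        if key in entries and entries[key] != energy:
            msg = f"{path}:{lineno}: conflicting duplicate for {key}: {entries[key]} vs {energy}"
            if strict:
                raise ValidationError(msg)
            logger.warning("%s (keeping last value)", msg)
        entries[key] = energy

    if not entries:
        raise TableFormatError(f"{path}: table has a header but no data rows")
    return BondEnergyTable(entries, source_name=path.name)


def write_table(table: BondEnergyTable, path: str | Path) -> None:
    """Write a table in the same delimited format :func:`load_bond_table` reads."""
    path = Path(path)
    lines = [",".join(_HEADER)]
    for key in sorted(table):
        energy = table[key]
        energy_s = f"{energy:g}"
        lines.append(f"{key.element_a},{key.element_b},{key.order},{energy_s}")
    path.write_text("\n".join(lines) + "\n")


def default_table() -> BondEnergyTable:
    """The shipped default table of standard average bond enthalpies (298 K)."""
    ref = resources.files("nbescore.data") / "bond_energies_default.csv"
    with resources.as_file(ref) as path:
        table = load_bond_table(path, strict=True)
    table.source_name = "builtin:standard-average-bond-enthalpies-298K"
    return table
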