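"""Molecule parsing and preparation on top of RDKit.

Molecules arrive as SDF (V2000) records or SMILES lines and are prepared for
bond-energy scoring: all hydrogens are made explicit, and aromatic systems
are kekulized to alternating single/double bonds so that every bond carries
an integer order in {1, 2, 3}. Explicit hydrogens matter: hydrogen bonds
(C-H, O-H, N-H) dominate the bond-energy sum of drug-like molecules, and
without them the normalized score would fall far below its intended scale.

The per-molecule product is a :class:`MoleculeRecord`: an identifier, the
bond multiset, and the molecular weight (sum of standard average atomic
weights, isotope-aware). The bond multiset is invariant under atom
renumbering and under equivalent SMILES spellings of the same structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .bond_table import VALID_ORDERS, normalize_element
from .errors import EmptyInputError, InputError, MoleculePreparationError

logger = logging.getLogger(__name__)

# RDKit logs every sanitization failure to stderr; we report skips ourselves.
RDLogger.DisableLog("rdApp.error")

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.QUADRUPLE: 4,
    Chem.BondType.QUINTUPLE: 5,
    Chem.BondType.HEXTUPLE: 6,
}


@dataclass(frozen=True, order=True)
class Bond:
    """One chemical bond: two element symbols plus an integer order.

    Elements are stored in sorted order so the bond is orientation-free.
    Orders outside {1, 2, 3} can only be produced by preparing a molecule
    with ``on_unsupported="keep"``; such bonds never match an energy table.
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
        object.__setattr__(self, "order", int(order))

    def __str__(self) -> str:
        glyph = {1: "-", 2: "=", 3: "#"}.get(self.order, f"({self.order})")
        return f"{self.element_a}{glyph}{self.element_b}"


@dataclass(frozen=True)
class MoleculeRecord:
    """A prepared molecule: identifier, bond multiset, molecular weight."""

    id: str
    bonds: tuple[Bond, ...]
    mw: float
    n_atoms: int
    source_format: Literal["sdf", "smiles"]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass
class ParseResult:
    """Records parsed from one input plus the count of skipped entries."""

    records: list[MoleculeRecord] = field(default_factory=list)
    n_skipped: int = 0
    skipped: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def prepare_molecule(
    mol: Chem.Mol,
    largest_fragment: bool = False,
    on_unsupported: Literal["error", "keep"] = "error",
) -> Chem.Mol:
    """Prepare a raw RDKit molecule for bond enumeration.

    Steps: optionally keep only the largest fragment (counterion stripping),
    sanitize, add explicit hydrogens, kekulize aromatic systems. After
    preparation every bond order is in {1, 2, 3}; a bond that cannot be
    expressed that way (quadruple, dative, ...) raises
    :class:`MoleculePreparationError` under ``on_unsupported="error"`` or is
    passed through with its raw order under ``"keep"`` (where it will count
    as unmatched during scoring).
    """
    if mol is None:
        raise MoleculePreparationError("molecule is None (parse failure)")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
    try:
        mol = Chem.Mol(mol)
        if largest_fragment:
            frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
            mol = max(frags, key=lambda m: m.GetNumAtoms())
        Chem.SanitizeMol(mol)
        mol = Chem.AddHs(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except MoleculePreparationError:
        raise
    except Exception as exc:
        raise MoleculePreparationError(f"cannot prepare molecule: {exc}", molecule_id=name) from exc

    if on_unsupported == "error":
        for bond in mol.GetBonds():
            if _BOND_ORDER.get(bond.GetBondType()) not in VALID_ORDERS:
                raise MoleculePreparationError(
                    f"unsupported bond type {bond.GetBondType()} between atoms "
                    f"{bond.GetBeginAtom().GetSymbol()} and {bond.GetEndAtom().GetSymbol()}",
                    molecule_id=name,
                )
    if name is not None:
        mol.SetProp("_Name", name)
    return mol


def enumerate_bonds(mol: Chem.Mol) -> list[Bond]:
    """One :class:`Bond` per connection-table edge of a prepared molecule."""
    bonds = []
    for bond in mol.GetBonds():
        order = _BOND_ORDER.get(bond.GetBondType())
        if order is None:
            raise MoleculePreparationError(
                f"bond type {bond.GetBondType()} has no integer order; "
                "prepare the molecule first"
            )
        bonds.append(Bond(bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol(), order))
    return bonds


def molecular_weight(mol: Chem.Mol) -> float:
    """Molecular weight in g/mol: standard average atomic weights summed over
    all atoms including explicit hydrogens; isotope-labeled atoms contribute
    their isotope mass."""
    return Descriptors.MolWt(mol)


def record_from_mol(
    mol: Chem.Mol,
    id: str,
    source_format: Literal["sdf", "smiles"],
    largest_fragment: bool = False,
    on_unsupported: Literal["error", "keep"] = "error",
) -> MoleculeRecord:
    """Prepare one raw molecule and package it as a :class:`MoleculeRecord`."""
    prepared = prepare_molecule(mol, largest_fragment=largest_fragment, on_unsupported=on_unsupported)
    return MoleculeRecord(
        id=str(id),
        bonds=tuple(enumerate_bonds(prepared)),
        mw=molecular_weight(prepared),
        n_atoms=prepared.GetNumAtoms(),
        source_format=source_format,
    )


def molecule_from_smiles(
    smiles: str,
    id: str | None = None,
    largest_fragment: bool = False,
    on_unsupported: Literal["error", "keep"] = "error",
) -> MoleculeRecord:
    """Parse a single SMILES string into a prepared :class:`MoleculeRecord`."""
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise MoleculePreparationError(f"invalid SMILES: {smiles!r}", molecule_id=id)
    return record_from_mol(
        mol, id if id is not None else smiles, "smiles",
        largest_fragment=largest_fragment, on_unsupported=on_unsupported,
    )


def parse_sdf(
    path: str | Path,
    largest_fragment: bool = False,
    on_unsupported: Literal["error", "keep"] = "error",
) -> ParseResult:
    """Parse a (possibly multi-record) SDF V2000 file.

    Records that fail sanitization or preparation are skipped with a logged
    warning and counted in ``n_skipped``. Zero parseable records raise
    :class:`EmptyInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"SDF file not found: {path}")
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path}: empty SDF file")
    result = ParseResult()
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    except OSError as exc:
        raise InputError(f"{path}: cannot open as SDF: {exc}") from exc
    for index, mol in enumerate(supplier):
        if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            mol_id = mol.GetProp("_Name").strip()
        else:
            mol_id = f"record_{index + 1}"
        if mol is None:
            logger.warning("%s: record %d unparseable, skipped", path, index + 1)
            result.n_skipped += 1
            result.skipped.append(mol_id)
            continue
        try:
            record = record_from_mol(
                mol, mol_id, "sdf",
                largest_fragment=largest_fragment, on_unsupported=on_unsupported,
            )
        except MoleculePreparationError as exc:
            logger.warning("%s: record %s skipped: %s", path, mol_id, exc)
            result.n_skipped += 1
            result.skipped.append(mol_id)
            continue
        result.records.append(record)
    if not result.records:
        raise EmptyInputError(f"{path}: no parseable molecule records (skipped {result.n_skipped})")
    return result


def parse_smiles(
    source: str | Path,
    largest_fragment: bool = False,
    on_unsupported: Literal["error", "keep"] = "error",
) -> ParseResult:
    """Parse a SMILES line file: ``<SMILES>[whitespace]<id>`` per line.

    ``#`` comment lines and blank lines are ignored; a missing identifier
    defaults to the line number. Invalid SMILES are skipped and counted.
    """
    path = Path(source)
    if not path.exists():
        raise InputError(f"SMILES file not found: {path}")
    return parse_smiles_lines(
        path.read_text().splitlines(),
        largest_fragment=largest_fragment,
        on_unsupported=on_unsupported,
        origin=str(path),
    )


def parse_smiles_lines(
    lines: Iterable[str],
    largest_fragment: bool = False,
    on_unsupported: Literal["error", "keep"] = "error",
    origin: str = "<lines>",
) -> ParseResult:
    """Parse SMILES from an in-memory sequence of lines (same contract as
    :func:`parse_smiles`)."""
    result = ParseResult()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"line_{lineno}"
        try:
            record = molecule_from_smiles(
                smiles, mol_id,
                largest_fragment=largest_fragment, on_unsupported=on_unsupported,
            )
        except MoleculePreparationError as exc:
            logger.warning("%s:%d: skipped %r: %s", origin, lineno, smiles, exc)
            result.n_skipped += 1
            result.skipped.append(mol_id)
            continue
        result.records.append(record)
    if not result.records:
        raise EmptyInputError(f"{origin}: no parseable SMILES (skipped {result.n_skipped})")
    return result
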