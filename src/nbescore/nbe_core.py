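"""The normalized bond energy (NBE) score.

NBE of a molecule is the sum of the per-bond energies (kJ/mol), taken from a
bond-energy table, divided by the molecular weight (g/mol):

    NBE = (sum_i BondEnergy(i)) / MW

Summing over bonds makes the raw energy grow with molecular size; dividing
by MW removes that size dependence, leaving an intensive score (kJ/g) that
can be compared across molecules. Bonds absent from the table are handled by
an explicit policy: ``skip`` (contribute zero, counted per molecule in
``n_unmatched``) or ``error`` (abort that molecule with a diagnostic naming
the missing bond key).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .bond_table import BondEnergyTable, VALID_ORDERS
from .errors import InputError, UnmatchedBondError
from .molecule_io import MoleculeRecord

logger = logging.getLogger(__name__)

UnmatchedPolicy = Literal["skip", "error"]

RESULT_COLUMNS = ("id", "nbe", "total_bond_energy_kj_mol", "mw", "n_bonds", "n_unmatched")


@dataclass(frozen=True)
class NBEResult:
    """Per-molecule scoring output.

    ``nbe`` is ``total_bond_energy / mw`` exactly (kJ/g); ``n_unmatched``
    counts bonds that were absent from the table and contributed zero.
    """

    id: str
    nbe: float
    total_bond_energy: float
    mw: float
    n_bonds: int
    n_unmatched: int
    table_source: str


@dataclass
class RunSummary:
    """Batch-level accounting: what was scored, skipped, or partially matched."""

    n_scored: int = 0
    n_skipped: int = 0
    n_with_unmatched: int = 0
    skipped_ids: list[str] = field(default_factory=list)


def compute_nbe(
    molecule: MoleculeRecord,
    table: BondEnergyTable,
    unmatched_policy: UnmatchedPolicy = "skip",
) -> NBEResult:
    """Score one prepared molecule against a bond-energy table."""
    if unmatched_policy not in ("skip", "error"):
        raise ValueError(f"unmatched_policy must be 'skip' or 'error', got {unmatched_policy!r}")
    if not molecule.mw > 0:
        raise AssertionError(f"{molecule.id}: non-positive molecular weight {molecule.mw}")

    total = 0.0
    n_unmatched = 0
    for bond in molecule.bonds:
        energy = (
            table.lookup(bond.element_a, bond.element_b, bond.order)
            if bond.order in VALID_ORDERS
            else None
        )
        if energy is None:
            if unmatched_policy == "error":
                raise UnmatchedBondError(
                    f"{molecule.id}: bond {bond} not in table {table.source_name!r}"
                )
            n_unmatched += 1
        else:
            total += energy
    return NBEResult(
        id=molecule.id,
        nbe=total / molecule.mw,
        total_bond_energy=total,
        mw=molecule.mw,
        n_bonds=molecule.n_bonds,
        n_unmatched=n_unmatched,
        table_source=table.source_name,
    )


def batch_compute(
    molecules: Iterable[MoleculeRecord],
    table: BondEnergyTable,
    unmatched_policy: UnmatchedPolicy = "skip",
) -> tuple[list[NBEResult], RunSummary]:
    """Score a sequence of molecules, preserving input order.

    Under ``skip`` nothing is fatal; under ``error`` the first unmatched
    bond aborts the batch (the exception carries the offending molecule and
    bond key).
    """
    results: list[NBEResult] = []
    summary = RunSummary()
    for molecule in molecules:
        result = compute_nbe(molecule, table, unmatched_policy)
        results.append(result)
        summary.n_scored += 1
        if result.n_unmatched > 0:
            summary.n_with_unmatched += 1
            logger.warning(
                "%s: %d of %d bonds unmatched in table %r",
                result.id, result.n_unmatched, result.n_bonds, table.source_name,
            )
    return results, summary


def write_results(
    results: Sequence[NBEResult],
    path,
    precision: int | None = None,
    delimiter: str = "\t",
    header_comments: Sequence[str] = (),
) -> None:
    """Write results as delimited text with columns
    ``id, nbe, total_bond_energy_kj_mol, mw, n_bonds, n_unmatched``.

    ``path`` may be a filesystem path or an open text stream.
    ``precision=None`` writes full float repr (round-trippable);
    an integer fixes the number of decimal places for nbe/energy/mw.
    """

    def fmt(x: float) -> str:
        return repr(float(x)) if precision is None else f"{x:.{precision}f}"

    def emit(fh) -> None:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow([r.id, fmt(r.nbe), fmt(r.total_bond_energy), fmt(r.mw), r.n_bonds, r.n_unmatched])

    if hasattr(path, "write"):
        emit(path)
    else:
        with Path(path).open("w", newline="") as fh:
            emit(fh)


def read_results(path: str | Path, delimiter: str = "\t") -> list[NBEResult]:
    """Read a results table written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"results file not found: {path}")
    table_source = "unknown"
    rows: list[NBEResult] = []
    with path.open() as fh:
        lines = [ln for ln in fh if ln.strip()]
    data_lines = []
    for ln in lines:
        if ln.startswith("#"):
            if "bond_table:" in ln:
                table_source = ln.split("bond_table:", 1)[1].strip()
            continue
        data_lines.append(ln)
    if not data_lines:
        raise InputError(f"{path}: no data rows")
    reader = csv.DictReader(data_lines, delimiter=delimiter)
    missing = set(RESULT_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    for row in reader:
        rows.append(
            NBEResult(
                id=row["id"],
                nbe=float(row["nbe"]),
                total_bond_energy=float(row["total_bond_energy_kj_mol"]),
                mw=float(row["mw"]),
                n_bonds=int(row["n_bonds"]),
                n_unmatched=int(row["n_unmatched"]),
                table_source=table_source,
            )
        )
    return rows
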