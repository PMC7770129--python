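"""Exception hierarchy shared across the package.

Grouped so the CLI can map families of failures onto distinct exit codes:
input/parse problems vs. validation problems vs. bad arguments.
"""


class NBEError(Exception):
    """Base class for all package errors."""


class InputError(NBEError):
    """Unreadable, empty, or unparseable input (files, records)."""


class EmptyInputError(InputError):
    """An input that yielded zero usable records."""


class TableFormatError(InputError):
    """A bond-table file that cannot be parsed (bad header, malformed row)."""


class ValidationError(NBEError):
    """Well-formed input whose content violates a contract (bad order, energy <= 0, conflicting duplicates)."""


class ArgumentError(NBEError, ValueError):
    """A caller-supplied argument outside its documented domain."""


class MoleculePreparationError(NBEError):
    """A molecule that could not be sanitized, kekulized, or carries an unsupported bond order."""

    def __init__(self, message: str, molecule_id: str | None = None):
        super().__init__(message)
        self.molecule_id = molecule_id


class UnmatchedBondError(NBEError):
    """A bond absent from the energy table under the ``error`` policy."""


class InsufficientDataError(NBEError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(NBEError):
    """Data on which the requested statistic is undefined (e.g. zero variance everywhere)."""
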