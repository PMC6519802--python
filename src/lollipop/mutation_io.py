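"""Reading, validation and protein-change parsing for cohort mutation tables.

The input is a MAF-like delimited text table (tab or comma) with four
required columns: ``Hugo_Symbol``, ``Sample_ID``, ``Protein_Change`` and
``Mutation_Type``.  The widely circulated example files also use the
misspelling ``Mutaiton_Type`` for the fourth column; both spellings are
accepted and normalized to ``Mutation_Type``.  Column order is free and
extra columns are ignored.

Protein changes are HGVS short-form strings (``p.R175H``, ``R273*``,
``p.E285fs`` ...).  Parsing is total: a string that cannot be interpreted
yields ``None`` instead of an exception, and the reader routes such rows
into the table's reject list so that no input row is silently dropped.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

__all__ = [
    "ProteinChange",
    "MutationRecord",
    "RejectedRow",
    "MutationTable",
    "ValidationReport",
    "MissingColumnsError",
    "EmptyInputError",
    "parse_protein_change",
    "read_mutation_table",
    "write_mutation_table",
    "write_rejects",
    "validate_table",
]

REQUIRED_COLUMNS = ("Hugo_Symbol", "Sample_ID", "Protein_Change", "Mutation_Type")

#: Accepted header aliases, normalized to the canonical name.
_HEADER_ALIASES = {"Mutaiton_Type": "Mutation_Type"}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U", "Xaa": "X",
}


class MissingColumnsError(ValueError):
    """Raised when required columns are absent from the header."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"missing required column(s): {', '.join(self.missing)}")


class EmptyInputError(ValueError):
    """Raised when the input stream contains no header row."""


@dataclass(frozen=True)
class ProteinChange:
    """A parsed amino-acid alteration.

    ``position`` is the 1-based residue index (HGVS/UniProt convention).
    ``ref_residue``/``alt_residue`` are one-letter codes, ``*`` for a stop,
    or ``None`` when the notation does not state them.  ``kind`` is one of
    ``missense``, ``nonsense``, ``frameshift``, ``inframe_indel``,
    ``splice``, ``synonymous``, ``other``.
    """

    position: int
    ref_residue: Optional[str]
    alt_residue: Optional[str]
    kind: str
    raw: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"residue position must be >= 1, got {self.position}")
        if self.kind == "missense":
            if (
                self.ref_residue not in _STANDARD_AA
                or self.alt_residue not in _STANDARD_AA
                or self.ref_residue == self.alt_residue
            ):
                raise ValueError(f"invalid missense change {self.raw!r}")

    @property
    def label(self) -> str:
        """Normalized short label used for counting and plot annotation."""
        ref = self.ref_residue or ""
        if self.kind == "missense" or self.kind == "nonsense" or self.kind == "synonymous":
            return f"{ref}{self.position}{self.alt_residue}"
        if self.kind == "frameshift":
            return f"{ref}{self.position}fs"
        if self.kind == "splice":
            return f"{ref}{self.position}_splice"
        # inframe_indel / other: strip a leading "p." from the raw text
        raw = self.raw.strip()
        return raw[2:] if raw.lower().startswith("p.") else raw


def _normalize_residues(text: str) -> str:
    """Rewrite three-letter residue codes to one-letter, ``Ter`` to ``*``."""

    def repl(m: re.Match) -> str:
        return _THREE_TO_ONE[m.group(0)]

    return re.sub("|".join(_THREE_TO_ONE), repl, text)


_RE_MISSENSE_LIKE = re.compile(r"^([A-Z])(\d+)([A-Z*=])$")
_RE_FRAMESHIFT = re.compile(r"^([A-Z])?(\d+)([A-Z])?fs(\*\d*|Ter\d*)?$", re.IGNORECASE)
_RE_SPLICE = re.compile(r"^([A-Z])?(\d+)_splice$", re.IGNORECASE)
_RE_INDEL = re.compile(
    r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?(del|ins|dup|delins)([A-Z*]*)$"
)
_RE_POSITION = re.compile(r"(\d+)")


def parse_protein_change(text: str) -> Optional[ProteinChange]:
    """Parse an HGVS short-form protein change; return ``None`` on failure.

    Accepts one- and three-letter residue codes, with or without a leading
    ``p.``.  Any string with an extractable residue position yields at least
    ``kind="other"``; a string with no digits at all is a parse failure.
    """
    if not isinstance(text, str):
        return None
    raw = text.strip()
    body = raw
    if body.lower().startswith("p."):
        body = body[2:]
    body = _normalize_residues(body.strip())
    if not body:
        return None

    m = _RE_SPLICE.match(body)
    if m:
        ref, pos = m.group(1), int(m.group(2))
        if pos >= 1:
            return ProteinChange(pos, ref, None, "splice", raw)

    m = _RE_FRAMESHIFT.match(body)
    if m:
        ref, pos = m.group(1), int(m.group(2))
        if pos >= 1:
            ref = ref.upper() if ref else None
            return ProteinChange(pos, ref, None, "frameshift", raw)

    m = _RE_INDEL.match(body)
    if m:
        pos = int(m.group(2))
        if pos >= 1:
            return ProteinChange(pos, m.group(1), None, "inframe_indel", raw)

    m = _RE_MISSENSE_LIKE.match(body)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if pos >= 1:
            if alt == "*":
                return ProteinChange(pos, ref, "*", "nonsense", raw)
            if alt == "=" or alt == ref:
                return ProteinChange(pos, ref, ref, "synonymous", raw)
            if ref in _STANDARD_AA and alt in _STANDARD_AA:
                return ProteinChange(pos, ref, alt, "missense", raw)
            return ProteinChange(pos, None, None, "other", raw)

    # Fallback: any extractable position makes the row plottable.
    m = _RE_POSITION.search(body)
    if m and int(m.group(1)) >= 1:
        return ProteinChange(int(m.group(1)), None, None, "other", raw)
    return None


@dataclass(frozen=True)
class MutationRecord:
    """One validated input row with its parsed protein change attached."""

    gene_symbol: str
    sample_id: str
    protein_change_raw: str
    mutation_type_raw: str
    change: ProteinChange

    def __post_init__(self) -> None:
        for name in ("gene_symbol", "sample_id", "protein_change_raw", "mutation_type_raw"):
            if not getattr(self, name).strip():
                raise ValueError(f"{name} must be non-empty")


@dataclass(frozen=True)
class RejectedRow:
    row_index: int  # 1-based index over data rows (header excluded)
    raw_row: str
    reason: str


@dataclass
class MutationTable:
    """Partition of the input data rows into parsed records and rejects."""

    records: list[MutationRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.records) + len(self.rejects)

    def gene_symbols(self) -> list[str]:
        seen: dict[str, str] = {}
        for r in self.records:
            seen.setdefault(r.gene_symbol.upper(), r.gene_symbol)
        return sorted(seen.values())


@dataclass(frozen=True)
class ValidationReport:
    missing_columns: tuple[str, ...]
    n_rows: int
    n_parsed: int
    n_rejected: int
    warnings: tuple[str, ...]


def _open_text(source: Union[str, Path, IO]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline="")
    if isinstance(source, io.BufferedIOBase) or isinstance(source, io.RawIOBase):
        return io.TextIOWrapper(source, encoding="utf-8", newline="")
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            return io.StringIO(data.decode("utf-8"), newline="")
        return io.StringIO(data, newline="")
    raise TypeError(f"unsupported source type: {type(source)!r}")


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_mutation_table(
    source: Union[str, Path, IO],
    delimiter: Optional[str] = None,
) -> MutationTable:
    """Read a delimited mutation table into a :class:`MutationTable`.

    The delimiter (tab vs comma) is auto-detected from the header row when
    not given.  Rows whose ``Protein_Change`` parses become records; all
    other data rows land in ``rejects`` with a reason.  Missing required
    columns or an empty file raise immediately.
    """
    fh = _open_text(source)
    first = fh.readline()
    if not first.strip():
        raise EmptyInputError("input contains no header row")
    delim = delimiter or _detect_delimiter(first)

    header = [h.strip() for h in next(csv.reader([first], delimiter=delim))]
    normalized = [_HEADER_ALIASES.get(h, h) for h in header]
    col_index = {name: i for i, name in enumerate(normalized)}
    missing = [c for c in REQUIRED_COLUMNS if c not in col_index]
    if missing:
        raise MissingColumnsError(missing)

    idx = [col_index[c] for c in REQUIRED_COLUMNS]
    table = MutationTable()
    reader = csv.reader(fh, delimiter=delim)
    for row_no, row in enumerate(reader, start=1):
        raw_line = delim.join(row)
        if not any(cell.strip() for cell in row):
            continue  # blank line, not a data row
        if len(row) < len(header):
            table.rejects.append(RejectedRow(row_no, raw_line, "too few fields"))
            continue
        gene, sample, pchange, mtype = (row[i].strip() for i in idx)
        empty = [
            name
            for name, val in zip(REQUIRED_COLUMNS, (gene, sample, pchange, mtype))
            if not val
        ]
        if empty:
            table.rejects.append(
                RejectedRow(row_no, raw_line, f"empty field(s): {', '.join(empty)}")
            )
            continue
        change = parse_protein_change(pchange)
        if change is None:
            table.rejects.append(
                RejectedRow(row_no, raw_line, f"unparseable Protein_Change: {pchange!r}")
            )
            continue
        table.records.append(MutationRecord(gene, sample, pchange, mtype, change))
    return table


def write_mutation_table(
    table: MutationTable, path: Union[str, Path], delimiter: str = "\t"
) -> None:
    """Write records back to a four-column delimited file (round-trippable)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for r in table.records:
            writer.writerow(
                [r.gene_symbol, r.sample_id, r.protein_change_raw, r.mutation_type_raw]
            )


def write_rejects(table: MutationTable, path: Union[str, Path]) -> None:
    """Export rejected rows as TSV with columns row_index, raw_line, reason."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["row_index", "raw_line", "reason"])
        for rej in table.rejects:
            writer.writerow([rej.row_index, rej.raw_row, rej.reason])


def validate_table(table: MutationTable) -> ValidationReport:
    """Summarize a parsed table; warn on duplicate (sample, gene, change) rows."""
    seen: set[tuple[str, str, str]] = set()
    warnings: list[str] = []
    for r in table.records:
        key = (r.sample_id, r.gene_symbol.upper(), r.change.label)
        if key in seen:
            warnings.append(
                f"duplicate row: sample {r.sample_id}, gene {r.gene_symbol}, "
                f"change {r.change.label}"
            )
        seen.add(key)
    return ValidationReport(
        missing_columns=(),
        n_rows=table.n_rows,
        n_parsed=len(table.records),
        n_rejected=len(table.rejects),
        warnings=tuple(warnings),
    )
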