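"""Protein length and domain features, from UniProt or local fixture files.

Two symmetric paths feed the plotting pipeline:

* **online** — :func:`resolve_accession` finds the reviewed UniProt entry
  for a gene symbol and :func:`fetch_protein_record` pulls its sequence
  length and domain features over the REST API (stdlib ``urllib`` behind an
  injectable transport, so tests replay recorded responses and never touch
  the network);
* **offline** — :func:`load_protein_record` reads the same information from
  a small human-readable cache file (one file per accession), which
  :func:`save_protein_record` writes.  Fetched records are written through
  to the cache, so a firewalled deployment can run entirely from files.

The module also exposes the bundled oncogene / tumor-suppressor gene
catalog used to populate gene pickers.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

__all__ = [
    "DomainFeature",
    "ProteinRecord",
    "GeneCatalog",
    "LookupError_",
    "TransportError",
    "FormatError",
    "RecordValidationError",
    "resolve_accession",
    "fetch_protein_record",
    "load_protein_record",
    "save_protein_record",
    "list_gene_catalog",
    "load_gene_catalog",
]

UNIPROT_SEARCH_URL = "https://rest.uniprot.org/uniprotkb/search"
UNIPROT_ENTRY_URL = "https://rest.uniprot.org/uniprotkb/{accession}.json"

#: UniProt feature classes drawn on the domain track by default.  The narrow
#: default ("Domain") matches typical published lollipop figures; "Region"
#: and "Motif" can be opted in.
DEFAULT_FEATURE_CLASSES = ("Domain",)

Transport = Callable[[str], bytes]


class LookupError_(ValueError):
    """Gene symbol or accession not found in the source."""


class TransportError(ConnectionError):
    """Network-level failure, distinct from a lookup miss."""


class FormatError(ValueError):
    """Response or file does not have the expected shape."""


class RecordValidationError(FormatError):
    """A record field violates its invariant; names the offending field."""


@dataclass(frozen=True, order=True)
class DomainFeature:
    """A named protein region with 1-based inclusive residue bounds."""

    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise RecordValidationError(
                f"domain {self.name!r}: need 1 <= start <= end, got [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    gene_symbol: str
    organism_id: int
    length: int
    domains: tuple[DomainFeature, ...]
    retrieved_at: str = "fixture"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise RecordValidationError(f"length: must be >= 1, got {self.length}")
        for d in self.domains:
            if d.end > self.length:
                raise RecordValidationError(
                    f"domain {d.name!r}: end {d.end} exceeds protein length {self.length}"
                )
        if list(self.domains) != sorted(self.domains):
            object.__setattr__(self, "domains", tuple(sorted(self.domains)))


@dataclass(frozen=True)
class GeneCatalog:
    """Unique gene symbols (case-insensitive uniqueness, case preserved)."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        folded = [s.upper() for s in self.symbols]
        if len(set(folded)) != len(folded):
            # deduplicate, keeping first-seen case, stable order
            seen: dict[str, str] = {}
            for s in self.symbols:
                seen.setdefault(s.upper(), s)
            object.__setattr__(self, "symbols", tuple(seen.values()))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in {s.upper() for s in self.symbols}


def _default_transport(url: str) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            return resp.read()
    except urllib.error.HTTPError as exc:
        if exc.code == 404:
            raise LookupError_(f"not found: {url}") from exc
        raise TransportError(f"HTTP {exc.code} fetching {url}") from exc
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise TransportError(f"network failure fetching {url}: {exc}") from exc


def resolve_accession(
    gene_symbol: str,
    organism_id: int = 9606,
    transport: Optional[Transport] = None,
) -> str:
    """Resolve a gene symbol to its reviewed UniProt accession.

    Only reviewed (Swiss-Prot) entries with an exact gene-name match are
    considered.  When several remain, the lexicographically smallest
    accession is returned so the choice is deterministic.
    """
    transport = transport or _default_transport
    query = f'gene_exact:{gene_symbol} AND organism_id:{organism_id} AND reviewed:true'
    url = (
        UNIPROT_SEARCH_URL
        + "?"
        + urllib.parse.urlencode(
            {"query": query, "fields": "accession,gene_primary", "format": "json", "size": "25"}
        )
    )
    body = transport(url)
    try:
        payload = json.loads(body)
        results = payload["results"]
    except (ValueError, KeyError, TypeError) as exc:
        raise FormatError(f"malformed search response for {gene_symbol!r}") from exc
    accessions = []
    for entry in results:
        acc = entry.get("primaryAccession")
        if acc:
            accessions.append(acc)
    if not accessions:
        raise LookupError_(
            f"no reviewed UniProt entry for gene {gene_symbol!r} (taxon {organism_id})"
        )
    return min(accessions)


def _parse_entry_json(body: bytes, feature_classes: Sequence[str]) -> ProteinRecord:
    try:
        entry = json.loads(body)
        accession = entry["primaryAccession"]
        length = int(entry["sequence"]["length"])
        organism_id = int(entry["organism"]["taxonId"])
        genes = entry.get("genes") or []
        gene_symbol = ""
        if genes:
            gene_symbol = genes[0].get("geneName", {}).get("value", "")
        domains = []
        for feat in entry.get("features", []):
            if feat.get("type") not in feature_classes:
                continue
            loc = feat["location"]
            start = int(loc["start"]["value"])
            end = int(loc["end"]["value"])
            domains.append(DomainFeature(start, end, feat.get("description") or feat["type"]))
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, RecordValidationError):
            raise
        raise FormatError("malformed UniProt entry response") from exc
    return ProteinRecord(
        accession=accession,
        gene_symbol=gene_symbol,
        organism_id=organism_id,
        length=length,
        domains=tuple(sorted(domains)),
        retrieved_at=datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
    )


def fetch_protein_record(
    accession: str,
    feature_classes: Sequence[str] = DEFAULT_FEATURE_CLASSES,
    transport: Optional[Transport] = None,
    cache_dir: Optional[Union[str, Path]] = None,
) -> ProteinRecord:
    """Fetch a protein record from UniProt; write through to ``cache_dir``."""
    transport = transport or _default_transport
    body = transport(UNIPROT_ENTRY_URL.format(accession=accession))
    record = _parse_entry_json(body, feature_classes)
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        save_protein_record(record, cache_dir / f"{record.accession}.domains.txt")
    return record


# ---------------------------------------------------------------------------
# Cache / fixture files.  Schema: tab-separated key-value header lines
# (accession, gene_symbol, organism_id, length, retrieved_at) followed by
# one "domain <name> <start> <end>" line per feature.  Lines starting with
# '#' are comments.


def save_protein_record(record: ProteinRecord, path: Union[str, Path]) -> None:
    lines = [
        "# protein-record v1",
        f"accession\t{record.accession}",
        f"gene_symbol\t{record.gene_symbol}",
        f"organism_id\t{record.organism_id}",
        f"length\t{record.length}",
        f"retrieved_at\t{record.retrieved_at}",
    ]
    for d in record.domains:
        lines.append(f"domain\t{d.name}\t{d.start}\t{d.end}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_protein_record(path: Union[str, Path]) -> ProteinRecord:
    """Load a cache/fixture file; ``retrieved_at`` becomes ``"fixture"``."""
    path = Path(path)
    fields: dict[str, str] = {}
    domains: list[DomainFeature] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "domain":
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: domain line needs name, start, end")
            try:
                domains.append(DomainFeature(int(parts[2]), int(parts[3]), parts[1]))
            except ValueError as exc:
                if isinstance(exc, RecordValidationError):
                    raise
                raise FormatError(f"{path}:{lineno}: non-integer domain bounds") from exc
        elif len(parts) == 2:
            fields[parts[0]] = parts[1]
        else:
            raise FormatError(f"{path}:{lineno}: unrecognized line {line!r}")
    missing = [k for k in ("accession", "gene_symbol", "organism_id", "length") if k not in fields]
    if missing:
        raise FormatError(f"{path}: missing field(s): {', '.join(missing)}")
    try:
        return ProteinRecord(
            accession=fields["accession"],
            gene_symbol=fields["gene_symbol"],
            organism_id=int(fields["organism_id"]),
            length=int(fields["length"]),
            domains=tuple(sorted(domains)),
            retrieved_at="fixture",
        )
    except RecordValidationError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer organism_id or length") from exc


# ---------------------------------------------------------------------------
# Gene catalog

_CATALOG_RESOURCE = "cancer_gene_catalog.synthetic.txt"


def _read_symbol_lines(lines: Iterable[str]) -> GeneCatalog:
    symbols = []
    for line in lines:
        sym = line.strip()
        if sym and not sym.startswith("#"):
            symbols.append(sym)
    return GeneCatalog(tuple(symbols))


def load_gene_catalog(path: Union[str, Path]) -> GeneCatalog:
    """Load a user catalog: one symbol per line, '#' comments allowed."""
    return _read_symbol_lines(Path(path).read_text(encoding="utf-8").splitlines())


def list_gene_catalog(extra_path: Optional[Union[str, Path]] = None) -> GeneCatalog:
    """Return the bundled 409-gene catalog, optionally extended from a file."""
    text = (
        resources.files("lollipop.data").joinpath(_CATALOG_RESOURCE).read_text(encoding="utf-8")
    )
    catalog = _read_symbol_lines(text.splitlines())
    if extra_path is not None:
        extra = load_gene_catalog(extra_path)
        catalog = GeneCatalog(catalog.symbols + extra.symbols)
    return catalog


def bundled_fixture_path(name: str) -> Path:
    """Path to a bundled demo fixture (e.g. ``TP53``) inside the package."""
    res = resources.files("lollipop.data").joinpath(f"{name}.synthetic.domains.txt")
    return Path(str(res))
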