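"""Proteome I/O: FASTA reading/writing, taxonomy metadata, TSV tables.

A :class:`Proteome` is an ordered collection of protein records tagged with a
UniProt-style proteome identifier, a domain of life and a clade (the first
lineage term after the domain). FASTA headers in the UniProt
``db|ACCESSION|name`` style yield the central accession token; any other
header yields its first whitespace-delimited token.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, SchemaError

logger = logging.getLogger(__name__)

DOMAINS_OF_LIFE = ("Archaea", "Bacteria", "Eukaryota", "Viruses")


@dataclass
class ProteinRecord:
    """One protein: accession plus an uppercase amino-acid sequence."""

    accession: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """Ordered protein collection with organism-level metadata."""

    proteome_id: str
    proteins: list[ProteinRecord] = field(default_factory=list)
    domain_of_life: str = "Unknown"
    clade: str = ""

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    @property
    def n_residues(self) -> int:
        return sum(len(p) for p in self.proteins)

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    def get(self, accession: str) -> ProteinRecord:
        for p in self.proteins:
            if p.accession == accession:
                return p
        raise KeyError(accession)


def _accession_from_header(header_id: str) -> str:
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id


def read_fasta(path: str | Path, proteome_id: str | None = None) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    Sequences are uppercased with all whitespace removed; ``*`` stop
    characters are stripped with a logged warning. A record with an empty
    sequence raises :class:`FormatError` naming the record.
    """
    path = Path(path)
    if proteome_id is None:
        proteome_id = path.stem
    proteins: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        if "*" in seq:
            logger.warning("stripping %d stop character(s) from %s",
                           seq.count("*"), acc)
            seq = seq.replace("*", "")
        if not seq:
            raise FormatError(f"record {acc!r} in {path} has an empty sequence")
        if acc in seen:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        proteins.append(ProteinRecord(acc, seq))
    return Proteome(proteome_id, proteins)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome as plain ``>accession`` FASTA."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="")
        for p in proteome.proteins
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def parse_lineage(lineage: str) -> tuple[str, str]:
    """Extract (domain_of_life, clade) from a taxonomy lineage string.

    The domain is the first element recognized among Archaea / Bacteria /
    Eukaryota / Viruses; the clade is the next element, if any. Unrecognized
    or degenerate input yields ``("Unknown", "")``; this never raises.
    """
    if not lineage:
        return "Unknown", ""
    sep = ";" if ";" in lineage else ","
    terms = [t.strip() for t in lineage.split(sep) if t.strip()]
    lowered = {d.lower(): d for d in DOMAINS_OF_LIFE}
    for i, term in enumerate(terms):
        dom = lowered.get(term.lower())
        if dom is not None:
            clade = terms[i + 1] if i + 1 < len(terms) else ""
            return dom, clade
    return "Unknown", ""


def read_metadata(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the sidecar metadata TSV (proteome_id, domain_of_life, lineage).

    Returns ``{proteome_id: (domain_of_life, clade)}``. An empty
    domain_of_life column is derived from the lineage via
    :func:`parse_lineage`.
    """
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("proteome_id", "lineage"):
            if col not in idx:
                raise SchemaError(f"metadata file {path} lacks column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            pid = fields[idx["proteome_id"]]
            lineage = fields[idx["lineage"]] if idx["lineage"] < len(fields) else ""
            dom, clade = parse_lineage(lineage)
            if "domain_of_life" in idx and idx["domain_of_life"] < len(fields):
                explicit = fields[idx["domain_of_life"]].strip()
                if explicit:
                    dom = explicit
            out[pid] = (dom, clade)
    return out


def apply_metadata(proteome: Proteome, meta: Mapping[str, tuple[str, str]]) -> Proteome:
    """Attach domain/clade metadata to a proteome in place; returns it."""
    if proteome.proteome_id in meta:
        proteome.domain_of_life, proteome.clade = meta[proteome.proteome_id]
    return proteome


def _render(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    schema: Sequence[str],
) -> None:
    """Write records as a TSV with header, 6-significant-digit floats and
    deterministic row order (sorted by the first schema column)."""
    schema = list(schema)
    rendered: list[list[str]] = []
    for row in rows:
        missing = [c for c in schema if c not in row]
        if missing:
            raise SchemaError(f"row missing column(s) {missing}: {dict(row)!r}")
        rendered.append([_render(row[c]) for c in schema])
    rendered.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("\t".join(schema) + "\n")
        for r in rendered:
            fh.write("\t".join(r) + "\n")
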