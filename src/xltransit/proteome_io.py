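"""UniProt-dialect FASTA reading/writing and accession handling.

Headers follow either the UniProt convention
``>sp|ACCESSION|ENTRY_NAME description`` (or ``tr|``) or a bare
``>ACCESSION``. Sequences are restricted to the 20 standard residues —
ambiguity codes (B, J, O, U, X, Z) and ``*`` stop characters are rejected at
parse time so that every downstream mass is exact.

UniProt distinguishes the canonical sequence of an entry from its isoforms by
a dash-suffixed accession (``P02649`` vs ``P02649-2``); ``classify_accession``
implements that rule.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio import SeqIO

from .errors import ParseError

STANDARD_RESIDUES = frozenset("GASPVTCLINDQKEMHFRYW")

# UniProt accession grammar (6-character form), optional -N isoform suffix.
_ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
    r"(?:-\d+)?$"
)


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: a canonical or isoform UniProt accession with its
    entry name, database tag (``sp`` reviewed / ``tr`` unreviewed),
    description, and sequence."""

    accession: str
    entry_name: str
    db_tag: str
    description: str
    sequence: str

    @property
    def label(self) -> str:
        """The ``db|ACC|ENTRY_NAME`` display label used in result tables."""
        return f"{self.db_tag}|{self.accession}|{self.entry_name}"


def classify_accession(accession: str) -> tuple[str, str]:
    """Classify an accession as ``"canonical"`` or ``"isoform"`` and return
    its base accession (the part before the dash; itself when canonical)."""
    if not accession:
        raise ParseError("empty accession")
    if "-" in accession:
        return "isoform", accession.split("-", 1)[0]
    return "canonical", accession


def _record_from_header(header: str, sequence: str, index: int) -> ProteinRecord:
    if header.startswith(("sp|", "tr|")):
        fields = header.split("|")
        if len(fields) < 3 or not fields[1] or not fields[2]:
            raise ParseError(
                f"record {index}: malformed UniProt header '>{header.split()[0]}' "
                f"(expected 'sp|ACCESSION|ENTRY_NAME description')"
            )
        db_tag, accession = fields[0], fields[1]
        rest = "|".join(fields[2:])
        entry_name, _, description = rest.partition(" ")
    else:
        accession, _, description = header.partition(" ")
        db_tag, entry_name = "sp", ""
    if not _ACCESSION_RE.match(accession):
        raise ParseError(
            f"record {index}: accession {accession!r} does not match the "
            f"UniProt accession grammar"
        )
    for pos, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_RESIDUES:
            raise ParseError(
                f"record {index} ({accession}): illegal residue {aa!r} at "
                f"position {pos}"
            )
    return ProteinRecord(
        accession=accession,
        entry_name=entry_name,
        db_tag=db_tag,
        description=description.strip(),
        sequence=sequence,
    )


def parse_fasta(stream: TextIO | str) -> list[ProteinRecord]:
    """Read a UniProt-dialect FASTA stream into :class:`ProteinRecord` s.

    Sequences are whitespace-stripped and uppercased; record order is
    preserved. Malformed headers and non-standard residues raise
    :class:`ParseError` naming the offending record and position.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[ProteinRecord] = []
    for index, rec in enumerate(SeqIO.parse(stream, "fasta"), start=1):
        sequence = str(rec.seq).replace(" ", "").upper()
        if not sequence:
            raise ParseError(f"record {index} ({rec.id}): empty sequence")
        records.append(_record_from_header(rec.description, sequence, index))
    return records


def write_fasta(
    records: Iterable[ProteinRecord], stream: TextIO | None = None, width: int = 60
) -> str:
    """Serialize records back to the UniProt header dialect.

    Returns the FASTA text; also writes it to ``stream`` when given. A
    parse → write → parse round trip is the identity on records.
    """
    chunks: list[str] = []
    for rec in records:
        if rec.entry_name:
            header = f">{rec.db_tag}|{rec.accession}|{rec.entry_name}"
            if rec.description:
                header += f" {rec.description}"
        else:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
        chunks.append(header)
        chunks.extend(
            rec.sequence[i : i + width] for i in range(0, len(rec.sequence), width)
        )
    text = "\n".join(chunks) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def index_by_accession(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Accession → record map (last one wins on duplicates)."""
    return {rec.accession: rec for rec in records}
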