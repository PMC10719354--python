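"""In-silico enzymatic digestion.

High-specificity cleavage rules with a no-cleavage-before-proline exception,
missed-cleavage enumeration, and length filtering. Cross-linked lysines block
tryptic cleavage in real samples, so linkable peptides typically require
missed cleavages; the pipeline default is ``max_missed=2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

from .errors import XLTransitError

if TYPE_CHECKING:  # pragma: no cover
    from .proteome_io import ProteinRecord


@dataclass(frozen=True)
class EnzymeSpec:
    """A protease: cleaves after ``cleave_after`` unless the next residue is
    in ``exception_next`` (Keil-style high-specificity rule)."""

    name: str
    cleave_after: frozenset[str]
    exception_next: frozenset[str]


TRYPSIN = EnzymeSpec("trypsin", frozenset("KR"), frozenset("P"))
#: High-specificity chymotrypsin (F/W/Y only, not L/M).
CHYMOTRYPSIN = EnzymeSpec("chymotrypsin", frozenset("FWY"), frozenset("P"))

ENZYMES: dict[str, EnzymeSpec] = {e.name: e for e in (TRYPSIN, CHYMOTRYPSIN)}


@dataclass(frozen=True)
class Peptide:
    """A digestion product located in its parent protein.

    ``start``/``end`` are 1-based inclusive coordinates; ``missed_cleavages``
    counts the internal cleavage sites the peptide spans. The terminus flags
    record whether the peptide carries the protein N-/C-terminus, which
    matters downstream for linker-site eligibility.
    """

    parent_accession: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int
    is_protein_nterm: bool
    is_protein_cterm: bool

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Positions ``i`` (1-based, between residues i and i+1) where the enzyme
    cuts: residue i in ``cleave_after`` and residue i+1 not in
    ``exception_next``. The protein C-terminus is not a cleavage site."""
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in enzyme.cleave_after
        and sequence[i] not in enzyme.exception_next
    ]


def digest(
    record: "ProteinRecord", enzyme: EnzymeSpec, max_missed: int = 2
) -> list[Peptide]:
    """All peptides with 0..``max_missed`` missed cleavages.

    Fully specific digestion: every peptide terminus is either a protein
    terminus or a valid cleavage boundary. Peptides are unique by
    ``(start, end)`` and returned in positional order. The C-terminal peptide
    is emitted even at length 1 — length filtering is a separate stage.
    """
    if max_missed < 0:
        raise XLTransitError(f"max_missed must be >= 0, got {max_missed}")
    seq = record.sequence
    n = len(seq)
    boundaries = [0] + cleavage_sites(seq, enzyme) + [n]
    peptides: list[Peptide] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            peptides.append(
                Peptide(
                    parent_accession=record.accession,
                    sequence=seq[start - 1 : end],
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                    is_protein_nterm=start == 1,
                    is_protein_cterm=end == n,
                )
            )
    return peptides


def filter_by_length(
    peptides: Iterable[Peptide], min_len: int, max_len: int
) -> list[Peptide]:
    """Keep peptides with ``min_len <= length <= max_len``, order preserved."""
    if min_len < 1 or min_len > max_len:
        raise XLTransitError(
            f"invalid length range [{min_len}, {max_len}]: need 1 <= min <= max"
        )
    return [p for p in peptides if min_len <= len(p) <= max_len]


def get_enzyme(name: str) -> EnzymeSpec:
    """Look up a bundled enzyme by name (case-insensitive)."""
    try:
        return ENZYMES[name.lower()]
    except KeyError:
        raise XLTransitError(
            f"unknown enzyme {name!r}; valid names: {sorted(ENZYMES)}"
        ) from None
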