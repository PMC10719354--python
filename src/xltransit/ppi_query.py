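"""STRING interaction tables, UniProt↔STRING mapping, and interactor ranking.

STRING distributes protein.links files as whitespace-separated
``protein1 protein2 combined_score`` rows with identifiers like
``9606.ENSP00000379873`` and integer scores 0–999; the combined score is
STRING's confidence that two proteins interact, displayed on [0, 1]. The
ranked list for a target is tiered by the standard STRING confidence
thresholds: highest (> 0.9), high (> 0.7), medium (> 0.4), low (> 0.15).

STRING does not distinguish a UniProt entry's canonical form from its
isoforms — both share one STRING identifier — so isoform targets resolve
through their base accession.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .errors import ParseError, XLTransitError
from .proteome_io import ProteinRecord, classify_accession

logger = logging.getLogger("xltransit.ppi_query")

TIER_THRESHOLDS = (
    ("highest", 0.9),
    ("high", 0.7),
    ("medium", 0.4),
    ("low", 0.15),
)


@dataclass(frozen=True)
class PPIEdge:
    """One undirected STRING interaction with its combined score on [0, 1]."""

    protein_a: str
    protein_b: str
    combined_score: float


@dataclass(frozen=True)
class Interactor:
    """One ranked partner of the target: display label, score, and tier."""

    rank: int
    label: str
    accession: str
    combined_score: float
    tier: str


class AccessionMap:
    """Bidirectional UniProt accession ↔ STRING identifier mapping.

    Many UniProt accessions may share one STRING identifier; the reverse
    lookup returns the lexicographically smallest mapped accession for
    determinism. Isoform accessions resolve via their base accession.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._to_string: dict[str, str] = {}
        self._to_uniprot: dict[str, str] = {}
        for uniprot, string_id in pairs:
            self._to_string[uniprot] = string_id
            if string_id not in self._to_uniprot or uniprot < self._to_uniprot[string_id]:
                self._to_uniprot[string_id] = uniprot

    def string_id(self, accession: str) -> str | None:
        """STRING identifier for a UniProt accession (isoforms via base)."""
        if accession in self._to_string:
            return self._to_string[accession]
        _, base = classify_accession(accession)
        return self._to_string.get(base)

    def uniprot(self, string_id: str) -> str | None:
        return self._to_uniprot.get(string_id)

    def __len__(self) -> int:
        return len(self._to_string)


def load_accession_map(stream: TextIO | str) -> AccessionMap:
    """Read a two-column TSV of ``uniprot_accession<TAB>string_id``."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"accession map line {lineno}: expected 2 tab-separated "
                f"columns, got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    return AccessionMap(pairs)


def load_ppi_table(
    stream: TextIO | str, score_scale: str = "string_integer"
) -> list[PPIEdge]:
    """Read a STRING protein.links-dialect table.

    ``score_scale="string_integer"`` divides integer scores 0–999 by 1000
    (the scale STRING files carry); ``"unit"`` passes reals in [0, 1]
    through. An optional header line is skipped.
    """
    if score_scale not in ("string_integer", "unit"):
        raise XLTransitError(f"unknown score_scale {score_scale!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] != 3:
        raise ParseError(f"PPI table: expected 3 columns, got {df.shape[1]}")
    offset = 1
    first = df.iloc[0]
    try:
        float(first.iloc[2])
    except ValueError:
        df = df.iloc[1:]  # header line
        offset = 2
    edges: list[PPIEdge] = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + offset
        a, b, raw = row
        try:
            score = float(raw)
        except ValueError:
            raise ParseError(f"PPI table line {lineno}: bad score {raw!r}") from None
        if score_scale == "string_integer":
            if not (score.is_integer() and 0 <= score <= 999):
                raise ParseError(
                    f"PPI table line {lineno}: score {raw!r} outside the "
                    f"STRING integer range 0-999"
                )
            score /= 1000.0
        elif not 0.0 <= score <= 1.0:
            raise ParseError(
                f"PPI table line {lineno}: score {raw!r} outside [0, 1]"
            )
        if a == b:
            raise ParseError(f"PPI table line {lineno}: self-edge {a!r}")
        edges.append(PPIEdge(protein_a=a, protein_b=b, combined_score=score))
    return edges


def confidence_tier(score: float) -> str:
    """STRING confidence tier of a combined score; thresholds are strict."""
    if not 0.0 <= score <= 1.0:
        raise XLTransitError(f"combined score {score} outside [0, 1]")
    for tier, threshold in TIER_THRESHOLDS:
        if score > threshold:
            return tier
    return "below_cutoff"


def query_interactors(
    target_accession: str,
    edges: Iterable[PPIEdge],
    accession_map: AccessionMap,
    top_n: int,
    proteome: Mapping[str, ProteinRecord] | None = None,
) -> list[Interactor]:
    """Rank the top-N interactors of a target protein.

    Edges are undirected; symmetric duplicates are collapsed keeping the
    maximum score. Partners sort by combined score descending with ties
    broken by partner STRING identifier, then accession. Partners with no
    reverse mapping are kept under their raw STRING identifier with a logged
    warning.
    """
    if top_n < 0:
        raise XLTransitError(f"top_n must be >= 0, got {top_n}")
    target_id = accession_map.string_id(target_accession)
    if target_id is None:
        raise XLTransitError(
            f"unknown target {target_accession!r}: no STRING mapping"
        )
    # partner STRING id -> best score over both directions
    partners: dict[str, float] = {}
    for edge in edges:
        if edge.protein_a == target_id:
            partner = edge.protein_b
        elif edge.protein_b == target_id:
            partner = edge.protein_a
        else:
            continue
        if partner not in partners or edge.combined_score > partners[partner]:
            partners[partner] = edge.combined_score

    decorated: list[tuple[float, str, str, str]] = []
    for string_id, score in partners.items():
        accession = accession_map.uniprot(string_id)
        if accession is None:
            logger.warning(
                "partner %s has no UniProt mapping; keeping raw STRING id",
                string_id,
            )
            decorated.append((score, string_id, string_id, string_id))
            continue
        if proteome is not None and accession in proteome:
            label = proteome[accession].label
        else:
            label = f"sp|{accession}|"
        decorated.append((score, string_id, accession, label))

    decorated.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [
        Interactor(
            rank=i,
            label=label,
            accession=accession,
            combined_score=score,
            tier=confidence_tier(score),
        )
        for i, (score, _sid, accession, label) in enumerate(
            decorated[:top_n], start=1
        )
    ]
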