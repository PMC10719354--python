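"""Self-contained test inputs: the APOE interactor fixture and synthetic
proteomes.

``apoe_fixture`` rebuilds, with no downloads, the worked APOE example: the
published top-10 APOE interactor table (ranks, ``sp|ACC|ENTRY_NAME`` labels
and combined scores are the real, published values) together with an
11-protein proteome whose sequences are SYNTHETIC stand-ins — short
constructed sequences with controlled lysine placement, NOT the real human
protein sequences — and a synthetic UniProt→STRING mapping. That is exactly
what reproducing the interactor ranking and exercising the mass pipeline
requires; nothing downstream depends on the true sequences.

``synth_proteome`` generates reproducible random proteomes with a requested
lysine density so digestion and linker-site behaviour can be tested with
controllable structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import XLTransitError
from .proteome_io import ProteinRecord, write_fasta

#: The published top-10 APOE (P02649) interactor table: (rank, accession,
#: entry name, combined score). Scores and order are verbatim.
APOE_TABLE1 = (
    (1, "Q07954", "LRP1_HUMAN", 0.999),
    (2, "Q14114", "LRP8_HUMAN", 0.999),
    (3, "P04114", "APOB_HUMAN", 0.998),
    (4, "P05067", "A4_HUMAN", 0.998),
    (5, "P01130", "LDLR_HUMAN", 0.998),
    (6, "P02647", "APOA1_HUMAN", 0.997),
    (7, "P10636", "TAU_HUMAN", 0.997),
    (8, "P98155", "VLDLR_HUMAN", 0.997),
    (9, "Q9NZC2", "TREM2_HUMAN", 0.995),
    (10, "Q92673", "SORL_HUMAN", 0.995),
)

APOE_ACCESSION = "P02649"
_APOE_STRING_ID = "9606.ENSP00000100000"

_PREFIX_POOL = "ADEGHILNQSTV"

STANDARD_RESIDUES = "GASPVTCLINDQKEMHFRYW"


@dataclass(frozen=True)
class FixtureBundle:
    """A complete, parseable input set: FASTA text, STRING-dialect PPI
    table, accession-map TSV, and per-record provenance notes."""

    proteome_fasta: str
    ppi_table: str
    accession_map: str
    provenance: dict[str, str]

    def write_to(self, directory: str | Path) -> dict[str, Path]:
        """Materialize the bundle as files; returns the written paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": directory / "proteome.fasta",
            "ppi": directory / "ppi_links.txt",
            "map": directory / "accession_map.tsv",
        }
        paths["proteome"].write_text(self.proteome_fasta)
        paths["ppi"].write_text(self.ppi_table)
        paths["map"].write_text(self.accession_map)
        return paths


def _stand_in_sequence(index: int) -> str:
    """Deterministic synthetic stand-in sequence.

    Tryptic digestion with <=2 missed cleavages yields exactly one 9-residue
    peptide per protein, ``xCDEyMKGR`` with two index-varied filler residues
    (one internal linkable K, one C for static carbamidomethylation, one M
    for variable oxidation), embedded between a variable prefix and a fixed
    tail so every fixture protein feeds the worked length-9 search with a
    distinct peptide.
    """
    pool = _PREFIX_POOL
    letters = [pool[(index * 7 + k * 3 + 1) % len(pool)] for k in range(5)]
    core = pool[index % len(pool)] + "CDE" + pool[(index * 5 + 2) % len(pool)] + "MKGR"
    return "M" + "".join(letters) + "K" + core + "AGGSE"


def apoe_fixture() -> FixtureBundle:
    """The APOE worked-example bundle (deterministic, byte-stable).

    Partner STRING identifiers are synthetic and assigned in published rank
    order, so equal combined scores rank in the published order. Sequences
    are synthetic stand-ins (see module docstring).
    """
    records = [
        ProteinRecord(
            accession=APOE_ACCESSION,
            entry_name="APOE_HUMAN",
            db_tag="sp",
            description="Apolipoprotein E (synthetic stand-in sequence)",
            sequence=_stand_in_sequence(0),
        )
    ]
    provenance = {APOE_ACCESSION: "published_apoe_table (synthetic stand-in sequence)"}
    map_lines = [f"{APOE_ACCESSION}\t{_APOE_STRING_ID}"]
    ppi_lines = ["protein1 protein2 combined_score"]
    for rank, accession, entry_name, score in APOE_TABLE1:
        string_id = f"9606.ENSP{100000 + rank:011d}"
        records.append(
            ProteinRecord(
                accession=accession,
                entry_name=entry_name,
                db_tag="sp",
                description=f"{entry_name.split('_')[0]} (synthetic stand-in sequence)",
                sequence=_stand_in_sequence(rank),
            )
        )
        provenance[accession] = "published_apoe_table (synthetic stand-in sequence)"
        map_lines.append(f"{accession}\t{string_id}")
        ppi_lines.append(f"{_APOE_STRING_ID} {string_id} {round(score * 1000)}")
    return FixtureBundle(
        proteome_fasta=write_fasta(records),
        ppi_table="\n".join(ppi_lines) + "\n",
        accession_map="\n".join(map_lines) + "\n",
        provenance=provenance,
    )


def synth_proteome(
    n: int,
    length_range: tuple[int, int] = (30, 60),
    lysine_density: float = 0.05,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Reproducible random proteome with a requested lysine density.

    Each sequence draws residues i.i.d.: K with probability
    ``lysine_density``, the remaining 19 standard residues uniformly over the
    rest of the probability mass. Identical ``(n, length_range,
    lysine_density, seed)`` always yield identical records.
    """
    if not 1 <= n <= 999:
        raise XLTransitError(f"n must be in [1, 999], got {n}")
    if not 0.0 <= lysine_density <= 1.0:
        raise XLTransitError(
            f"lysine density must be in [0, 1], got {lysine_density}"
        )
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise XLTransitError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    others = [aa for aa in STANDARD_RESIDUES if aa != "K"]
    probs = [lysine_density] + [(1.0 - lysine_density) / len(others)] * len(others)
    alphabet = ["K"] + others
    records: list[ProteinRecord] = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        records.append(
            ProteinRecord(
                accession=f"P1A{i:03d}",
                entry_name=f"SYN{i:03d}_SYNTH",
                db_tag="sp",
                description=f"synthetic random protein (seed={seed})",
                sequence=seq,
            )
        )
    return records
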