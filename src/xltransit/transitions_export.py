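"""Result-table assembly and CSV export.

Two tables leave the pipeline: the ranked interactor list (rank, label,
combined score, confidence tier) and the SRM transition list with twelve
fixed columns — combined score, protein A peptide, cross linker, protein B
peptide, precursor charge, precursor m/z, protein A ion, protein A ion type,
protein B ion, protein B ion type, product charge, product m/z.

Peptides are annotated with mass-delta brackets after the modified residue
(``PEPTM[+15.99491]K``), the notation Skyline and most vendor tools accept.
m/z values are written with six decimal places.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .chem_masses import ModForm
from .ppi_query import Interactor
from .product_enum import PRODUCT_KINDS, FragmentIon, LinkProduct

TRANSITION_COLUMNS = (
    "combined score",
    "protein A peptide",
    "cross linker",
    "protein B peptide",
    "precursor charge",
    "precursor m/z",
    "protein A ion",
    "protein A ion type",
    "protein B ion",
    "protein B ion type",
    "product charge",
    "product m/z",
)

INTERACTOR_COLUMNS = ("rank", "protein name", "interaction probability", "confidence")


@dataclass(frozen=True)
class TransitionRow:
    """One exported transition-list row (the twelve-column schema).

    Exactly one of the protein A / protein B ion columns is populated per
    row — a b/y fragment belongs to one constituent peptide. m/z values are
    stored already rounded to six decimals so that CSV export/import is the
    identity.
    """

    combined_score: float | None
    protein_a_peptide: str
    cross_linker: str
    protein_b_peptide: str
    precursor_charge: int
    precursor_mz: float
    protein_a_ion: str
    protein_a_ion_type: str
    protein_b_ion: str
    protein_b_ion_type: str
    product_charge: int
    product_mz: float


def annotate_modform(form: ModForm | None) -> str:
    """Render a peptide form with bracketed mass-delta annotations."""
    if form is None:
        return ""
    deltas: dict[int, float] = {}
    for site, mod in form.applied:
        deltas[site] = deltas.get(site, 0.0) + mod.delta_mass
    out: list[str] = []
    for i, aa in enumerate(form.sequence, start=1):
        out.append(aa)
        if i in deltas:
            out.append(f"[{deltas[i]:+.5f}]")
    return "".join(out)


def build_transition_table(
    interactors: Sequence[Interactor],
    products: Sequence[LinkProduct],
    fragments: Sequence[FragmentIon],
) -> list[TransitionRow]:
    """Fan (product, fragment) pairs out into transition rows.

    Each fragment becomes one row sharing its parent product's precursor
    columns. The combined score is resolved from the interactor whose
    accession matches the product's protein-B peptide; products with no B
    side (target-only loop/mono-links) carry an empty score. Rows sort by
    score descending (None last), then product kind, peptide coordinates,
    and charges; separate modification forms of one peptide are separate
    rows.
    """
    score_by_accession = {it.accession: it.combined_score for it in interactors}
    by_parent: dict[int, list[FragmentIon]] = {}
    for frag in fragments:
        by_parent.setdefault(id(frag.parent), []).append(frag)

    rows: list[tuple[tuple, TransitionRow]] = []
    for product in products:
        score: float | None = None
        if product.beta is not None:
            score = score_by_accession.get(product.beta.peptide.parent_accession)
        pep_a = annotate_modform(product.alpha)
        pep_b = annotate_modform(product.beta)
        for frag in by_parent.get(id(product), ()):
            if frag.of_peptide == "alpha":
                a_ion, a_type, b_ion, b_type = frag.ion_label, frag.series, "", ""
            else:
                a_ion, a_type, b_ion, b_type = "", "", frag.ion_label, frag.series
            row = TransitionRow(
                combined_score=score,
                protein_a_peptide=pep_a,
                cross_linker=product.linker.name,
                protein_b_peptide=pep_b,
                precursor_charge=product.precursor_charge,
                precursor_mz=round(product.precursor_mz, 6),
                protein_a_ion=a_ion,
                protein_a_ion_type=a_type,
                protein_b_ion=b_ion,
                protein_b_ion_type=b_type,
                product_charge=frag.charge,
                product_mz=round(frag.mz, 6),
            )
            sort_key = (
                score is None,
                -(score or 0.0),
                PRODUCT_KINDS.index(product.kind),
                pep_a,
                pep_b,
                tuple(s.position for s in product.sites),
                product.precursor_charge,
                frag.of_peptide,
                frag.series,
                frag.index,
                frag.remnant_delta,
                frag.charge,
            )
            rows.append((sort_key, row))
    rows.sort(key=lambda kr: kr[0])
    return [row for _, row in rows]


def _format_score(score: float | None) -> str:
    return "" if score is None else f"{score:g}"


def export_transitions_csv(
    rows: Iterable[TransitionRow], destination: TextIO | str
) -> None:
    """Write the transition table as RFC 4180 CSV (UTF-8, header row,
    six-decimal fixed-point m/z)."""
    close = False
    if isinstance(destination, str):
        destination = open(destination, "w", newline="", encoding="utf-8")
        close = True
    try:
        writer = csv.writer(destination)
        writer.writerow(TRANSITION_COLUMNS)
        for row in rows:
            writer.writerow(
                (
                    _format_score(row.combined_score),
                    row.protein_a_peptide,
                    row.cross_linker,
                    row.protein_b_peptide,
                    row.precursor_charge,
                    f"{row.precursor_mz:.6f}",
                    row.protein_a_ion,
                    row.protein_a_ion_type,
                    row.protein_b_ion,
                    row.protein_b_ion_type,
                    row.product_charge,
                    f"{row.product_mz:.6f}",
                )
            )
    finally:
        if close:
            destination.close()


def import_transitions_csv(source: TextIO | str) -> list[TransitionRow]:
    """Re-read an exported transition CSV; export → import is the identity."""
    close = False
    if isinstance(source, str):
        source = open(source, "r", newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.reader(source)
        header = next(reader)
        if tuple(header) != TRANSITION_COLUMNS:
            raise ValueError(f"unexpected transition CSV header: {header}")
        rows: list[TransitionRow] = []
        for rec in reader:
            rows.append(
                TransitionRow(
                    combined_score=float(rec[0]) if rec[0] else None,
                    protein_a_peptide=rec[1],
                    cross_linker=rec[2],
                    protein_b_peptide=rec[3],
                    precursor_charge=int(rec[4]),
                    precursor_mz=float(rec[5]),
                    protein_a_ion=rec[6],
                    protein_a_ion_type=rec[7],
                    protein_b_ion=rec[8],
                    protein_b_ion_type=rec[9],
                    product_charge=int(rec[10]),
                    product_mz=float(rec[11]),
                )
            )
        return rows
    finally:
        if close:
            source.close()


def export_interactors_csv(
    interactors: Iterable[Interactor], destination: TextIO | str
) -> None:
    """Write the ranked interactor table (rank, label, score, tier)."""
    close = False
    if isinstance(destination, str):
        destination = open(destination, "w", newline="", encoding="utf-8")
        close = True
    try:
        writer = csv.writer(destination)
        writer.writerow(INTERACTOR_COLUMNS)
        for it in interactors:
            writer.writerow((it.rank, it.label, f"{it.combined_score:g}", it.tier))
    finally:
        if close:
            destination.close()


def export_transitions_text(rows: Iterable[TransitionRow]) -> str:
    """Transition CSV as a string (convenience for tests and logging)."""
    buf = io.StringIO()
    export_transitions_csv(rows, buf)
    return buf.getvalue()
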