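"""Monoisotopic mass bookkeeping.

Residue masses, peptide neutral mass, static/variable modifications with
combinatorial expansion, and m/z conversion. All masses are monoisotopic —
SRM/PRM transition lists are built from monoisotopic values.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .digestion import Peptide
from .errors import ParseError, XLTransitError

# Monoisotopic residue masses in Da for the 20 standard amino acids,
# IUPAC 1997 element masses as tabulated by Unimod/ExPASy.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841392,
    "T": 101.04767847,
    "C": 103.00918448,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048509,
    "H": 137.05891186,
    "F": 147.06841392,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

WATER_MASS = 18.0105646863  # H2O, monoisotopic
PROTON_MASS = 1.00727646688  # mass of H+

STANDARD_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASSES)


@dataclass(frozen=True)
class Modification:
    """A mass modification applied to specific residues.

    ``static`` modifications are applied to every eligible site
    unconditionally; ``variable`` modifications are expanded into
    with/without forms over all site subsets.
    """

    name: str
    targets: frozenset[str]
    delta_mass: float
    mode: str  # "static" | "variable"

    def __post_init__(self) -> None:
        if self.mode not in ("static", "variable"):
            raise XLTransitError(
                f"modification {self.name!r}: mode must be 'static' or "
                f"'variable', got {self.mode!r}"
            )
        bad = set(self.targets) - STANDARD_RESIDUES
        if bad:
            raise XLTransitError(
                f"modification {self.name!r} targets non-standard residues "
                f"{sorted(bad)}"
            )


#: The two modifications the tool ships by default: carbamidomethylation of
#: cysteine (static, iodoacetamide alkylation) and methionine oxidation
#: (variable) — the most commonly encountered pair in shotgun proteomics.
CARBAMIDOMETHYL = Modification(
    name="carbamidomethyl", targets=frozenset("C"), delta_mass=57.02146372, mode="static"
)
OXIDATION = Modification(
    name="oxidation", targets=frozenset("M"), delta_mass=15.99491462, mode="variable"
)
DEFAULT_MODIFICATIONS: dict[str, Modification] = {
    "carbamidomethyl": CARBAMIDOMETHYL,
    "oxidation": OXIDATION,
}


@dataclass(frozen=True)
class ModForm:
    """A peptide together with a concrete set of applied modifications.

    ``applied`` holds ``(site, modification)`` pairs with 1-based sites into
    the peptide sequence, sorted by site. ``neutral_mass`` is the peptide's
    monoisotopic neutral mass including all applied deltas.
    """

    peptide: Peptide
    applied: tuple[tuple[int, Modification], ...]
    neutral_mass: float

    @property
    def sequence(self) -> str:
        return self.peptide.sequence


def peptide_neutral_mass(sequence: str, applied: Iterable[float] = ()) -> float:
    """Monoisotopic neutral mass: sum of residue masses + water + mod deltas.

    Parameters
    ----------
    sequence
        Peptide sequence over the 20 standard residues.
    applied
        Mass deltas of the modifications carried by this form.
    """
    try:
        total = sum(MONOISOTOPIC_RESIDUE_MASSES[aa] for aa in sequence)
    except KeyError as exc:
        raise XLTransitError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None
    return total + WATER_MASS + sum(applied)


def mz(neutral_mass: float, z: int) -> float:
    """m/z of an ion with ``z`` protons: (M + z * proton) / z."""
    if z < 1:
        raise XLTransitError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON_MASS) / z


def enumerate_modforms(
    peptide: Peptide,
    static_mods: Sequence[Modification] = (),
    variable_mods: Sequence[Modification] = (),
    cap: int = 1024,
) -> list[ModForm]:
    """Expand a peptide into all modification forms.

    Static modifications are applied at every eligible site unconditionally.
    Variable modifications generate one form per subset of eligible sites
    (2^k forms for k sites). Forms are ordered unmodified-first, then by the
    variable-site index tuple, which is deterministic.

    Raises an error when the variable expansion would exceed ``cap`` forms.
    """
    seq = peptide.sequence
    static_applied: list[tuple[int, Modification]] = []
    for mod in static_mods:
        for i, aa in enumerate(seq, start=1):
            if aa in mod.targets:
                static_applied.append((i, mod))

    var_sites: list[tuple[int, Modification]] = []
    for mod in variable_mods:
        for i, aa in enumerate(seq, start=1):
            if aa in mod.targets:
                var_sites.append((i, mod))
    var_sites.sort(key=lambda sm: sm[0])

    k = len(var_sites)
    if 2**k > cap:
        raise XLTransitError(
            f"variable-modification expansion of {seq!r} would produce 2^{k} "
            f"forms, above the cap of {cap}"
        )

    forms: list[ModForm] = []
    for r in range(k + 1):
        for subset in combinations(var_sites, r):
            applied = tuple(sorted(static_applied + list(subset), key=lambda sm: sm[0]))
            mass = peptide_neutral_mass(seq, (m.delta_mass for _, m in applied))
            forms.append(ModForm(peptide=peptide, applied=applied, neutral_mass=mass))
    return forms


def load_modifications_csv(stream: io.TextIOBase | Iterable[str]) -> list[Modification]:
    """Read user modification definitions from CSV.

    Columns: ``name,targets,delta_mass,mode`` where ``targets`` is a string of
    residue letters (e.g. ``"STY"``) and mode is ``static`` or ``variable``.
    Lines starting with ``#`` are comments.
    """
    mods: list[Modification] = []
    rows = csv.reader(line for line in stream if not line.lstrip().startswith("#"))
    header_seen = False
    for lineno, row in enumerate(rows, start=1):
        if not row:
            continue
        if not header_seen and row[0].strip().lower() == "name":
            header_seen = True
            continue
        if len(row) != 4:
            raise ParseError(
                f"modification CSV row {lineno}: expected 4 columns, got {len(row)}"
            )
        name, targets, delta, mode = (c.strip() for c in row)
        try:
            delta_mass = float(delta)
        except ValueError:
            raise ParseError(
                f"modification CSV row {lineno}: bad delta_mass {delta!r}"
            ) from None
        mods.append(
            Modification(
                name=name,
                targets=frozenset(targets),
                delta_mass=delta_mass,
                mode=mode.lower(),
            )
        )
    return mods
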