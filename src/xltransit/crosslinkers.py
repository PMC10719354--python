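"""Cross-linker catalog and reactive-site location.

A cross-linker is described by five attributes: its reactive specificity per
side, spacer arm length, cleavability, intact mass delta, and — for
MS-cleavable reagents — the remnant mass pairs its gas-phase cleavage leaves
on the two peptides. Conservation (each remnant pair sums to the intact
delta) is validated at catalog load so every downstream fragment mass is
consistent by construction.

The bundled catalog ships a representative subset spanning
cleavable/non-cleavable, symmetric/asymmetric and zero-length chemistry;
user catalogs in the same CSV schema are merged over it by name.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, TextIO

from .digestion import Peptide
from .errors import ParseError, XLTransitError

#: Tolerance for the remnant-pair conservation check at catalog load.
CONSERVATION_TOL = 1e-3

_ANY_RESIDUE = frozenset("GASPVTCLINDQKEMHFRYW")


@dataclass(frozen=True)
class CrossLinker:
    """One catalog entry; ``remnant_pairs`` holds ``(delta_on_A, delta_on_B)``
    tuples produced by gas-phase cleavage (empty for non-cleavable)."""

    name: str
    site_a_targets: frozenset[str]
    site_b_targets: frozenset[str]
    nterm_reactive_a: bool
    nterm_reactive_b: bool
    spacer_arm: float
    cleavable: bool
    intact_delta: float
    remnant_pairs: tuple[tuple[float, float], ...]

    @property
    def symmetric(self) -> bool:
        """True when every remnant pair leaves equal masses on both sides."""
        return bool(self.remnant_pairs) and all(
            abs(a - b) < 1e-9 for a, b in self.remnant_pairs
        )

    def targets(self, side: str) -> frozenset[str]:
        if side == "A":
            return self.site_a_targets
        if side == "B":
            return self.site_b_targets
        raise XLTransitError(f"linker side must be 'A' or 'B', got {side!r}")

    def nterm_reactive(self, side: str) -> bool:
        return self.nterm_reactive_a if side == "A" else self.nterm_reactive_b


@dataclass(frozen=True)
class LinkSite:
    """A linker attachment point on a peptide: 1-based residue position, or
    position 0 for the protein N-terminal alpha-amine."""

    peptide: Peptide
    position: int
    residue: str  # "^" for the N-terminus pseudo-site


def _parse_targets(token: str) -> frozenset[str]:
    token = token.strip()
    if token == "*":
        return _ANY_RESIDUE
    targets = frozenset(token.upper())
    bad = targets - _ANY_RESIDUE
    if bad:
        raise ParseError(f"linker target set {token!r}: non-standard residues {sorted(bad)}")
    return targets


def load_linker_catalog(stream: TextIO | str) -> list[CrossLinker]:
    """Read a linker catalog CSV and validate the conservation invariant.

    Schema: ``name,site_a,site_b,nterm_reactive,spacer_arm_A,cleavable,
    intact_delta,remnant_pairs`` with remnant pairs encoded ``a1:b1;a2:b2``.
    ``#`` lines are comments; a header row is required.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows = csv.reader(line for line in stream if not line.lstrip().startswith("#"))
    linkers: list[CrossLinker] = []
    header_seen = False
    for row in rows:
        if not row or not any(c.strip() for c in row):
            continue
        if not header_seen:
            if [c.strip().lower() for c in row[:2]] != ["name", "site_a"]:
                raise ParseError("linker catalog: missing header row")
            header_seen = True
            continue
        if len(row) != 8:
            raise ParseError(
                f"linker catalog row {row[:1]}: expected 8 columns, got {len(row)}"
            )
        name, site_a, site_b, nterm, spacer, cleavable, intact, pairs_raw = (
            c.strip() for c in row
        )
        cleavable_flag = cleavable.lower() in ("true", "yes", "1")
        intact_delta = float(intact)
        pairs: list[tuple[float, float]] = []
        if pairs_raw:
            for token in pairs_raw.split(";"):
                a_str, _, b_str = token.partition(":")
                pair = (float(a_str), float(b_str))
                if abs(pair[0] + pair[1] - intact_delta) > CONSERVATION_TOL:
                    raise ParseError(
                        f"linker {name!r}: remnant pair {pair} sums to "
                        f"{pair[0] + pair[1]:.6f}, not the intact delta "
                        f"{intact_delta:.6f}"
                    )
                pairs.append(pair)
        if cleavable_flag and not pairs:
            raise ParseError(f"linker {name!r}: cleavable but no remnant pairs")
        if not cleavable_flag and pairs:
            raise ParseError(f"linker {name!r}: non-cleavable but has remnant pairs")
        nterm_tokens = set(nterm.upper())
        linkers.append(
            CrossLinker(
                name=name,
                site_a_targets=_parse_targets(site_a),
                site_b_targets=_parse_targets(site_b),
                nterm_reactive_a="A" in nterm_tokens,
                nterm_reactive_b="B" in nterm_tokens,
                spacer_arm=float(spacer),
                cleavable=cleavable_flag,
                intact_delta=intact_delta,
                remnant_pairs=tuple(pairs),
            )
        )
    return linkers


def bundled_catalog() -> list[CrossLinker]:
    """The catalog shipped with the package (DSSO, DSBU, DSS, BS3,
    sulfo-SDA, EDC)."""
    text = resources.files("xltransit.data").joinpath("linkers.csv").read_text()
    return load_linker_catalog(text)


def merge_catalogs(
    base: Iterable[CrossLinker], overrides: Iterable[CrossLinker]
) -> list[CrossLinker]:
    """Merge a user catalog over a base catalog by linker name."""
    merged = {linker.name: linker for linker in base}
    for linker in overrides:
        merged[linker.name] = linker
    return list(merged.values())


def get_linker(catalog: Iterable[CrossLinker], name: str) -> CrossLinker:
    by_name = {linker.name.lower(): linker for linker in catalog}
    try:
        return by_name[name.lower()]
    except KeyError:
        raise XLTransitError(
            f"unknown cross-linker {name!r}; valid names: "
            f"{sorted(l.name for l in by_name.values())}"
        ) from None


def linkable_sites(
    peptide: Peptide,
    linker: CrossLinker,
    side: str,
    allow_cleaved_cterm: bool = False,
) -> list[LinkSite]:
    """Locate the positions on a peptide where one linker side can react.

    Every residue in the side's target set is a site, except the C-terminal
    residue when that terminus was produced by enzymatic cleavage: a
    conjugated lysine blocks trypsin, so a cleaved site cannot also carry the
    linker (set ``allow_cleaved_cterm=True`` to disable the exclusion). The
    protein N-terminal alpha-amine is an additional site (position 0) when
    the linker side is amine-reactive and the peptide starts the protein.
    """
    targets = linker.targets(side)
    sites: list[LinkSite] = []
    if linker.nterm_reactive(side) and peptide.is_protein_nterm:
        sites.append(LinkSite(peptide=peptide, position=0, residue="^"))
    last = len(peptide.sequence)
    for i, aa in enumerate(peptide.sequence, start=1):
        if aa not in targets:
            continue
        if i == last and not peptide.is_protein_cterm and not allow_cleaved_cterm:
            continue
        sites.append(LinkSite(peptide=peptide, position=i, residue=aa))
    return sites
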