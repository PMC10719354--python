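"""Cross-link product enumeration and fragment-ion generation.

A cross-linking reaction between a target (protein A) and an interactor
(protein B) yields four product classes at the peptide level:

1. inter-link — two peptides joined through the linker;
2. loop-link on A — both linker ends on one A peptide;
3. loop-link on B — both linker ends on one B peptide;
4. mono-link (dead-end) — one end reacted, the other hydrolyzed.

Precursor neutral masses follow directly: inter-links add the intact linker
delta to the sum of both peptide masses, loop-links add it to one peptide,
and mono-links add the intact delta plus water (the hydrolyzed free end).

Fragments are b/y series (the CID/HCD convention targeted SRM assays use).
A fragment whose residue span covers a linked site carries linker mass: for
MS-cleavable linkers one variant per remnant assignment (both orientations
for asymmetric remnant pairs), for non-cleavable linkers the intact delta
plus — for inter-links — the entire partner peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem_masses import (
    MONOISOTOPIC_RESIDUE_MASSES,
    WATER_MASS,
    ModForm,
    mz,
)
from .crosslinkers import CrossLinker, LinkSite, linkable_sites
from .errors import XLTransitError

PRODUCT_KINDS = ("inter_link", "loop_link_A", "loop_link_B", "mono_link")


@dataclass(frozen=True)
class LinkProduct:
    """One enumerated cross-linked species at one precursor charge.

    ``alpha`` is the peptide form from protein A, ``beta`` from protein B;
    loop- and mono-links involve a single peptide so exactly one of the two
    is set. ``sites`` holds one LinkSite (mono), two on one peptide (loop),
    or one per peptide (inter, alpha's first).
    """

    kind: str
    alpha: ModForm | None
    beta: ModForm | None
    sites: tuple[LinkSite, ...]
    linker: CrossLinker
    neutral_mass: float
    precursor_charge: int
    precursor_mz: float


@dataclass(frozen=True)
class FragmentIon:
    """One b/y fragment of a link product at one charge.

    ``remnant_delta`` is the linker-derived mass the fragment carries beyond
    its bare peptide mass (0 when the fragment does not span a linked site).
    """

    parent: LinkProduct
    series: str  # "b" | "y"
    index: int
    of_peptide: str  # "alpha" | "beta"
    carries_link: bool
    remnant_delta: float
    charge: int
    mz: float
    ion_label: str


def _modform_key(form: ModForm | None) -> tuple:
    if form is None:
        return ("",)
    p = form.peptide
    return (
        p.parent_accession,
        p.start,
        p.end,
        tuple((site, mod.name) for site, mod in form.applied),
    )


def _product_key(product: LinkProduct) -> tuple:
    return (
        PRODUCT_KINDS.index(product.kind),
        _modform_key(product.alpha),
        _modform_key(product.beta),
        tuple(s.position for s in product.sites),
        product.precursor_charge,
    )


def enumerate_link_products(
    peps_a: Sequence[ModForm],
    peps_b: Sequence[ModForm],
    linker: CrossLinker,
    precursor_charges: Iterable[int],
    include_homodimers: bool = False,
    a_side_products: bool = True,
    b_side_products: bool = True,
    allow_cleaved_cterm: bool = False,
) -> list[LinkProduct]:
    """Enumerate every link product over two peptide universes.

    Inter-links are formed over all (A-side site × B-side site) pairs;
    loop-links over same-peptide site pairs with distinct positions;
    mono-links at every reactive site (deduplicated by position over the two
    linker sides). Each species is crossed with every requested precursor
    charge. ``include_homodimers`` additionally emits A–A and B–B
    inter-links. ``a_side_products``/``b_side_products`` gate the loop- and
    mono-links of the respective protein so a pipeline can enumerate shared
    target-only products once.

    An empty site universe yields an empty list, not an error.
    """
    charges = sorted(set(precursor_charges))
    if any(z < 1 for z in charges):
        raise XLTransitError("precursor charges must be >= 1")

    def sites_of(form: ModForm, side: str) -> list[LinkSite]:
        return linkable_sites(
            form.peptide, linker, side, allow_cleaved_cterm=allow_cleaved_cterm
        )

    products: list[LinkProduct] = []

    def add(kind: str, alpha, beta, sites, neutral: float) -> None:
        for z in charges:
            products.append(
                LinkProduct(
                    kind=kind,
                    alpha=alpha,
                    beta=beta,
                    sites=tuple(sites),
                    linker=linker,
                    neutral_mass=neutral,
                    precursor_charge=z,
                    precursor_mz=mz(neutral, z),
                )
            )

    def inter_pairs(forms_x, forms_y, same_universe: bool):
        for i, fa in enumerate(forms_x):
            sa_list = sites_of(fa, "A")
            if not sa_list:
                continue
            start_j = i if same_universe else 0
            for j in range(start_j, len(forms_y)):
                fb = forms_y[j]
                sb_list = sites_of(fb, "B")
                for sa in sa_list:
                    for sb in sb_list:
                        neutral = fa.neutral_mass + fb.neutral_mass + linker.intact_delta
                        add("inter_link", fa, fb, (sa, sb), neutral)

    inter_pairs(list(peps_a), list(peps_b), same_universe=False)
    if include_homodimers:
        inter_pairs(list(peps_a), list(peps_a), same_universe=True)
        inter_pairs(list(peps_b), list(peps_b), same_universe=True)

    def loops_and_monos(forms: Sequence[ModForm], kind_loop: str, role: str) -> None:
        for form in forms:
            sa_list = sites_of(form, "A")
            sb_list = sites_of(form, "B")
            symmetric_sides = linker.site_a_targets == linker.site_b_targets and (
                linker.nterm_reactive_a == linker.nterm_reactive_b
            )
            for sa in sa_list:
                for sb in sb_list:
                    if sa.position == sb.position:
                        continue
                    if symmetric_sides and sa.position > sb.position:
                        continue  # mirror duplicate for homobifunctional linkers
                    neutral = form.neutral_mass + linker.intact_delta
                    alpha = form if role == "alpha" else None
                    beta = form if role == "beta" else None
                    add(kind_loop, alpha, beta, (sa, sb), neutral)
            mono_positions = {}
            for site in sa_list + sb_list:
                mono_positions.setdefault(site.position, site)
            for pos in sorted(mono_positions):
                neutral = form.neutral_mass + linker.intact_delta + WATER_MASS
                alpha = form if role == "alpha" else None
                beta = form if role == "beta" else None
                add("mono_link", alpha, beta, (mono_positions[pos],), neutral)

    if a_side_products:
        loops_and_monos(list(peps_a), "loop_link_A", "alpha")
    if b_side_products:
        loops_and_monos(list(peps_b), "loop_link_B", "beta")

    products.sort(key=_product_key)
    return products


def _bare_fragment_masses(form: ModForm) -> tuple[list[float], list[float]]:
    """Neutral b_1..b_{n-1} and y_1..y_{n-1} masses of a peptide form,
    including any applied modification deltas within the fragment span."""
    seq = form.sequence
    n = len(seq)
    deltas = [0.0] * (n + 1)
    for site, mod in form.applied:
        deltas[site] += mod.delta_mass
    prefix = [0.0]
    for i, aa in enumerate(seq, start=1):
        prefix.append(prefix[-1] + MONOISOTOPIC_RESIDUE_MASSES[aa] + deltas[i])
    total = prefix[n]
    b_masses = [prefix[i] for i in range(1, n)]
    y_masses = [total - prefix[n - i] + WATER_MASS for i in range(1, n)]
    return b_masses, y_masses


def _span_contains(series: str, index: int, n: int, position: int) -> bool:
    """Whether fragment ``series``/``index`` of an n-residue peptide covers a
    linked site (position 0 = N-terminal alpha-amine, covered by b ions)."""
    if series == "b":
        return position <= index
    return position >= n - index + 1 and position > 0


def _remnant_variants(linker: CrossLinker) -> list[float]:
    """Distinct remnant deltas a link-spanning fragment can carry after
    gas-phase cleavage: one per symmetric pair, both orientations per
    asymmetric pair."""
    variants: list[float] = []
    for a, b in linker.remnant_pairs:
        if abs(a - b) < 1e-9:
            variants.append(a)
        else:
            variants.extend((a, b))
    seen: list[float] = []
    for v in variants:
        if not any(abs(v - s) < 1e-9 for s in seen):
            seen.append(v)
    return seen


def fragment_ions(
    product: LinkProduct, product_charges: Iterable[int]
) -> list[FragmentIon]:
    """Generate b/y fragments of a link product at the requested charges.

    Fragments not spanning a linked site carry bare peptide masses. For
    link-spanning fragments:

    * cleavable inter-link — one variant per remnant assignment (both
      orientations for asymmetric pairs; their remnants sum to the intact
      delta);
    * non-cleavable inter-link — the intact delta plus the full partner
      peptide;
    * loop-link — fragments spanning both sites carry the intact delta;
      fragments spanning exactly one site are suppressed (the ring keeps the
      two backbone halves attached);
    * mono-link — the intact delta plus water (the hydrolyzed end).
    """
    charges = sorted(set(product_charges))
    if any(z < 1 for z in charges):
        raise XLTransitError("product charges must be >= 1")
    linker = product.linker
    ions: list[FragmentIon] = []

    roles: list[tuple[str, ModForm, list[LinkSite], ModForm | None]] = []
    if product.kind == "inter_link":
        assert product.alpha is not None and product.beta is not None
        roles.append(("alpha", product.alpha, [product.sites[0]], product.beta))
        roles.append(("beta", product.beta, [product.sites[1]], product.alpha))
    else:
        form = product.alpha if product.alpha is not None else product.beta
        role = "alpha" if product.alpha is not None else "beta"
        assert form is not None
        roles.append((role, form, list(product.sites), None))

    for role, form, sites, partner in roles:
        n = len(form.sequence)
        b_masses, y_masses = _bare_fragment_masses(form)
        for series, masses in (("b", b_masses), ("y", y_masses)):
            for index, bare in enumerate(masses, start=1):
                covered = [
                    s for s in sites if _span_contains(series, index, n, s.position)
                ]
                if product.kind in ("loop_link_A", "loop_link_B") and len(covered) == 1:
                    continue  # ring cannot be opened by backbone cleavage alone
                if not covered:
                    extra_variants = [0.0]
                elif product.kind == "inter_link":
                    if linker.cleavable:
                        extra_variants = _remnant_variants(linker)
                    else:
                        assert partner is not None
                        extra_variants = [linker.intact_delta + partner.neutral_mass]
                elif product.kind == "mono_link":
                    extra_variants = [linker.intact_delta + WATER_MASS]
                else:  # loop-link spanning both sites
                    extra_variants = [linker.intact_delta]
                for extra in extra_variants:
                    for z in charges:
                        neutral = bare + extra
                        ions.append(
                            FragmentIon(
                                parent=product,
                                series=series,
                                index=index,
                                of_peptide=role,
                                carries_link=bool(covered),
                                remnant_delta=extra if covered else 0.0,
                                charge=z,
                                mz=mz(neutral, z),
                                ion_label=f"{series}{index}",
                            )
                        )

    ions.sort(
        key=lambda f: (
            f.of_peptide,
            f.series,
            f.index,
            f.remnant_delta,
            f.charge,
        )
    )
    return ions
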