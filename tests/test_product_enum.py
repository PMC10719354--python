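"""Product enumeration and fragment generation: the four product classes,
remnant handling, and mass conservation."""

import random

import pytest

from xltransit import (
    ModForm,
    Peptide,
    WATER_MASS,
    bundled_catalog,
    enumerate_link_products,
    enumerate_modforms,
    fragment_ions,
    get_linker,
    linkable_sites,
    load_linker_catalog,
    peptide_neutral_mass,
)

DSSO = get_linker(bundled_catalog(), "DSSO")
DSS = get_linker(bundled_catalog(), "DSS")

SYMMETRIC = load_linker_catalog(
    "name,site_a,site_b,nterm_reactive,spacer_arm_A,cleavable,intact_delta,remnant_pairs\n"
    "SYMTEST,K,K,AB,10.0,true,100.0,50.0:50.0\n"
)[0]


def form(sequence: str, accession="P00001", is_cterm=True) -> ModForm:
    pep = Peptide(accession, sequence, 1, len(sequence), 0, False, is_cterm)
    return ModForm(pep, (), peptide_neutral_mass(sequence))


# one internal K each -> 1 inter-link, no loops, 1 mono each
ONE_SITE_A = form("PEPKIDE", "P00001")
ONE_SITE_B = form("GGKAGGE", "Q00001")
# two K sites each -> all four kinds
TWO_SITE_A = form("PEKPKIDE", "P00001")
TWO_SITE_B = form("GGKAKGGE", "Q00001")


class TestEnumerate:
    def test_one_site_each_gives_inter_and_monos_only(self):
        products = enumerate_link_products([ONE_SITE_A], [ONE_SITE_B], DSSO, {2})
        kinds = [p.kind for p in products]
        assert kinds.count("inter_link") == 1
        assert kinds.count("mono_link") == 2
        assert not any(k.startswith("loop") for k in kinds)

    def test_two_sites_each_realizes_all_four_kinds(self):
        products = enumerate_link_products([TWO_SITE_A], [TWO_SITE_B], DSSO, {2})
        assert {p.kind for p in products} == {
            "inter_link",
            "loop_link_A",
            "loop_link_B",
            "mono_link",
        }

    def test_inter_link_neutral_mass_arithmetic(self):
        (inter,) = [
            p
            for p in enumerate_link_products([ONE_SITE_A], [ONE_SITE_B], DSSO, {2})
            if p.kind == "inter_link"
        ]
        expected = (
            ONE_SITE_A.neutral_mass + ONE_SITE_B.neutral_mass + 158.003765
        )
        assert inter.neutral_mass == pytest.approx(expected, abs=1e-5)

    def test_loop_and_mono_neutral_masses(self):
        products = enumerate_link_products([TWO_SITE_A], [], DSSO, {2})
        loop = next(p for p in products if p.kind == "loop_link_A")
        mono = next(p for p in products if p.kind == "mono_link")
        assert loop.neutral_mass == pytest.approx(
            TWO_SITE_A.neutral_mass + DSSO.intact_delta, abs=1e-6
        )
        assert mono.neutral_mass == pytest.approx(
            TWO_SITE_A.neutral_mass + DSSO.intact_delta + WATER_MASS, abs=1e-6
        )

    def test_empty_site_universe_gives_empty_output(self):
        no_sites = form("PEPTIDE")
        assert enumerate_link_products([no_sites], [no_sites], DSSO, {2}) == []

    def test_counts_match_brute_force_oracle(self):
        """Product counts on random universes equal a direct enumeration over
        every (peptide, site-combination, kind, charge) tuple."""
        rng = random.Random(3)
        charges = {2, 3}
        for _ in range(20):
            def universe(tag):
                forms = []
                for i in range(rng.randint(0, 4)):
                    seq = "".join(
                        rng.choice("GAKPLVE") for _ in range(rng.randint(2, 9))
                    )
                    forms.append(form(seq, f"{tag}{i:05d}"))
                return forms

            peps_a, peps_b = universe("P0000"), universe("Q0000")
            products = enumerate_link_products(peps_a, peps_b, DSSO, charges)

            def nsites(f):
                return len(linkable_sites(f.peptide, DSSO, "A"))

            inter = sum(
                nsites(fa) * nsites(fb) for fa in peps_a for fb in peps_b
            )
            loops = sum(
                n * (n - 1) // 2 for n in map(nsites, peps_a + peps_b)
            )
            monos = sum(map(nsites, peps_a + peps_b))
            expected = (inter + loops + monos) * len(charges)
            assert len(products) == expected

    def test_each_species_crossed_with_every_precursor_charge(self):
        products = enumerate_link_products([ONE_SITE_A], [ONE_SITE_B], DSSO, {2, 3})
        inters = [p for p in products if p.kind == "inter_link"]
        assert sorted(p.precursor_charge for p in inters) == [2, 3]
        m2, m3 = sorted(inters, key=lambda p: p.precursor_charge)
        assert m2.precursor_mz > m3.precursor_mz  # m/z decreases with charge
        assert all(p.precursor_mz > 0 for p in products)

    def test_homodimer_flag_adds_within_universe_links(self):
        base = enumerate_link_products([ONE_SITE_A], [], DSSO, {2})
        with_dimers = enumerate_link_products(
            [ONE_SITE_A], [], DSSO, {2}, include_homodimers=True
        )
        assert not any(p.kind == "inter_link" for p in base)
        dimers = [p for p in with_dimers if p.kind == "inter_link"]
        assert len(dimers) == 1  # A x A self-pair, one site each side


class TestFragments:
    def test_b_y_complementarity_on_bare_fragments(self):
        for sequence in ("PEPKIDE", "GGKAGGEACDLMNQSTVWHF"[:20], "AK"):
            f = form(sequence)
            (mono,) = [
                p
                for p in enumerate_link_products([f], [], DSSO, {2})
                if p.kind == "mono_link"
            ] or [None]
            if mono is None:
                continue
            ions = fragment_ions(mono, {1})
            bare = {
                (i.series, i.index): i.mz * i.charge - i.charge * 1.00727646688
                for i in ions
                if not i.carries_link
            }
            n = len(sequence)
            for (series, index), neutral in bare.items():
                partner = bare.get(("y" if series == "b" else "b", n - index))
                if partner is not None:
                    assert neutral + partner == pytest.approx(
                        peptide_neutral_mass(sequence), abs=1e-6
                    )

    def test_dsso_link_spanning_fragment_has_two_remnant_variants(self):
        (inter,) = [
            p
            for p in enumerate_link_products([ONE_SITE_A], [ONE_SITE_B], DSSO, {2})
            if p.kind == "inter_link"
        ]
        ions = fragment_ions(inter, {1})
        # y4 of alpha PEPKIDE spans the linked K at position 4
        variants = [
            i for i in ions if i.of_peptide == "alpha" and i.ion_label == "y4"
        ]
        assert len(variants) == 2
        deltas = sorted(i.remnant_delta for i in variants)
        assert deltas[0] == pytest.approx(54.010565, abs=1e-5)
        assert deltas[1] == pytest.approx(103.993200, abs=1e-5)
        assert sum(deltas) == pytest.approx(158.003765, abs=1e-6)

    def test_cleavable_conservation_to_precursor_mass(self):
        """For any remnant orientation, (alpha + its remnant) + (beta + its
        remnant) equals the precursor neutral mass to 1e-6 Da."""
        for linker in (DSSO, SYMMETRIC):
            (inter,) = [
                p
                for p in enumerate_link_products(
                    [ONE_SITE_A], [ONE_SITE_B], linker, {2}
                )
                if p.kind == "inter_link"
            ]
            for delta_a, delta_b in linker.remnant_pairs:
                total = (
                    inter.alpha.neutral_mass
                    + delta_a
                    + inter.beta.neutral_mass
                    + delta_b
                )
                assert total == pytest.approx(inter.neutral_mass, abs=1e-6)

    def test_symmetric_linker_gives_single_remnant_variant(self):
        (inter,) = [
            p
            for p in enumerate_link_products([ONE_SITE_A], [ONE_SITE_B], SYMMETRIC, {2})
            if p.kind == "inter_link"
        ]
        ions = fragment_ions(inter, {1})
        variants = [
            i for i in ions if i.of_peptide == "alpha" and i.ion_label == "y4"
        ]
        assert len(variants) == 1
        assert variants[0].remnant_delta == pytest.approx(50.0)

    def test_noncleavable_fragment_carries_intact_plus_partner(self):
        (inter,) = [
            p
            for p in enumerate_link_products([ONE_SITE_A], [ONE_SITE_B], DSS, {2})
            if p.kind == "inter_link"
        ]
        ions = fragment_ions(inter, {1})
        (y4,) = [i for i in ions if i.of_peptide == "alpha" and i.ion_label == "y4"]
        assert y4.remnant_delta == pytest.approx(
            DSS.intact_delta + inter.beta.neutral_mass, abs=1e-6
        )

    def test_loop_fragments_spanning_one_site_suppressed(self):
        (loop,) = [
            p
            for p in enumerate_link_products([TWO_SITE_A], [], DSSO, {2})
            if p.kind == "loop_link_A"
        ]
        p1, p2 = sorted(s.position for s in loop.sites)  # K3 and K5 of PEKPKIDE
        n = len(loop.alpha.sequence)
        ions = fragment_ions(loop, {1})
        labels = {i.ion_label for i in ions}
        for index in range(1, n):
            covers_b = sum(pos <= index for pos in (p1, p2))
            assert (f"b{index}" in labels) == (covers_b != 1)
            covers_y = sum(pos >= n - index + 1 for pos in (p1, p2))
            assert (f"y{index}" in labels) == (covers_y != 1)
        both = [i for i in ions if i.carries_link]
        assert both and all(
            i.remnant_delta == pytest.approx(DSSO.intact_delta) for i in both
        )

    def test_mono_link_fragment_carries_hydrolyzed_linker(self):
        products = enumerate_link_products([ONE_SITE_A], [], DSSO, {2})
        mono = next(p for p in products if p.kind == "mono_link")
        ions = fragment_ions(mono, {1, 2})
        linked = [i for i in ions if i.carries_link]
        assert linked and all(
            i.remnant_delta == pytest.approx(DSSO.intact_delta + WATER_MASS, abs=1e-6)
            for i in linked
        )
        assert all(i.mz > 0 for i in ions)
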