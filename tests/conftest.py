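"""Shared fixtures and independent oracles.

The oracle functions here deliberately re-derive expected values by brute
force or from elemental composition (via pyteomics), independently of the
implementation paths they check.
"""

from __future__ import annotations

import pytest

from xltransit import SearchConfig, apoe_fixture

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_digest(sequence: str, cleave_after: set, exception_next: set,
                       max_missed: int) -> set[tuple[int, int]]:
    """Enumerate every (start, end) window (1-based inclusive) whose ends are
    valid boundaries and whose internal cleavage sites number <= max_missed,
    applying the cleave/exception rule at every position directly."""
    n = len(sequence)
    sites = {
        i
        for i in range(1, n)
        if sequence[i - 1] in cleave_after and sequence[i] not in exception_next
    }
    boundaries = {0} | sites | {n}
    windows = set()
    for start in sorted(boundaries - {n}):
        for end in sorted(boundaries - {0}):
            if end <= start:
                continue
            internal = {s for s in sites if start < s < end}
            if len(internal) <= max_missed:
                windows.add((start + 1, end))
    return windows


def brute_force_link_sites(sequence: str, targets: set, is_protein_nterm: bool,
                           is_protein_cterm: bool, nterm_reactive: bool) -> set[int]:
    """Scan every position directly for linker-site eligibility."""
    positions = set()
    if nterm_reactive and is_protein_nterm:
        positions.add(0)
    for i, aa in enumerate(sequence, start=1):
        if aa in targets and (i < len(sequence) or is_protein_cterm):
            positions.add(i)
    return positions


def composition_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula (pyteomics oracle)."""
    from pyteomics.mass import calculate_mass

    return calculate_mass(formula=formula)


def sequence_mass_oracle(sequence: str) -> float:
    """Monoisotopic neutral peptide mass from pyteomics' own residue
    compositions — independent of the package's hard-coded table."""
    from pyteomics.mass import calculate_mass

    return calculate_mass(sequence=sequence)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def apoe_bundle():
    return apoe_fixture()


@pytest.fixture(scope="session")
def apoe_paths(tmp_path_factory, apoe_bundle):
    return apoe_bundle.write_to(tmp_path_factory.mktemp("apoe"))


@pytest.fixture(scope="session")
def worked_config(apoe_paths, tmp_path_factory):
    """The published worked-example configuration: APOE target, trypsin,
    DSSO, top 10, peptide length 9, precursor charges 2+3, product charges
    1+2, carbamidomethyl static + oxidation variable."""
    out = tmp_path_factory.mktemp("out")
    return SearchConfig(
        target_accession="P02649",
        enzyme="trypsin",
        linker="DSSO",
        min_len=9,
        max_len=9,
        top_n=10,
        precursor_charges=(2, 3),
        product_charges=(1, 2),
        modifications=(("carbamidomethyl", "static"), ("oxidation", "variable")),
        proteome_path=str(apoe_paths["proteome"]),
        ppi_path=str(apoe_paths["ppi"]),
        map_path=str(apoe_paths["map"]),
        output_path=str(out / "transitions.csv"),
        interactors_output_path=str(out / "interactors.csv"),
    )
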