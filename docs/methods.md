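# Methods

`xltransit` computes the theoretical inputs a targeted cross-linking MS
(XL-MS) experiment needs before any spectrum is acquired: which proteins are
plausible interactors of a target, and the exact monoisotopic m/z of every
cross-linked species and fragment those interactions could produce under a
stated digestion/linker/charge/modification regime. This note documents the
model, the defaults, and the design choices made where the design was open.

## Interactor ranking

Interactions come from a STRING-dialect table (`protein1 protein2
combined_score`, identifiers like `9606.ENSP…`). Scores in STRING files are
integers 0–999 and are divided by 1000 on load; already-normalized unit
scores are accepted with `score_scale="unit"`. Edges are undirected;
symmetric duplicates collapse to the maximum score. The target's UniProt
accession resolves to a STRING identifier through a two-column mapping TSV;
isoform accessions (dash-suffixed, e.g. `P02649-2`) resolve through their
base accession because STRING does not distinguish isoforms.

Partners are ranked by combined score descending. Ties break by partner
STRING identifier ascending, then accession — STRING identifier order is the
order STRING's own exports present equal-scored partners in, and a
deterministic rule is required for reproducible output. Tiers use the
standard STRING confidence bands with *strict* inequalities: highest
(> 0.9), high (> 0.7), medium (> 0.4), low (> 0.15), below-cutoff otherwise;
exactly at a boundary a score falls in the lower tier.

## Digestion

Fully specific digestion with Keil-style high-specificity rules: trypsin
cleaves after K/R, chymotrypsin after F/W/Y, both blocked when the next
residue is proline. Chymotrypsin is deliberately the high-specificity form
(no L/M) for determinism; `EnzymeSpec` is a plain value object, so other
specificities are one constructor call away. Missed cleavages 0..`max_missed`
are enumerated (default 2: a linker-conjugated lysine blocks trypsin, so a
linkable peptide generally *must* retain a missed cleavage). Length filtering
is a separate stage, so single-residue C-terminal peptides exist until
filtered.

## Masses and modifications

All arithmetic is monoisotopic — SRM/PRM transition lists require it.
Residue masses, water (18.0105646863 Da) and the proton (1.00727646688 Da)
are hard-coded from the standard IUPAC/Unimod table and cross-checked in the
test suite against pyteomics' elemental compositions to 1e-4 Da. Peptide
neutral mass is Σ residues + water + Σ modification deltas; m/z is
(M + z·H⁺)/z.

Two modifications ship by default: carbamidomethyl (+57.02146 Da on C,
static) and oxidation (+15.99491 Da on M, variable). Static modifications
apply to every eligible site unconditionally; variable modifications expand
over all 2^k site subsets, unmodified form first, capped at 1024 forms per
peptide (a guard against pathological inputs, not a tuning knob). Users can
load further definitions from a small CSV (`name,targets,delta,mode`).

## Cross-linkers

A linker is: per-side residue specificity (plus per-side protein-N-terminus
reactivity), spacer arm length (metadata only — no distance model is in
scope), cleavability, the intact mass delta added when both sides are
conjugated, and, for MS-cleavable linkers, remnant pairs `(delta_on_A,
delta_on_B)`. The load-time invariant `delta_on_A + delta_on_B =
intact_delta` makes fragment masses conserve by construction; a catalog row
violating it is rejected. A linker is *symmetric* when every pair has equal
members.

The bundled catalog (DSSO, DSBU, DSS, BS3, sulfo-SDA, EDC) spans
cleavable/non-cleavable, symmetric/asymmetric and zero-length chemistry; it
is a schema demonstration, not a census, and user catalogs merge over it by
name. DSSO carries its primary cleavage pair, alkene (C₃H₂O, 54.010565 Da)
and sulfenic acid (C₃H₄O₂S, 103.993200 Da); the sulfenic-acid remnant's
water-loss product (thiol, 85.98264 Da) is not bundled because it only
balances against an alkene-plus-water bookkeeping entry — users who want it
can add a row pairing 85.982635 with 72.021130.

Site location: every residue in a side's target set is a site, except the
C-terminal residue of a peptide whose C-terminus was produced by enzymatic
cleavage — in a real sample the conjugated residue would have blocked that
cleavage, so a cleaved site cannot also carry the linker
(`allow_cleaved_cterm=True` disables this). The protein N-terminal
alpha-amine is an extra site (position 0) for amine-reactive sides on
protein-N-terminal peptides.

## Product enumeration

Four product classes per target/interactor peptide pair:

| kind | composition | neutral mass |
|---|---|---|
| inter-link | peptide A + peptide B | m_A + m_B + intact |
| loop-link (A or B) | one peptide, two sites | m + intact |
| mono-link (dead-end) | one peptide, one site | m + intact + water |

The mono-link adds water for the hydrolyzed free NHS end — standard
dead-end chemistry. Loop-link site pairs need only distinct positions
(adjacent allowed; the spacer arm is not used as a geometric filter).
Homodimeric A–A/B–B inter-links are available behind
`include_homodimers=True`, default off, so the default output is the plain
A×B table. Every species is crossed with every requested precursor charge;
precursor and product charge sets come straight from configuration and may
overlap.

## Fragments

b/y series only — the CID/HCD convention targeted assays use; the series
enum is trivially extensible. Fragments not spanning a linked site carry
bare masses (with their modification deltas). Fragments spanning a site:

* cleavable inter-link: one variant per remnant assignment. Asymmetric pairs
  emit both orientations (alpha takes `delta_on_A` or `delta_on_B`, the
  partner the complement) because which peptide retains which remnant is not
  predictable in advance; symmetric pairs emit one variant. Any orientation
  conserves: (alpha + its remnant) + (beta + its remnant) = precursor mass.
* non-cleavable inter-link: the fragment carries the intact delta plus the
  entire partner peptide.
* loop-link: fragments spanning both sites carry the intact delta; fragments
  spanning exactly one site are suppressed — the ring holds the two backbone
  halves together, so a single backbone cleavage cannot release such an ion.
  This suppression is applied for cleavable linkers too: releasing those
  ions requires a backbone *and* a linker cleavage in one product ion, a
  two-event species targeted assays do not schedule.
* mono-link: the fragment carries the intact delta plus water.

## Output

The transition list has twelve fixed columns: combined score, protein A
peptide, cross linker, protein B peptide, precursor charge, precursor m/z,
protein A ion, protein A ion type, protein B ion, protein B ion type,
product charge, product m/z. Modifications are annotated as bracketed mass
deltas after the residue (`PEM[+15.99491]KIDE`) — unambiguous and accepted
by Skyline-style tools; a variable modification therefore appears as two
rows, shifted and unshifted. m/z values are written at six decimals (vendor
transition-list convention) and rows store the rounded values, so CSV
export → import is the identity. The interactor table (rank, label, score,
tier) exports separately. Target-only loop-/mono-link rows carry an empty
combined score. An optional pass-through column for externally computed
peptide-response scores can be joined downstream; the package never computes
one.

## Fixtures and what passing tests show

`apoe_fixture()` rebuilds the APOE worked example: the published top-10
interactor table (exact scores and `sp|ACC|ENTRY_NAME` labels) over an
11-protein proteome whose *sequences are synthetic stand-ins* — short
constructed sequences, one length-9 tryptic peptide each with an internal
lysine, a cysteine and a methionine, with controlled placement. Synthetic
STRING identifiers are assigned in published rank order so equal scores
reproduce the published row order. Tests passing on this fixture demonstrate
the ranking, digestion, modification and mass machinery end to end; they do
not validate m/z values for the real human proteins, whose sequences are not
bundled. `synth_proteome(n, length_range, lysine_density, seed)` draws
residues i.i.d. (K at the requested density, default 0.05 ≈ the human
proteome's lysine frequency, remaining residues uniform) — it emulates
composition, not homology, domain structure or real cleavage-site spacing.

## Numerical choices and problem sizes

Catalog conservation is enforced at 1e-3 Da on load (CSV rounding
tolerance); bundled values are written so pairs balance at 1e-6 Da, the
tolerance the conservation tests use. Mass comparisons against the
composition oracle use 1e-4 Da. Property tests run on random sequences up to
50 residues (digestion, 200 draws), peptides up to 20 residues
(complementarity), and universes of ≤10 peptides (product counts) — sizes at
which brute-force oracles are exact and the whole suite runs in seconds.

## Known limitations

No isotope envelopes or average masses; no neutral losses other than linker
cleavage; no a/c/x/z fragment series; no semi-specific or non-specific
digestion; no spacer-arm distance filtering; no spectral-intensity or
peptide-response prediction; no live UniProt/STRING retrieval — all inputs
are files. Isoform sequences are taken as given in the input FASTA, never
derived.
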