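# xltransit

Transition-list generation for targeted cross-linking mass spectrometry
(XL-MS). Given a target protein, a proteome FASTA, a STRING-dialect
protein–protein interaction table, an enzyme, a cross-linker and a
modification regime, `xltransit`:

1. ranks the target's candidate interactors by STRING combined score, with
   confidence tiers (highest > 0.9, high > 0.7, medium > 0.4, low > 0.15);
2. digests target and interactors in silico (trypsin or chymotrypsin,
   no-cleavage-before-proline, missed cleavages) and expands static/variable
   modifications;
3. enumerates every theoretical cross-linked species — inter-links,
   loop-links on either protein, and mono-links (dead-ends) — with exact
   monoisotopic neutral masses and precursor m/z at the requested charges;
4. generates b/y fragment ions with correct MS-cleavable-linker remnant
   handling (e.g. DSSO's alkene/sulfenic-acid pair, 54.010565 +
   103.993200 = 158.003765 Da) and exports an SRM/PRM-ready CSV transition
   list.

It is aimed at proteomics researchers planning SRM/PRM validation of
protein–protein interactions, where the convoluted fragmentation of
cross-linked peptides makes hand calculation impractical.

## The arithmetic at the core

For a peptide with residues $r_1\dots r_n$ and applied modification deltas
$\Delta_i$, the neutral mass is $M = \sum_i m(r_i) + m(\mathrm{H_2O}) +
\sum \Delta_i$ (monoisotopic throughout), and an ion's m/z is
$(M + z\,m_{\mathrm{H^+}})/z$. A cross-linker adds its intact delta $L$:
inter-link $M_A + M_B + L$; loop-link $M + L$; mono-link $M + L +
m(\mathrm{H_2O})$. An MS-cleavable linker fragments into remnants
$(\ell_A, \ell_B)$ with $\ell_A + \ell_B = L$, so a link-spanning fragment
of one peptide carries $\ell_A$ or $\ell_B$ (both orientations are emitted
for asymmetric linkers) and any orientation conserves the precursor mass.
b/y fragments obey $b_i + y_{n-i} = M$.

## Worked example

The bundled fixture reproduces the APOE (P02649) search — trypsin, DSSO,
top 10 interactors, peptide length 9, precursor charges 2–3, product charges
1–2, carbamidomethyl (static) and oxidation (variable). Partner labels and
combined scores are the published values; the protein *sequences* in the
fixture are synthetic stand-ins, so the m/z columns demonstrate the
machinery, not the real human peptides.

```sh
xltransit write-fixture --dir apoe_fixture
xltransit run --target P02649 --enzyme trypsin --linker DSSO \
  --min-len 9 --max-len 9 --top-n 10 \
  --precursor-charge 2 --precursor-charge 3 \
  --product-charge 1 --product-charge 2 \
  --mod carbamidomethyl:static --mod oxidation:variable \
  --proteome apoe_fixture/proteome.fasta --ppi apoe_fixture/ppi_links.txt \
  --map apoe_fixture/accession_map.tsv \
  --out transitions.csv --interactors-out interactors.csv
```

prints

```
10 interactors, 9088 transitions -> transitions.csv
```

`interactors.csv` begins

```
rank,protein name,interaction probability,confidence
1,sp|Q07954|LRP1_HUMAN,0.999,highest
2,sp|Q14114|LRP8_HUMAN,0.999,highest
3,sp|P04114|APOB_HUMAN,0.998,highest
```

— the ranked interactor table: all ten partners score above 0.9 and tier as
highest confidence. `transitions.csv` begins

```
combined score,protein A peptide,cross linker,protein B peptide,precursor charge,precursor m/z,protein A ion,protein A ion type,protein B ion,protein B ion type,product charge,product m/z
0.999,AC[+57.02146]DEEMKGR,DSSO,DC[+57.02146]DENMKGR,2,1188.952719,b1,b,,,1,72.044390
0.999,AC[+57.02146]DEEMKGR,DSSO,DC[+57.02146]DENMKGR,2,1188.952719,b1,b,,,2,36.525833
```

Each row is one precursor→product transition: here a DSSO inter-link between
a target peptide and an LRP1-partner peptide (both carrying static
carbamidomethyl, bracketed as a mass delta), selected at 2+ (precursor m/z
1188.952719), monitoring the b1 ion of the protein-A peptide at 1+ and 2+.
Rows for fragments spanning the linked lysine appear in two remnant
variants (alkene and sulfenic acid); oxidized methionine forms appear as
separate shifted rows.

The same search is available as a library call:

```python
from xltransit import SearchConfig, run_search
interactors, rows = run_search(SearchConfig(target_accession="P02649", ...))
```

## Layout

| module | role |
|---|---|
| `xltransit.proteome_io` | UniProt-dialect FASTA I/O, canonical/isoform accessions |
| `xltransit.ppi_query` | STRING table + mapping ingestion, ranking, tiers |
| `xltransit.digestion` | enzymes, missed cleavages, length filter |
| `xltransit.chem_masses` | monoisotopic masses, modifications, m/z |
| `xltransit.crosslinkers` | linker catalog (CSV, user-extensible), site location |
| `xltransit.product_enum` | the four product classes, b/y fragments, remnants |
| `xltransit.transitions_export` | 12-column transition table, CSV round-trip |
| `xltransit.cli` | `SearchConfig`, `run_search`, the `xltransit` command |
| `xltransit.fixtures` | APOE fixture and synthetic proteomes |

See `docs/methods.md` for the model, defaults, and design decisions.
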