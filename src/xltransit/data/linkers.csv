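# Bundled cross-linker catalog. Columns:
#   name,site_a,site_b,nterm_reactive,spacer_arm_A,cleavable,intact_delta,remnant_pairs
# site_a/site_b: residue letters targeted by each reactive side ("*" = any residue).
# nterm_reactive: which sides also react with the protein N-terminal alpha-amine ("A","B","AB","").
# intact_delta: monoisotopic mass (Da) added when both sides are conjugated.
# remnant_pairs: gas-phase cleavage remnants as "deltaA:deltaB" pairs separated by ";"
#   (empty for non-cleavable linkers); each pair must sum to intact_delta.
# Per-linker reactive-site specificity follows vendor literature (Thermo
# Scientific crosslinker handbook and the primary DSSO/DSBU references);
# masses computed from elemental composition with IUPAC monoisotopic element
# masses: DSSO C6H6O3S -> C3H2O (alkene) + C3H4O2S (sulfenic acid);
# DSBU C9H12N2O3 -> C4H7NO + C5H5NO2; DSS/BS3 C8H10O2; sulfo-SDA adds C5H6O
# after diazirine photolysis; EDC is zero-length (amide bond, -H2O).
name,site_a,site_b,nterm_reactive,spacer_arm_A,cleavable,intact_delta,remnant_pairs
DSSO,K,K,AB,10.3,true,158.003765,54.010565:103.993200
DSBU,K,K,AB,12.5,true,196.084792,85.052764:111.032028
DSS,K,K,AB,11.4,false,138.068080,
BS3,K,K,AB,11.4,false,138.068080,
sulfo-SDA,K,*,A,3.9,false,82.041865,
EDC,DE,K,B,0.0,false,-18.010565,
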