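# SYNTHETIC PLACEHOLDER — not literature-derived.
# The alpha-S1-casein B allele has no deposited protein accession; it is
# reconstructed from the A-allele reference by positional edits.  The edit
# below is a format placeholder so the loading/application machinery can be
# exercised; replace it with the literature-derived substitutions before
# using this allele for biological conclusions.
gene: CSN1S1
reference: NP_001424592.1
allele: B
edits:
  - {kind: substitution, position: 16, ref: A, alt: V}
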