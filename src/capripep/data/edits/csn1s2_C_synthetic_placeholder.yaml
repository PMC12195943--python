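# SYNTHETIC PLACEHOLDER — not literature-derived.
# The alpha-S2-casein C allele is reconstructed from the A-allele reference
# by positional edits.  Replace with literature-derived substitutions.
gene: CSN1S2
reference: XP_013820127.2
allele: C
edits:
  - {kind: substitution, position: 9, ref: K, alt: E}
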