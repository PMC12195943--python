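# Default specificity table: gastric/pancreatic digestion trio.
# Sides: C-terminal = cut after the residue; N-terminal = cut before it.
# These are the headline preferences; full published specificity tables for
# these enzymes carry additional subsite preferences and exceptions that can
# be added here (blocked_by_next) without code changes.
enzymes:
  - name: pepsin
    ec: 3.4.23.1
    rules:
      - {residue: F, side: C-terminal}
      - {residue: L, side: C-terminal}
  - name: trypsin
    ec: 3.4.21.4
    rules:
      - {residue: K, side: C-terminal}
      - {residue: R, side: C-terminal}
  - name: chymotrypsin A
    ec: 3.4.21.1
    rules:
      - {residue: Y, side: C-terminal}
      - {residue: W, side: C-terminal}
      - {residue: F, side: C-terminal}
      - {residue: L, side: C-terminal}
      - {residue: N, side: C-terminal}
      - {residue: H, side: C-terminal}
      - {residue: M, side: C-terminal}
      - {residue: I, side: N-terminal}
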