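"""In silico digestion of a short protein with the default enzyme trio.

Builds a toy sequence, enumerates cleavage sites under simultaneous
pepsin + trypsin + chymotrypsin A action, and prints the released peptides
in both complete mode (fragments partition the protein) and partial mode
(every cut-bounded substring, modelling overlapping peptides from
successive cleavage events).
"""

from capripep import ProteinSequence, default_enzymes, digest

seq = ProteinSequence(id="demo", residues="MKWYAGPFLTRQGLVK")
enzymes = default_enzymes()

complete = digest(seq, enzymes, mode="complete")
print(f"sequence      : {seq.residues} (N={seq.n_residues})")
print(f"cut sites     : {list(complete.cut_sites)}")
print("complete mode :", [p.sequence for p in complete.peptides])

partial = digest(seq, enzymes, mode="partial")
print(f"partial mode  : {partial.n_intervals} cut-bounded intervals, "
      f"{partial.n_distinct_sequences} distinct sequences")

# Cut sites are inter-residue positions (site p = between residues p and
# p+1); complete-mode peptides concatenate back to the input, while partial
# mode enumerates every peptide any subset of cuts could have released.
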