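"""Constructing an allelic variant from a reference and diffing it back.

Applies the double T->A substitution that turns an interior TTM motif into
AAM — the kind of allele-level change that converts a non-bioactive released
fragment into a registered multifunctional peptide — then recovers the edit
list by positional comparison.
"""

from capripep import ProteinSequence, VariantEdit, apply_edits, diff_alleles

reference = ProteinSequence(id="ref", residues="GPLTTMQKWSF",
                            gene="CSN1S1", allele="A")
edits = [
    VariantEdit("substitution", 4, ref_residue="T", alt_residue="A"),
    VariantEdit("substitution", 5, ref_residue="T", alt_residue="A"),
]
variant = apply_edits(reference, edits, new_allele="E")

print(f"reference ({reference.allele}): {reference.residues}")
print(f"variant   ({variant.allele}): {variant.residues}")

recovered = diff_alleles(reference, variant)
for e in recovered:
    print(f"  {e.kind} at position {e.position}: "
          f"{e.ref_residue} -> {e.alt_residue}")

# Positions are 1-based in the reference frame; diff_alleles returns the
# minimal positional edit list, so applying it to the reference reproduces
# the variant exactly.
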