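"""Bioactive-fragment frequency profile (A = a/N and sigma-A) of a protein.

Scans a toy sequence against the bundled peptide-activity database and
prints the per-activity frequency of occurrence A and its sum over all
activities.  A higher sigma-A means more database-registered bioactive
fragments per residue — the standard screen for a protein's potential as a
bioactive-peptide precursor.
"""

from capripep import ProteinSequence, compute_profile, default_peptide_db

db = default_peptide_db()
seq = ProteinSequence(id="demo", residues="QGPFPLAAMGYSFQFPWAGAF")

profile = compute_profile(seq, db)
print(f"sequence: {seq.residues} (N={profile.N})")
for activity, a_value in sorted(profile.A_by_activity.items()):
    print(f"  A[{activity:10s}] = {a_value:.4f}   "
          f"({round(a_value * profile.N)} fragment occurrence(s))")
print(f"sigma-A = {profile.sigma_A:.4f}")

# Each A value is (positional occurrences of fragments with that activity) /
# (residue count); overlapping occurrences all count.  Values depend on the
# database used -- the bundled one is a small curated subset, so profiles
# are comparable only against other profiles computed with the same table.
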