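# Methods

## Model and assumptions

`capripep` treats a protein allele as a plain string over the 20 standard
one-letter amino-acid codes (ambiguity codes B/Z/X are rejected by default;
the alphabet is configurable).  Everything downstream is exact string
computation — there is no kinetics, no cleavage probability, no pH or
temperature model, and no fuzzy peptide matching.  The package's claims are
therefore combinatorial: *which* peptides a rule set can release and *how
often* database fragments occur, not how much of each peptide a real digest
would yield.

### Variant construction

Variants are reference + edit list.  Edit positions are 1-based in the
reference frame, matching how substitution positions are quoted in the
casein literature; edits are applied in descending position order so a
deletion never shifts the coordinates of a later-listed edit.  Insertions
attach *after* the stated position (position 0 prepends) and may carry a
multi-residue string: emitting several single-residue insertions at the
same position would make the result depend on application order, so a
contiguous inserted run is one edit.  Deletions stay single-residue.

Diffing two alleles is deliberately not an aligner.  Equal-length pairs are
compared position by position; unequal-length pairs are resolved only if a
common prefix and suffix cover the shorter sequence exactly — the single
contiguous indel case, which is sufficient for the α-S1 F allele, whose
exon loss removes one internal block.  Anything more complex raises a
"sequences not comparable" error rather than silently choosing one of many
possible alignments.

Whether literature positions refer to the precursor (with signal peptide)
or the mature protein is often unstated; the pipeline exposes a
`signal_peptide_trim` knob (default 0, i.e. sequences are used as given)
and records the value in the run manifest so every report states its frame.

### Digestion

Enzyme specificity is declarative: each rule names a target residue, a side
(C-terminal = cut after, N-terminal = cut before) and an optional
`blocked_by_next` set for residues across the scissile bond that suppress
the cut.  Simultaneous multi-enzyme action is the union of all sites —
the standard reading of a one-pot digest — and adding an enzyme can
therefore never remove a site.  Rules matching a terminal residue produce
no cut, so fragments are always nonempty.

Two release modes: `complete` cuts every site (fragments partition the
protein; count = sites + 1), and `partial` enumerates every substring
bounded by two boundaries from {start} ∪ sites ∪ {end} — the superset
modelling overlapping peptides from successive cleavage events (C(k+2, 2)
intervals for k sites).  Headline per-allele fragment counts use complete
mode and are reported under both conventions (distinct (start, end)
intervals and distinct sequences) because published counts do not always
say which they use.

The bundled enzyme table encodes the headline preferences of pepsin
(C-terminal after F, L), trypsin (C-terminal after K, R) and chymotrypsin A
(C-terminal after Y, W, F, L, N, H, M; N-terminal before I).  Published
specificity descriptions for these enzymes are explicitly non-exhaustive,
so the table is ordinary user-editable YAML; matching the exact fragment
counts of a particular web platform may require transcribing that
platform's full specificity table into the config.

### Frequency of occurrence of bioactive fragments

For one activity, A = a/N, where a counts *positional* occurrences of
database peptides carrying that activity as substrings of the protein
(overlapping matches all count, the same peptide at two positions counts
twice) and N is the residue count.  ΣA is the unweighted sum of A over all
activities; a peptide with three registered activities contributes three
occurrences.  The positional convention is chosen over distinct-sequence
counting because A is defined as a count of *fragments*, and it is the
convention under which A × N is always an integer — a property the tests
exploit for exact oracle comparison.  Matching is exact-sequence only: no
Leu/Ile equivalence, no modified residues, minimum database peptide length
2.

A and ΣA are database-relative.  The bundled database covers the 32
registered candidate peptides of the goat-casein analysis plus the
27-activity code registry; it is a curated subset, so ΣA values computed
against it are not comparable to values computed against a full
public database (thousands of peptides).  Users supply their own TSV for
that purpose.

### Filtering, annotation, matrix

Released peptides are kept if their length lies in [2, 6] and their score
exceeds 0.5 — the window in which short database fragments are dense and
external predictor scores are conventionally read as "probably bioactive".
The tie rule is strict-greater by default ("exceeds"), with
greater-or-equal available; every bundled score is strictly above 0.5, so
the choice does not affect the shipped counts.  Peptides absent from the
score table are excluded and counted in the log rather than silently scored
0, which would otherwise bias per-allele comparisons invisibly.

The bioactivity matrix is alleles × activities with integer cells counting
*distinct peptide sequences* carrying each activity — positional duplicates
within an allele count once, and two alleles releasing the same peptide at
different positions contribute equally.  Per-gene and per-allele candidate
counts, by contrast, include unregistered peptides (a released candidate
without a database entry is still a released candidate); only the matrix is
restricted to registered ones, since an unregistered peptide contributes no
activity column.  When an activity registry is supplied, zero columns are
kept in the serialized matrix so heatmap consumers see absences explicitly.

ΣA and per-activity A values are written to 4 decimal places in TSV
outputs; full precision is kept in memory.

## Synthetic data: what it emulates and what it does not

The generators emulate the *structure* of the real analysis — allele
families differing by point edits, a peptide→activity database, a score
table, digestion and filtering — with exact planted ground truth.  The 20
letters are partitioned into disjoint background, fragment, cleavage and
decoy sets; planted tokens are separated by at least one background
residue; each planted fragment is flanked by one cleavage residue on each
side; and the matching synthetic protease cuts on both sides of each
cleavage residue.  Consequently each fragment is released exactly as itself
in complete mode, occurs exactly its planted multiplicity, decoy database
entries occur zero times, and the single-residue cleavage fragments fall
below the length window.  Variant edits either destroy one planted fragment
copy (first residue → background letter) or create one new cleavage-site
pair (isolated background residue → cleavage residue), so per-allele
differences are known a priori.

Defaults: protein length 120, two planted fragment species (a dipeptide
planted twice, a tripeptide once), three standalone cleavage residues,
three alleles with one edit each, seed 42.  These sizes keep every stage's
output small enough to verify by hand while exercising multiplicity,
destruction and site creation.

What passing synthetic tests show is that the bookkeeping — occurrence
counting, site enumeration, release, filtering, aggregation — is exactly
correct.  What they do not show: generated proteins have no realistic
composition, repeat structure or homology, so nothing about predictive
transfer to real milk proteins follows.  Real-sequence conclusions
additionally depend on inputs this package deliberately treats as external:
accession sequences, a full peptide database, a trained scorer and a
complete enzyme specificity table.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  spec or CLI; generators are pure functions of the seed.
- Duplicate score rows must agree within 1e-9; ΣA/profile equality in tests
  is asserted at 1e-12 (pure counting divided by N admits no real rounding).
- Sort orders are fixed everywhere (sites ascending; occurrences by start
  then peptide; TSV rows by label then peptide), so identical inputs give
  byte-identical output files.
- The activity-code check in occurrence scans applies only when a registry
  is present: without one, an unseen code is indistinguishable from a
  zero-occurrence one and is counted as zero rather than rejected.
- The composition-based `heuristic_score` is a labelled stand-in for
  plumbing tests only; it is not equivalent to any trained predictor and is
  never used in shipped results.
- Hypothetical-allele edit lists (α-S1 B; α-S2 B and C) ship as placeholder
  YAML files labelled synthetic; the literature does not print the edits,
  so users must supply literature-derived lists to build those alleles
  faithfully.

## Known limitations

- No missed-cleavage probabilities or partial-digest sampling; `partial`
  mode enumerates all cut-bounded substrings rather than sampling likely
  ones.
- Unequal-length allele diffing handles a single contiguous indel only.
- The matrix offers raw counts only; no normalization or clustering.
- Accession-dependent quantities (per-allele fragment counts from real
  casein accessions, full-database ΣA values, neural predictor scores)
  require external resources and are out of scope; the replay entry point
  exists precisely so downstream stages can be validated without them.
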