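# capripep

Genotype-aware in silico proteolysis and bioactive-peptide profiling of milk
casein allelic variants.

Milk caseins (the α-S1, β, α-S2 and κ proteins encoded by *CSN1S1*, *CSN2*,
*CSN1S2* and *CSN3*) are highly polymorphic, and their allelic variants
differ in which short bioactive peptides — ACE inhibitors, DPP-IV
inhibitors, antioxidative and antimicrobial fragments — gastrointestinal
proteolysis can release. `capripep` is a library (plus a thin CLI) for
asking, entirely in silico: *given an allele's protein sequence, which
bioactive peptides would digestion release, and how do alleles of the same
gene differ?*  It is aimed at researchers screening protein variants as
precursors of functional peptides before committing to wet-lab hydrolysis.

## What it computes

1. **Allele construction** — variants are built from a reference sequence
   plus a positional edit list (substitutions, deletions, insertions;
   1-based coordinates), and two alleles can be diffed back into a minimal
   edit list.
2. **Digestion** — a declarative cleavage-rule engine (target residue, cut
   side, optional blocking residues) models the simultaneous action of any
   enzyme set as the union of their cut sites.  The bundled table covers
   pepsin (C-terminal after F, L), trypsin (C-terminal after K, R) and
   chymotrypsin A (C-terminal after Y, W, F, L, N, H, M; N-terminal before
   I).  Complete mode partitions the protein; partial mode also enumerates
   every cut-bounded substring (overlapping peptides from successive
   cleavage events).
3. **Frequency statistics** — for each activity, the frequency of occurrence
   of bioactive fragments

   &nbsp;&nbsp;&nbsp;&nbsp;*A = a / N*

   where *a* counts positional occurrences of database fragments with that
   activity inside the protein and *N* is the protein's residue count, plus
   the unweighted sum ΣA over all activities.
4. **Filtering and annotation** — released peptides are kept if they fall in
   a length window (default 2–6 residues) and their externally supplied
   bioactivity-likelihood score exceeds a threshold (default 0.5); survivors
   are annotated with their activity sets from a peptide→activity database.
5. **Bioactivity matrix** — alleles × activities integer counts of distinct
   annotated peptides (the quantitative content of a bioactivity heatmap),
   plus a report of allele-specific peptides (released by exactly one allele
   of a gene).

A synthetic-data module generates proteins, allele families, databases and
score tables with exact, planted ground truth (disjoint-alphabet
construction), so the whole pipeline is testable offline.

## Worked example

Replaying the bundled goat-casein candidate table (released peptides with
predictor scores, activity annotations and per-allele release marks for the
four casein genes) through the filter and aggregation stages:

```python
from capripep import default_candidate_table, replay_candidates

result = replay_candidates(default_candidate_table())
print(result.total_candidates, result.n_registered, result.n_multifunctional)
print(result.per_gene_counts)
print({a: result.per_allele_counts[("CSN1S1", a)] for a in "ABEF"})
```

prints

```
35 32 28
{'CSN1S1': 14, 'CSN1S2': 10, 'CSN2': 9, 'CSN3': 7}
{'A': 9, 'B': 9, 'E': 10, 'F': 6}
```

i.e. 35 candidate peptides pass the score/length filter, 32 of them carry a
database entry and 28 are multifunctional (two or more activities); 14
candidates come from α-S1-casein alleles (9, 9, 10 and 6 from alleles A, B,
E and F respectively), 10 from α-S2, 9 from β and 7 from κ.
`result.allele_specific` lists peptides unique to one allele of a gene —
e.g. AAM appears only in α-S1 allele E, where a double T→A substitution
turns the unregistered TTM fragment into a registered multifunctional
peptide, and AGPF only in α-S2 allele F (A→P at one position relative to
the AGAF of alleles A/B/C).

More narrative scripts live in `examples/` (digestion, A/ΣA profiling,
variant construction, synthetic end-to-end recovery), and the `capripep`
CLI exposes the same stages as `digest`, `profile`, `filter`, `run`,
`replay` and `simulate` subcommands.

## Scope notes

- The neural bioactivity scorer is not reimplemented; scores enter via a
  TSV (`peptide`, `score`).  A trivial composition heuristic is provided for
  synthetic tests only.
- The bundled peptide database is a small curated subset, not a mirror of
  any full bioactive-peptide database; ΣA values are only comparable across
  sequences profiled with the same database.
- Enzyme specificity is ordinary config; reproducing fragment counts from
  other platforms may require their full specificity tables.
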