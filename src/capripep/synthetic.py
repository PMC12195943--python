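"""Ground-truth synthetic data for every pipeline stage.

Real casein analyses depend on database accessions and an external scorer;
the generators here build proteins, allele families, peptide databases and
score tables whose correct outputs are known *by construction*, so each
stage can be tested exactly and offline.

The guarantee comes from a disjoint-alphabet design: the 20 amino-acid
letters are partitioned into

* a **background** set, used for filler runs,
* the residues of the **planted fragments** (the "bioactive" peptides),
* the **planted cleavage residues** (the only letters the matching synthetic
  protease targets), and
* a **decoy** set, used only for database entries that must never occur in
  any generated protein.

Every planted token is flanked by at least one background residue, and each
planted fragment is additionally flanked by one cleavage residue on each
side.  The matching protease (:func:`synthetic_protease`) cuts on *both*
sides of each cleavage residue, so a flanked fragment is released exactly as
itself in complete-mode digestion (the flanking single-residue cleavage
fragments fall below the minimum peptide length and carry no score, so the
filter drops them).  Because the alphabets do not overlap, each planted
fragment occurs exactly as many times as planted, every cleavage site is
exactly where recorded, and decoys occur zero times: recovery tests are
exact, not statistical.

A generated protein does not resemble a real one (no realistic composition
or repeat structure); what passing tests show is that the bookkeeping —
occurrence counting, site enumeration, release, filtering, matrix building —
is correct, not that predictions transfer to real milk proteins.

All generators are pure functions of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .bioactive import BioactiveDB
from .digestion import C_TERMINAL, N_TERMINAL, CleavageRule, Enzyme
from .errors import SpecError
from .sequences import STANDARD_AA, AlleleSet, ProteinSequence, VariantEdit, apply_edits

DEFAULT_FRAGMENTS = (("GY", "ACE-I", 2), ("WPH", "DPP-IV-I", 1))
DEFAULT_CUT_RESIDUES = (("K", 3),)
DEFAULT_BACKGROUND = frozenset("ADEFILNQSTV")
DEFAULT_DECOY = frozenset("CM")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``planted_fragments`` is a tuple of (peptide, activity code,
    multiplicity); ``planted_cut_residues`` of (residue, count) for
    standalone cleavage residues planted in the background;
    ``low_score_fragments`` names planted peptides that the generated score
    table should place *below* the filter threshold.
    """

    seed: int = 42
    protein_length: int = 120
    n_alleles: int = 3
    n_edits_per_allele: int = 1
    planted_fragments: tuple = DEFAULT_FRAGMENTS
    planted_cut_residues: tuple = DEFAULT_CUT_RESIDUES
    background_alphabet: frozenset = DEFAULT_BACKGROUND
    decoy_alphabet: frozenset = DEFAULT_DECOY
    low_score_fragments: tuple = ()

    def __post_init__(self) -> None:
        frag_res = set().union(*(set(p) for p, _, _ in self.planted_fragments)) \
            if self.planted_fragments else set()
        cut_res = {r for r, _ in self.planted_cut_residues}
        groups = {
            "background": set(self.background_alphabet),
            "fragment": frag_res,
            "cut": cut_res,
            "decoy": set(self.decoy_alphabet),
        }
        for name, residues in groups.items():
            bad = residues - STANDARD_AA
            if bad:
                raise SpecError(f"{name} alphabet has invalid residues {sorted(bad)}")
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = groups[a] & groups[b]
                if overlap:
                    raise SpecError(
                        f"{a} and {b} alphabets overlap: {sorted(overlap)}"
                    )
        if not self.background_alphabet:
            raise SpecError("background alphabet must be nonempty")
        if self.planted_fragments and not self.planted_cut_residues:
            raise SpecError(
                "planting fragments requires at least one cleavage residue "
                "for release flanks"
            )
        peptides = [p for p, _, _ in self.planted_fragments]
        for i, p in enumerate(peptides):
            for j, q in enumerate(peptides):
                if i != j and p in q:
                    raise SpecError(
                        f"planted fragment {p!r} is a substring of {q!r}; "
                        "occurrence counts would not be exact"
                    )
        if self.protein_length < self.total_planted_length + self.n_tokens + 1:
            raise SpecError(
                f"protein_length {self.protein_length} too small for "
                f"{self.total_planted_length} planted residues plus "
                f"{self.n_tokens + 1} separators"
            )

    @property
    def flank_residue(self) -> Optional[str]:
        return self.planted_cut_residues[0][0] if self.planted_cut_residues else None

    @property
    def n_tokens(self) -> int:
        return sum(m for _, _, m in self.planted_fragments) + sum(
            c for _, c in self.planted_cut_residues
        )

    @property
    def total_planted_length(self) -> int:
        flank = 2 if self.flank_residue else 0
        return sum((len(p) + flank) * m for p, _, m in self.planted_fragments) \
            + sum(c for _, c in self.planted_cut_residues)


@dataclass(frozen=True)
class GeneratedProtein:
    """A synthetic protein with its ground truth."""

    sequence: ProteinSequence
    #: (peptide, activity) -> tuple of 1-based start positions
    occurrences: dict
    #: ground-truth inter-residue cut sites under the matching protease
    cut_sites: tuple
    #: 1-based positions holding cleavage residues (flanks and standalone)
    cut_residue_positions: tuple
    #: 1-based positions holding background residues (safe to mutate)
    background_positions: tuple


@dataclass(frozen=True)
class AlleleFamily:
    """A reference plus variants with fully known edits and ground truth."""

    allele_set: AlleleSet
    edits: dict        # allele label -> tuple of VariantEdit
    occurrences: dict  # allele label -> occurrence map (as GeneratedProtein)
    cut_sites: dict    # allele label -> tuple of ground-truth cut sites


def synthetic_protease(spec: SyntheticSpec, name: str = "synthetic protease") -> Enzyme:
    """The protease matching the spec: cuts on both sides of every planted
    cleavage residue, nothing else — so flanked fragments are released
    exactly as themselves."""
    rules = []
    for res, _ in spec.planted_cut_residues:
        rules.append(CleavageRule(target_residue=res, side=C_TERMINAL))
        rules.append(CleavageRule(target_residue=res, side=N_TERMINAL))
    if not rules:
        raise SpecError("spec plants no cleavage residues")
    return Enzyme(name=name, ec_number="synthetic", rules=rules)


def _sites_for_cut_residue(pos: int, n: int) -> list[int]:
    """Sites contributed by a cleavage residue at 1-based *pos* under the
    dual-side synthetic protease (neighbours are never cleavage residues)."""
    sites = []
    if pos > 1:
        sites.append(pos - 1)
    if pos < n:
        sites.append(pos)
    return sites


def generate_protein(
    spec: SyntheticSpec,
    seq_id: str = "synthetic",
    gene: str = "SYN1",
    allele: str = "A",
    rng: Optional[np.random.Generator] = None,
) -> GeneratedProtein:
    """Build one protein with planted, releasable fragments and cleavage
    residues.  Tokens are shuffled and placed with at least one background
    residue between consecutive tokens and at both ends."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    flank = spec.flank_residue
    tokens: list[tuple[str, str, str]] = []
    for pep, act, mult in spec.planted_fragments:
        tokens.extend([("frag", pep, act)] * mult)
    for res, count in spec.planted_cut_residues:
        tokens.extend([("cut", res, "")] * count)
    order = rng.permutation(len(tokens)) if tokens else []
    tokens = [tokens[i] for i in order]

    def token_len(tok) -> int:
        return len(tok[1]) + 2 if tok[0] == "frag" else len(tok[1])

    n_gaps = len(tokens) + 1
    background_total = spec.protein_length - sum(token_len(t) for t in tokens)
    extra = background_total - n_gaps
    gap_sizes = 1 + rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))
    bg_letters = sorted(spec.background_alphabet)

    chars: list[str] = []
    occurrences: dict[tuple[str, str], list[int]] = {}
    cut_residue_positions: list[int] = []
    background_positions: list[int] = []

    def emit_background(size: int) -> None:
        for _ in range(size):
            background_positions.append(len(chars) + 1)
            chars.append(bg_letters[rng.integers(len(bg_letters))])

    for gap, token in zip(gap_sizes, tokens):
        emit_background(int(gap))
        kind, payload, act = token
        if kind == "frag":
            cut_residue_positions.append(len(chars) + 1)
            chars.append(flank)
            occurrences.setdefault((payload, act), []).append(len(chars) + 1)
            chars.extend(payload)
            cut_residue_positions.append(len(chars) + 1)
            chars.append(flank)
        else:
            cut_residue_positions.append(len(chars) + 1)
            chars.extend(payload)
    emit_background(int(gap_sizes[-1]))

    n = len(chars)
    sites = sorted(
        {s for p in cut_residue_positions for s in _sites_for_cut_residue(p, n)}
    )
    seq = ProteinSequence(
        id=seq_id, residues="".join(chars), gene=gene, allele=allele
    )
    return GeneratedProtein(
        sequence=seq,
        occurrences={k: tuple(v) for k, v in occurrences.items()},
        cut_sites=tuple(sites),
        cut_residue_positions=tuple(sorted(cut_residue_positions)),
        background_positions=tuple(background_positions),
    )


def generate_allele_family(spec: SyntheticSpec, gene: str = "SYN1") -> AlleleFamily:
    """Reference allele "A" plus ``n_alleles - 1`` variants "B", "C", ...

    Variant edits alternate between destroying one planted fragment copy
    (substituting its first residue with a background letter, which keeps
    the flanks but removes the database match) and creating a new cleavage
    site pair (substituting an isolated background residue with the first
    planted cleavage residue), so downstream per-allele differences are
    known a priori.
    """
    if spec.n_alleles < 2:
        raise SpecError("an allele family needs at least 2 alleles")
    rng = np.random.default_rng(spec.seed)
    reference = generate_protein(spec, seq_id=f"{gene}_ref", gene=gene,
                                 allele="A", rng=rng)
    bg_letters = sorted(spec.background_alphabet)
    cut_letter = spec.flank_residue
    labels = [chr(ord("A") + i) for i in range(spec.n_alleles)]
    n = reference.sequence.n_residues
    bg_set = set(reference.background_positions)

    alleles = {"A": reference.sequence}
    edits: dict[str, tuple] = {"A": ()}
    occ: dict[str, dict] = {"A": reference.occurrences}
    sites: dict[str, tuple] = {"A": reference.cut_sites}

    for label in labels[1:]:
        allele_edits: list[VariantEdit] = []
        remaining = {k: list(v) for k, v in reference.occurrences.items()}
        # background positions whose neighbours are background too: turning
        # one into a cleavage residue adds exactly the two sites {p-1, p}
        free_bg = [
            p for p in sorted(bg_set)
            if 2 <= p <= n - 1 and (p - 1) in bg_set and (p + 1) in bg_set
        ]
        new_sites: list[int] = []
        destroy_next = True
        for _ in range(spec.n_edits_per_allele):
            destroyable = [k for k in sorted(remaining) if remaining[k]]
            if destroy_next and destroyable:
                key = destroyable[int(rng.integers(len(destroyable)))]
                starts = remaining[key]
                start = starts.pop(int(rng.integers(len(starts))))
                ref_res = key[0][0]
                alt_choices = [b for b in bg_letters if b != ref_res]
                alt = alt_choices[int(rng.integers(len(alt_choices)))]
                allele_edits.append(
                    VariantEdit("substitution", start, ref_residue=ref_res,
                                alt_residue=alt)
                )
            elif cut_letter is not None and free_bg:
                idx = int(rng.integers(len(free_bg)))
                pos = free_bg[idx]
                free_bg = [p for p in free_bg if abs(p - pos) > 2]
                ref_res = reference.sequence.residues[pos - 1]
                allele_edits.append(
                    VariantEdit("substitution", pos, ref_residue=ref_res,
                                alt_residue=cut_letter)
                )
                new_sites.extend([pos - 1, pos])
            destroy_next = not destroy_next
        variant = apply_edits(reference.sequence, allele_edits,
                              new_allele=label, new_id=f"{gene}_{label}")
        alleles[label] = variant
        edits[label] = tuple(allele_edits)
        occ[label] = {k: tuple(v) for k, v in remaining.items() if v}
        sites[label] = tuple(sorted({*reference.cut_sites, *new_sites}))

    return AlleleFamily(
        allele_set=AlleleSet(gene=gene, reference_id="A", alleles=alleles),
        edits=edits,
        occurrences=occ,
        cut_sites=sites,
    )


def generate_db_and_scores(spec: SyntheticSpec) -> tuple[BioactiveDB, dict]:
    """Database of planted peptides plus never-occurring decoys, and a score
    table placing planted peptides above (or, if listed in
    ``low_score_fragments``, below) the default 0.5 threshold."""
    records: dict[str, frozenset] = {}
    for pep, act, _ in spec.planted_fragments:
        records[pep] = records.get(pep, frozenset()) | {act}
    decoy_letters = sorted(spec.decoy_alphabet)
    decoys = []
    if decoy_letters:
        a, b = decoy_letters[0], decoy_letters[-1]
        decoys = [a + b, b + a + a]
    for d in decoys:
        records[d] = frozenset({"AO"})
    scores: dict[str, float] = {}
    for pep, _, _ in spec.planted_fragments:
        scores[pep] = 0.4 if pep in spec.low_score_fragments else 0.9
    for d in decoys:
        scores[d] = 0.8
    db = BioactiveDB(records=records, source=f"synthetic(seed={spec.seed})")
    return db, scores
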