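"""Protein sequences, allelic variants and positional edits.

Casein genes (CSN1S1, CSN2, CSN1S2, CSN3) are highly polymorphic; their
protein-level allelic variants differ by point substitutions and, for the
alpha-S1 F allele, a large internal deletion caused by exon skipping.  This
module provides the :class:`ProteinSequence` container, construction of
variants from a reference plus an edit list, and the inverse operation
(positional diffing of two alleles).

Coordinates in :class:`VariantEdit` and in all reports are 1-based, matching
how substitution positions are quoted in the casein literature ("position
134", "positions 209 and 210"); internally slicing is ordinary 0-based
Python.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    ConfigError,
    EditConflictError,
    EditRangeError,
    FastaParseError,
    NotComparableError,
    SequenceValidationError,
    UsageError,
)

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes. Ambiguity codes (B, Z, X)
#: and non-standard letters are rejected by default.
STANDARD_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

EDIT_KINDS = ("substitution", "deletion", "insertion")


def validate_residues(
    residues: str,
    alphabet: frozenset[str] = STANDARD_AA,
    context: str = "sequence",
) -> None:
    """Raise :class:`SequenceValidationError` naming the first bad position."""
    for i, ch in enumerate(residues):
        if ch not in alphabet:
            raise SequenceValidationError(
                f"invalid residue {ch!r} at position {i + 1} in {context}"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid string with gene/allele metadata.

    Parameters
    ----------
    id : str
        Accession or allele label.
    residues : str
        Uppercase one-letter residue codes.
    gene : str
        Gene symbol (e.g. ``CSN1S1``); free-form for synthetic data.
    allele : str
        Allele label within the gene.
    alphabet : frozenset of str
        Permitted residue codes; defaults to the 20 standard ones.
    """

    id: str
    residues: str
    gene: str = ""
    allele: str = ""
    alphabet: frozenset = field(
        default=STANDARD_AA, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        validate_residues(self.residues, self.alphabet, context=f"record {self.id!r}")

    @property
    def n_residues(self) -> int:
        """N, the residue count — the denominator of A = a/N."""
        return len(self.residues)

    def label(self) -> str:
        """Human-readable ``gene:allele`` (or id when metadata absent)."""
        if self.gene and self.allele:
            return f"{self.gene}:{self.allele}"
        return self.id

    def trimmed(self, n: int) -> "ProteinSequence":
        """Drop the first *n* residues (e.g. a signal peptide)."""
        if n < 0 or n >= len(self.residues):
            raise UsageError(
                f"cannot trim {n} residues from {self.id!r} of length {len(self.residues)}"
            )
        return replace(self, residues=self.residues[n:])


@dataclass(frozen=True)
class VariantEdit:
    """A single positional difference between two alleles.

    ``position`` is the 1-based index in the *reference* sequence.  For a
    substitution or deletion, ``ref_residue`` is the single reference residue
    replaced or removed.  For an insertion, ``ref_residue`` is empty and
    ``alt_residue`` (one or more residues) is inserted immediately *after*
    ``position``; position 0 prepends.
    """

    kind: str
    position: int
    ref_residue: str = ""
    alt_residue: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise UsageError(f"unknown edit kind {self.kind!r}")
        if self.kind == "substitution":
            if len(self.ref_residue) != 1 or len(self.alt_residue) != 1:
                raise UsageError("substitution needs one ref and one alt residue")
        elif self.kind == "deletion":
            if len(self.ref_residue) != 1 or self.alt_residue:
                raise UsageError("deletion needs one ref residue and no alt")
        else:  # insertion
            if self.ref_residue or not self.alt_residue:
                raise UsageError("insertion needs alt residue(s) and no ref")
        min_pos = 0 if self.kind == "insertion" else 1
        if self.position < min_pos:
            raise EditRangeError(
                f"{self.kind} position {self.position} below minimum {min_pos}"
            )


@dataclass
class AlleleSet:
    """All alleles of one gene, keyed by allele label."""

    gene: str
    reference_id: str
    alleles: dict[str, ProteinSequence]

    def __post_init__(self) -> None:
        if self.reference_id not in self.alleles:
            raise UsageError(
                f"reference {self.reference_id!r} not among alleles "
                f"{sorted(self.alleles)}"
            )
        for label, seq in self.alleles.items():
            if seq.gene != self.gene:
                raise UsageError(
                    f"allele {label!r} carries gene {seq.gene!r}, expected {self.gene!r}"
                )

    @property
    def reference(self) -> ProteinSequence:
        return self.alleles[self.reference_id]


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _parse_header_metadata(description: str) -> tuple[str, str]:
    """Extract ``gene=`` / ``allele=`` tokens from a FASTA description."""
    gene = allele = ""
    for token in description.split()[1:]:
        if token.startswith("gene="):
            gene = token[5:]
        elif token.startswith("allele="):
            allele = token[7:]
    return gene, allele


def read_fasta(
    path: str | Path, alphabet: frozenset[str] = STANDARD_AA
) -> list[ProteinSequence]:
    """Read protein FASTA into :class:`ProteinSequence` records.

    Residues are uppercased and whitespace-stripped; a terminal stop symbol
    ``*`` is removed (and logged).  Headers may carry ``gene=<g> allele=<a>``
    tokens after the identifier.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} precedes any '>' header"
                )
            break
    else:
        raise FastaParseError(f"{path}: no FASTA records found")

    out: list[ProteinSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        residues = str(record.seq).upper().replace(" ", "").replace("\t", "")
        if residues.endswith("*"):
            residues = residues[:-1]
            logger.info("stripped terminal stop symbol from record %s", record.id)
        gene, allele = _parse_header_metadata(record.description)
        validate_residues(residues, alphabet, context=f"record {record.id!r}")
        out.append(
            ProteinSequence(
                id=record.id, residues=residues, gene=gene, allele=allele,
                alphabet=alphabet,
            )
        )
    if not out:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences using the ``id gene=<g> allele=<a>`` header dialect."""
    records = []
    for seq in sequences:
        desc_parts = []
        if seq.gene:
            desc_parts.append(f"gene={seq.gene}")
        if seq.allele:
            desc_parts.append(f"allele={seq.allele}")
        records.append(
            SeqRecord(Seq(seq.residues), id=seq.id, description=" ".join(desc_parts))
        )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------

def apply_edits(
    reference: ProteinSequence,
    edits: Sequence[VariantEdit],
    new_allele: str = "",
    new_id: str = "",
) -> ProteinSequence:
    """Construct a variant by applying *edits* to *reference*.

    Edits are applied in descending position order so every position refers
    to the original reference frame.  The reference is never mutated.
    """
    chars = list(reference.residues)
    n = len(chars)
    for edit in sorted(edits, key=lambda e: e.position, reverse=True):
        p = edit.position
        if edit.kind == "insertion":
            if p > n:
                raise EditRangeError(
                    f"insertion after position {p} exceeds reference length {n}"
                )
            chars[p:p] = list(edit.alt_residue)
            continue
        if p > n:
            raise EditRangeError(
                f"{edit.kind} position {p} exceeds reference length {n}"
            )
        found = reference.residues[p - 1]
        if found != edit.ref_residue:
            raise EditConflictError(
                f"{edit.kind} at position {p}: expected {edit.ref_residue!r}, "
                f"found {found!r}"
            )
        if edit.kind == "substitution":
            chars[p - 1] = edit.alt_residue
        else:  # deletion
            del chars[p - 1]
    return ProteinSequence(
        id=new_id or f"{reference.id}|{new_allele or 'variant'}",
        residues="".join(chars),
        gene=reference.gene,
        allele=new_allele,
        alphabet=reference.alphabet,
    )


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def diff_alleles(a: ProteinSequence, b: ProteinSequence) -> list[VariantEdit]:
    """Minimal positional edit list turning *a* into *b*.

    Equal-length pairs are compared position by position (substitutions
    only).  Unequal lengths are resolved by a single-contiguous-indel
    heuristic — sufficient for the alpha-S1 F allele, whose exon loss removes
    one internal block.  Anything more complex raises
    :class:`NotComparableError` rather than silently aligning.
    """
    if a.gene != b.gene:
        raise UsageError(f"gene mismatch: {a.gene!r} vs {b.gene!r}")
    ra, rb = a.residues, b.residues
    if len(ra) == len(rb):
        return [
            VariantEdit("substitution", i + 1, ref_residue=x, alt_residue=y)
            for i, (x, y) in enumerate(zip(ra, rb))
            if x != y
        ]
    # Single contiguous indel: common prefix + common suffix must cover the
    # shorter sequence exactly.
    short, long = (ra, rb) if len(ra) < len(rb) else (rb, ra)
    d = len(long) - len(short)
    p = _common_prefix_len(short, long)
    s = _common_prefix_len(short[::-1], long[::-1])
    if p + s < len(short):
        raise NotComparableError(
            f"{a.id!r} vs {b.id!r}: sequences not comparable by a single "
            "contiguous indel; substitutions co-occur with the length change"
        )
    p = min(p, len(short) - s)  # anchor the gap at the leftmost position
    if len(ra) > len(rb):  # deletion from a
        return [
            VariantEdit("deletion", p + i + 1, ref_residue=ra[p + i])
            for i in range(d)
        ]
    return [VariantEdit("insertion", p, alt_residue=rb[p : p + d])]


# ---------------------------------------------------------------------------
# Edit-list config files
# ---------------------------------------------------------------------------

def load_edit_list(path: str | Path) -> list[VariantEdit]:
    """Load a YAML edit list.

    Expected form::

        edits:
          - {kind: substitution, position: 209, ref: T, alt: A}
          - {kind: deletion, position: 3, ref: D}
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "edits" not in doc:
        raise ConfigError(f"{path}: expected a top-level 'edits' list")
    edits = []
    for i, row in enumerate(doc["edits"]):
        try:
            edits.append(
                VariantEdit(
                    kind=row["kind"],
                    position=int(row["position"]),
                    ref_residue=str(row.get("ref", "") or ""),
                    alt_residue=str(row.get("alt", "") or ""),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: edits[{i}]: {exc}") from exc
    return edits
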