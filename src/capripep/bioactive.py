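"""Peptide -> activity database: loading, lookup and occurrence scanning.

The database maps short peptide sequences to sets of activity codes
(``ACE-I`` for angiotensin-converting-enzyme inhibition, ``DPP-IV-I`` for
dipeptidyl-peptidase-IV inhibition, and so on).  It serves two roles:

* **fragment-occurrence counting** over an intact protein, feeding the
  frequency statistic A = a/N (see :mod:`capripep.profiling`);
* **annotation** of peptides released by in silico digestion.

Matching is exact-sequence, case-sensitive over uppercase residues: no
Leu/Ile equivalence, no modified residues.  Occurrences are positional —
overlapping matches all count, and the same peptide at two positions counts
twice — which is the convention under which A sums fragments rather than
distinct sequences.

The bundled fixture database covers the 32 registered candidate peptides
from the goat-casein analysis plus the activity-code registry; it is a small
curated subset, *not* a mirror of any full bioactive-peptide database, so
profiles computed against it are comparable only within this package's
outputs.  Users can supply their own TSV of any size in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .errors import FormatError, UsageError, ValidationError
from .sequences import STANDARD_AA, ProteinSequence


class ActivityLabel(NamedTuple):
    code: str
    description: str


class FragmentOccurrence(NamedTuple):
    """One positional match of a database peptide inside a protein."""

    peptide: str
    activity: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass
class BioactiveDB:
    """Map peptide sequence -> set of activity codes."""

    records: dict
    registry: dict = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for peptide, codes in self.records.items():
            if len(peptide) < 2:
                raise ValidationError(
                    f"database peptide {peptide!r} shorter than 2 residues"
                )
            bad = set(peptide) - STANDARD_AA
            if bad:
                raise ValidationError(
                    f"database peptide {peptide!r} has invalid residues {sorted(bad)}"
                )
            self.records[peptide] = frozenset(codes)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def activities(self) -> list[str]:
        """All activity codes present in the records, sorted."""
        out: set[str] = set()
        for codes in self.records.values():
            out |= codes
        return sorted(out)

    def lookup(self, peptide: str) -> frozenset:
        """Activity codes for an exact peptide match; empty set if absent."""
        if not peptide:
            raise UsageError("lookup of an empty peptide")
        return self.records.get(peptide, frozenset())


def lookup(db: BioactiveDB, peptide: str) -> frozenset:
    return db.lookup(peptide)


def load_peptide_db(
    path: str | Path,
    registry: Optional[dict] = None,
) -> BioactiveDB:
    """Load a peptide database TSV with columns ``peptide``, ``activity_code``
    (one row per peptide-activity pair; optional ``description``,
    ``reference`` columns ignored for matching).  Duplicate rows collapse.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"peptide", "activity_code"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: dict[str, set] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        peptide = (row.peptide or "").strip().upper()
        code = (row.activity_code or "").strip()
        if not peptide or not code:
            raise ValidationError(f"{path}: row {row_no}: empty peptide or code")
        bad = set(peptide) - STANDARD_AA
        if bad:
            raise ValidationError(
                f"{path}: row {row_no}: invalid residues {sorted(bad)} in {peptide!r}"
            )
        records.setdefault(peptide, set()).add(code)
    return BioactiveDB(
        records={p: frozenset(c) for p, c in records.items()},
        registry=registry or {},
        source=str(path),
    )


def load_activity_registry(path: str | Path) -> dict:
    """Load the activity-code registry TSV (columns ``code``, ``description``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"code", "description"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    registry: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.code in registry:
            raise ValidationError(f"{path}: duplicate activity code {row.code!r}")
        registry[row.code] = row.description
    return registry


def default_registry() -> dict:
    """The bundled activity-code registry."""
    ref = resources.files("capripep.data") / "activity_registry.tsv"
    with resources.as_file(ref) as path:
        return load_activity_registry(path)


def default_peptide_db() -> BioactiveDB:
    """The bundled goat-casein candidate-peptide database (curated subset)."""
    from .pipeline import load_candidate_table  # local import avoids a cycle

    ref = resources.files("capripep.data") / "goat_casein_candidates.tsv"
    with resources.as_file(ref) as path:
        table = load_candidate_table(path)
    records = {
        row.peptide: frozenset(row.activities)
        for row in table
        if row.activities
    }
    return BioactiveDB(records=records, registry=default_registry(),
                       source="bundled goat-casein candidate subset")


def find_occurrences(
    seq: ProteinSequence,
    db: BioactiveDB,
    activity: Optional[str] = None,
) -> list[FragmentOccurrence]:
    """Every positional match of every database peptide within *seq*.

    One :class:`FragmentOccurrence` per (peptide, activity, start) triple;
    overlapping matches all count.  Restricted to one activity code when
    *activity* is given.  Sorted by start position, then peptide.
    """
    if not seq.residues:
        raise UsageError("cannot scan an empty sequence")
    if activity is not None and db.registry:
        # without a registry an unseen code is indistinguishable from a
        # zero-occurrence one, so validation applies only when one exists
        if activity not in set(db.registry) | set(db.activities()):
            raise UsageError(f"unknown activity code {activity!r}")
    residues = seq.residues
    hits: list[FragmentOccurrence] = []
    for peptide, codes in db.records.items():
        if activity is not None:
            codes = codes & {activity}
            if not codes:
                continue
        k = len(peptide)
        pos = residues.find(peptide)
        while pos != -1:
            for code in sorted(codes):
                hits.append(FragmentOccurrence(peptide, code, pos + 1, pos + k))
            pos = residues.find(peptide, pos + 1)
    hits.sort(key=lambda h: (h.start, h.peptide, h.activity))
    return hits


def write_db_tsv(db: BioactiveDB, path: str | Path) -> None:
    """Serialize the records to the canonical peptide/activity_code TSV."""
    rows = [
        {"peptide": p, "activity_code": c}
        for p in sorted(db.records)
        for c in sorted(db.records[p])
    ]
    pd.DataFrame(rows, columns=["peptide", "activity_code"]).to_csv(
        path, sep="\t", index=False
    )
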