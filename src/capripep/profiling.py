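"""Bioactive-fragment frequency statistics and the allele x activity matrix.

The frequency of occurrence of bioactive fragments with a given activity in
a protein is

    A = a / N

where ``a`` counts positional occurrences of database fragments carrying
that activity within the protein and ``N`` is the protein's residue count.
The unweighted sum of A over all activities, written sigma-A here, is the
protein's overall bioactive potential: a larger value means more bioactive
fragments per residue.  Both are dimensionless and depend on the database
used — values computed against different databases are not comparable.

Separately, released-and-filtered peptides are annotated with their activity
sets and aggregated into a :class:`BioactivityMatrix` (alleles x activities,
integer counts of distinct peptide sequences), the quantitative content of a
bioactivity heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .bioactive import BioactiveDB, find_occurrences
from .digestion import Fragment
from .errors import UsageError
from .sequences import ProteinSequence


@dataclass(frozen=True)
class ActivityProfile:
    """Per-activity A values and their sum for one sequence."""

    sequence_id: str
    A_by_activity: dict
    sigma_A: float
    N: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sequence_id": self.sequence_id, "activity": act, "A": a}
                for act, a in sorted(self.A_by_activity.items())
            ],
            columns=["sequence_id", "activity", "A"],
        )


class AnnotatedPeptide(NamedTuple):
    """A released peptide with its activity annotation.

    ``registered`` is False for peptides absent from the database — they are
    retained (a filter can pass peptides the database has never seen) but
    flagged, mirroring unregistered candidates in published tables.
    """

    peptide: str
    start: Optional[int]
    end: Optional[int]
    activities: frozenset

    @property
    def registered(self) -> bool:
        return bool(self.activities)


def compute_A(seq: ProteinSequence, db: BioactiveDB, activity: str) -> float:
    """A = a/N for one activity: positional fragment count over residue count."""
    if seq.n_residues < 1:
        raise UsageError("sequence must have at least one residue")
    hits = find_occurrences(seq, db, activity=activity)
    return len(hits) / seq.n_residues


def compute_profile(seq: ProteinSequence, db: BioactiveDB) -> ActivityProfile:
    """A per activity over the whole database, plus sigma-A.

    Activities with zero occurrences are omitted from the map (they are
    exact zeros); sigma-A is the sum of the retained values.
    """
    if seq.n_residues < 1:
        raise UsageError("sequence must have at least one residue")
    counts: dict[str, int] = {}
    for hit in find_occurrences(seq, db):
        counts[hit.activity] = counts.get(hit.activity, 0) + 1
    n = seq.n_residues
    A_by_activity = {act: c / n for act, c in counts.items()}
    return ActivityProfile(
        sequence_id=seq.id,
        A_by_activity=A_by_activity,
        sigma_A=sum(A_by_activity.values()),
        N=n,
    )


def annotate_peptides(
    peptides: Iterable[Union[str, Fragment]],
    db: BioactiveDB,
) -> list[AnnotatedPeptide]:
    """Attach activity sets to released peptides.

    Accepts plain sequences or coordinate-tracked :class:`Fragment` records.
    Unregistered peptides (empty activity set) are retained and flagged via
    :attr:`AnnotatedPeptide.registered`.
    """
    out: list[AnnotatedPeptide] = []
    for item in peptides:
        if isinstance(item, str):
            pep, start, end = item, None, None
        else:
            pep, start, end = item.sequence, item.start, item.end
        out.append(AnnotatedPeptide(pep, start, end, db.lookup(pep)))
    return out


@dataclass
class BioactivityMatrix:
    """Alleles x activities count matrix.

    Each cell counts *distinct peptide sequences* of that allele annotated
    with that activity: two alleles releasing the same peptide at different
    positions contribute equally, and a duplicate release within one allele
    counts once.
    """

    table: pd.DataFrame  # int counts, index=allele labels, columns=activity codes

    def cell(self, allele: str, activity: str) -> int:
        return int(self.table.loc[allele, activity])

    def row_sums(self) -> pd.Series:
        return self.table.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="allele")

    def to_long(self) -> pd.DataFrame:
        """Long format (allele, activity, count) for plotting."""
        long = (
            self.table.reset_index(names="allele")
            .melt(id_vars="allele", var_name="activity", value_name="count")
            .sort_values(["allele", "activity"], kind="stable")
            .reset_index(drop=True)
        )
        return long


def build_matrix(
    annotations_by_allele: dict,
    registry: Optional[Sequence[str]] = None,
) -> BioactivityMatrix:
    """Aggregate per-allele annotations into the bioactivity matrix.

    Parameters
    ----------
    annotations_by_allele : dict
        Allele label -> list of :class:`AnnotatedPeptide`.
    registry : sequence of activity codes, optional
        Fixed column set (zero columns kept, e.g. for heatmaps where white
        means absent activity).  Defaults to the codes observed in the input.
    """
    if not annotations_by_allele:
        raise UsageError("at least one allele required")
    observed: set[str] = set()
    per_allele_sets: dict[str, dict[str, set]] = {}
    for allele, annotations in annotations_by_allele.items():
        by_activity: dict[str, set] = {}
        seen: set[str] = set()
        for ann in annotations:
            if ann.peptide in seen:
                continue  # distinct peptide sequences only
            seen.add(ann.peptide)
            for code in ann.activities:
                by_activity.setdefault(code, set()).add(ann.peptide)
        per_allele_sets[allele] = by_activity
        observed |= set(by_activity)
    columns = list(registry) if registry is not None else sorted(observed)
    unknown = observed - set(columns)
    if unknown:
        raise UsageError(
            f"activities {sorted(unknown)} observed but absent from the registry"
        )
    rows = sorted(per_allele_sets)
    data = [
        [len(per_allele_sets[r].get(c, ())) for c in columns] for r in rows
    ]
    table = pd.DataFrame(data, index=rows, columns=columns, dtype=int)
    return BioactivityMatrix(table=table)


def write_profiles_tsv(
    profiles: Sequence[ActivityProfile], per_activity_path: str | Path,
    summary_path: str | Path,
) -> None:
    """Write per-activity A values and a sigma-A summary.

    Values are written to 4 decimal places to match common reporting of
    sigma-A; full precision is retained in memory.
    """
    frames = [p.to_frame() for p in profiles]
    per_activity = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["sequence_id", "activity", "A"])
    )
    per_activity.to_csv(per_activity_path, sep="\t", index=False,
                        float_format="%.4f")
    summary = pd.DataFrame(
        [
            {"sequence_id": p.sequence_id, "sigma_A": p.sigma_A, "N": p.N}
            for p in profiles
        ],
        columns=["sequence_id", "sigma_A", "N"],
    )
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.4f")
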