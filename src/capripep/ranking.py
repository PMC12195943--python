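"""Bioactivity-likelihood filtering of released peptides.

An external predictor assigns each peptide a score in [0, 1]; a score above
0.5 is conventionally read as "probably bioactive".  That predictor is out
of scope here — scores enter only through a TSV (``peptide``, ``score``),
and a deliberately simple heuristic scorer is provided for synthetic tests.

Filtering keeps peptides inside a length window (default 2-6 residues, the
range in which database fragments are dense and predictor scores are
meaningful) whose score clears the threshold (default strictly greater than
0.5).  Peptides missing from the score map are excluded by default — and
counted, so their absence is visible — rather than silently scored zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Union

import pandas as pd

from .digestion import DigestResult, Fragment
from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

STRICT_GREATER = "strict-greater"
GREATER_EQUAL = "greater-or-equal"


@dataclass(frozen=True)
class FilterPolicy:
    """Threshold + length window + tie and missing-score behaviour."""

    threshold: float = 0.5
    min_length: int = 2
    max_length: int = 6
    keep_rule: str = STRICT_GREATER
    missing_score: str = "exclude"  # or "zero"

    def __post_init__(self) -> None:
        if not 1 <= self.min_length <= self.max_length:
            raise UsageError(
                f"invalid length window [{self.min_length}, {self.max_length}]"
            )
        if self.keep_rule not in (STRICT_GREATER, GREATER_EQUAL):
            raise UsageError(f"unknown keep_rule {self.keep_rule!r}")
        if self.missing_score not in ("exclude", "zero"):
            raise UsageError(f"unknown missing_score policy {self.missing_score!r}")

    def passes_score(self, score: float) -> bool:
        if self.keep_rule == STRICT_GREATER:
            return score > self.threshold
        return score >= self.threshold

    def passes_length(self, peptide: str) -> bool:
        return self.min_length <= len(peptide) <= self.max_length


class Candidate(NamedTuple):
    """A retained peptide, deduplicated by sequence.

    ``positions`` lists every (start, end) at which the sequence was
    released; empty when the input carried no coordinates.
    """

    peptide: str
    score: float
    positions: tuple


def load_scores(path: str | Path) -> dict:
    """Load a peptide-score TSV (columns ``peptide``, ``score``).

    Duplicate peptides must agree within 1e-9; scores must lie in [0, 1].
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    missing = {"peptide", "score"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    scores: dict[str, float] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        peptide = (row.peptide or "").strip().upper()
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: row {row_no}: non-numeric score {row.score!r}"
            ) from None
        if not (0.0 <= score <= 1.0) or math.isnan(score):
            raise ValidationError(
                f"{path}: row {row_no}: score {score} outside [0, 1]"
            )
        if peptide in scores and abs(scores[peptide] - score) > 1e-9:
            raise ValidationError(
                f"{path}: row {row_no}: conflicting scores for {peptide!r}: "
                f"{scores[peptide]} vs {score}"
            )
        scores[peptide] = score
    return scores


def write_scores_tsv(scores: dict, path: str | Path) -> None:
    pd.DataFrame(
        [{"peptide": p, "score": s} for p, s in sorted(scores.items())],
        columns=["peptide", "score"],
    ).to_csv(path, sep="\t", index=False)


def filter_candidates(
    digest: Union[DigestResult, Iterable[Union[str, Fragment]]],
    scores: dict,
    policy: Optional[FilterPolicy] = None,
) -> list[Candidate]:
    """Apply the length window and score threshold to released peptides.

    Accepts a :class:`DigestResult` or any iterable of fragments/sequences.
    Output is deduplicated by peptide sequence (first-appearance order) with
    all release positions preserved.
    """
    policy = policy or FilterPolicy()
    fragments = digest.peptides if isinstance(digest, DigestResult) else digest
    by_sequence: dict[str, list] = {}
    for item in fragments:
        if isinstance(item, str):
            pep, pos = item, None
        else:
            pep, pos = item.sequence, (item.start, item.end)
        by_sequence.setdefault(pep, []).append(pos)
    out: list[Candidate] = []
    n_missing = 0
    for pep, positions in by_sequence.items():
        if not policy.passes_length(pep):
            continue
        if pep in scores:
            score = scores[pep]
        elif policy.missing_score == "zero":
            score = 0.0
        else:
            n_missing += 1
            continue
        if policy.passes_score(score):
            out.append(
                Candidate(
                    peptide=pep,
                    score=score,
                    positions=tuple(p for p in positions if p is not None),
                )
            )
    if n_missing:
        logger.info("%d length-eligible peptides had no score and were excluded",
                    n_missing)
    return out


def heuristic_score(peptide: str) -> float:
    """A trivial composition-based stand-in scorer for synthetic tests.

    Fraction of proline/aromatic residues with a mild length penalty —
    deterministic, bounded in [0, 1], and **not** equivalent to any trained
    bioactivity predictor.  Useful only to exercise the filter plumbing.
    """
    if not peptide:
        raise UsageError("cannot score an empty peptide")
    favored = sum(1 for ch in peptide if ch in "PWYF")
    return (favored / len(peptide)) * (1.0 - 0.02 * min(len(peptide), 20))
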