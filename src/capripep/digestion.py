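"""Cleavage-rule engine and in silico proteolysis.

Enzyme specificity is declarative: each :class:`CleavageRule` names a target
residue, the side of the scissile bond relative to it (C-terminal = cut
after the residue, N-terminal = cut before it), and an optional set of
residues on the distal side that block the cut (e.g. trypsin rarely cleaves
Lys-Pro bonds).

Simultaneous multi-enzyme digestion is modelled as the union of all cut
sites ("one-pot" digestion).  Two release modes are provided:

``complete``
    Every site is cut; the released peptides partition the protein.
``partial``
    Every substring bounded by any two boundaries (sequence ends or cut
    sites) is released — the superset that models overlapping peptides from
    successive cleavage events.

The default enzyme table encodes the gastric/pancreatic trio used for milk
protein digestion simulations: pepsin (EC 3.4.23.1, C-terminal after F, L),
trypsin (EC 3.4.21.4, C-terminal after K, R) and chymotrypsin A
(EC 3.4.21.1, C-terminal after Y, W, F, L, N, H, M and N-terminal before I).
Published specificity tables for these enzymes are longer than any short
summary; the table is therefore ordinary user-editable config, and exact
fragment counts from other platforms may require their full tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import yaml

from .errors import ConfigError, UsageError
from .sequences import STANDARD_AA, ProteinSequence

C_TERMINAL = "C-terminal"
N_TERMINAL = "N-terminal"
_SIDE_ALIASES = {
    "c": C_TERMINAL, "c-terminal": C_TERMINAL, "cterm": C_TERMINAL,
    "n": N_TERMINAL, "n-terminal": N_TERMINAL, "nterm": N_TERMINAL,
}


def _normalize_side(side: str) -> str:
    try:
        return _SIDE_ALIASES[side.strip().lower()]
    except KeyError:
        raise ConfigError(f"unknown cleavage side {side!r}") from None


@dataclass(frozen=True)
class CleavageRule:
    """One specificity rule: cut on *side* of *target_residue* unless the
    residue across the bond is in *blocked_by_next*."""

    target_residue: str
    side: str
    blocked_by_next: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", _normalize_side(self.side))
        object.__setattr__(self, "blocked_by_next", frozenset(self.blocked_by_next))
        if self.target_residue not in STANDARD_AA:
            raise ConfigError(f"invalid target residue {self.target_residue!r}")
        bad = self.blocked_by_next - STANDARD_AA
        if bad:
            raise ConfigError(f"invalid blocking residues {sorted(bad)}")


@dataclass(frozen=True)
class Enzyme:
    """A named protease with a nonempty list of cleavage rules."""

    name: str
    ec_number: str
    rules: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if not self.rules:
            raise ConfigError(f"enzyme {self.name!r} has an empty rule list")
        seen = set()
        for rule in self.rules:
            key = (rule.target_residue, rule.side)
            if key in seen:
                raise ConfigError(
                    f"enzyme {self.name!r}: duplicate rule for {key}"
                )
            seen.add(key)


class Fragment(NamedTuple):
    """A released peptide with 1-based inclusive coordinates in its source."""

    sequence: str
    start: int
    end: int


@dataclass(frozen=True)
class DigestResult:
    """Peptides released from one sequence by a set of enzymes."""

    source_id: str
    enzymes: tuple
    mode: str
    cut_sites: tuple
    peptides: tuple

    @property
    def n_intervals(self) -> int:
        """Distinct (start, end) fragments."""
        return len(self.peptides)

    @property
    def n_distinct_sequences(self) -> int:
        return len({p.sequence for p in self.peptides})

    def sequences(self) -> list[str]:
        """Distinct released peptide sequences, in order of first appearance."""
        return list(dict.fromkeys(p.sequence for p in self.peptides))


def cut_sites(seq: ProteinSequence, enzymes: Iterable[Enzyme]) -> list[int]:
    """Union of inter-residue cut positions over all rules of all enzymes.

    A site ``p`` (0 < p < N) is a cut between residues p and p+1 in 1-based
    terms.  Rules matching a terminal residue never cut (a fragment must be
    nonempty).
    """
    residues = seq.residues
    n = len(residues)
    if n == 0:
        raise UsageError("cannot digest an empty sequence")
    sites: set[int] = set()
    for enzyme in enzymes:
        for rule in enzyme.rules:
            target, blocked = rule.target_residue, rule.blocked_by_next
            for i0, res in enumerate(residues):
                i = i0 + 1  # 1-based
                if res != target:
                    continue
                if rule.side == C_TERMINAL:
                    if i < n and residues[i0 + 1] not in blocked:
                        sites.add(i)
                else:  # N-terminal: cut before the target
                    if i > 1 and residues[i0 - 1] not in blocked:
                        sites.add(i - 1)
    return sorted(sites)


def digest(
    seq: ProteinSequence,
    enzymes: Sequence[Enzyme],
    mode: str = "complete",
) -> DigestResult:
    """Release peptides from *seq* under simultaneous action of *enzymes*."""
    if mode not in ("complete", "partial"):
        raise UsageError(f"unknown digestion mode {mode!r}")
    sites = cut_sites(seq, enzymes)
    n = len(seq.residues)
    boundaries = [0, *sites, n]
    fragments: list[Fragment] = []
    if mode == "complete":
        for lo, hi in zip(boundaries, boundaries[1:]):
            fragments.append(Fragment(seq.residues[lo:hi], lo + 1, hi))
    else:
        for i, lo in enumerate(boundaries):
            for hi in boundaries[i + 1 :]:
                fragments.append(Fragment(seq.residues[lo:hi], lo + 1, hi))
        fragments.sort(key=lambda f: (f.start, f.end))
    return DigestResult(
        source_id=seq.id,
        enzymes=tuple(e.name for e in enzymes),
        mode=mode,
        cut_sites=tuple(sites),
        peptides=tuple(fragments),
    )


# ---------------------------------------------------------------------------
# Enzyme table config
# ---------------------------------------------------------------------------

def load_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Load enzymes from a YAML config.

    Expected form::

        enzymes:
          - name: trypsin
            ec: 3.4.21.4
            rules:
              - {residue: K, side: C-terminal, blocked_by_next: [P]}
              - {residue: R, side: C-terminal}
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "enzymes" not in doc:
        raise ConfigError(f"{path}: expected a top-level 'enzymes' list")
    enzymes = []
    for i, entry in enumerate(doc["enzymes"]):
        keypath = f"enzymes[{i}]"
        try:
            name = entry["name"]
            rules = [
                CleavageRule(
                    target_residue=r["residue"],
                    side=r["side"],
                    blocked_by_next=frozenset(r.get("blocked_by_next", []) or []),
                )
                for r in entry.get("rules", [])
            ]
            enzymes.append(Enzyme(name=name, ec_number=str(entry.get("ec", "")), rules=tuple(rules)))
        except ConfigError as exc:
            raise ConfigError(f"{path}: {keypath}: {exc}") from exc
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: {keypath}: missing or bad key {exc}") from exc
    return enzymes


def default_enzymes() -> list[Enzyme]:
    """The bundled pepsin/trypsin/chymotrypsin A table."""
    ref = resources.files("capripep.data") / "enzymes_default.yaml"
    with resources.as_file(ref) as path:
        return load_enzyme_table(path)
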