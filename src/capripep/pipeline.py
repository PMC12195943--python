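"""End-to-end orchestration: sequences -> variants -> digestion -> filter ->
annotation -> profiles and bioactivity matrix.

Two entry points:

:func:`run_pipeline`
    The full workflow over FASTA input, edit-list configs, an enzyme table,
    a peptide database and a score table, writing TSV reports plus a JSON
    run manifest with stage counts.  Outputs are deterministically ordered,
    so identical inputs give byte-identical files.

:func:`replay_candidates`
    A replay mode that starts from a precomputed candidate-peptide table
    (sequence, score, activities, per-allele release marks) instead of
    digesting accessions.  The bundled table for goat casein alleles allows
    the downstream filter/annotate/matrix stages to be exercised — and their
    published summary counts reproduced — entirely offline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional

import pandas as pd

from . import __version__ as _pkg_version
from .bioactive import (
    BioactiveDB,
    default_peptide_db,
    default_registry,
    load_activity_registry,
    load_peptide_db,
)
from .digestion import DigestResult, default_enzymes, digest, load_enzyme_table
from .errors import ConfigError, FormatError, ValidationError
from .profiling import (
    AnnotatedPeptide,
    BioactivityMatrix,
    annotate_peptides,
    build_matrix,
    compute_profile,
    write_profiles_tsv,
)
from .ranking import FilterPolicy, filter_candidates, load_scores
from .sequences import (
    ProteinSequence,
    apply_edits,
    load_edit_list,
    read_fasta,
)

import yaml


# ---------------------------------------------------------------------------
# Candidate table (replay input)
# ---------------------------------------------------------------------------

class CandidateRow(NamedTuple):
    """One row of a candidate-peptide table.

    ``alleles`` is a frozenset of (gene, allele) pairs in which the peptide
    was released; ``activities`` is empty for peptides not registered in the
    reference database (shown as "-" in published tables).
    """

    peptide: str
    score: float
    activities: frozenset
    alleles: frozenset

    @property
    def registered(self) -> bool:
        return bool(self.activities)

    @property
    def multifunctional(self) -> bool:
        return len(self.activities) >= 2


def _parse_allele_marks(spec: str, context: str) -> frozenset:
    pairs: set[tuple[str, str]] = set()
    for segment in spec.split("|"):
        segment = segment.strip()
        if not segment:
            continue
        if ":" not in segment:
            raise FormatError(f"{context}: bad allele segment {segment!r}")
        gene, alleles = segment.split(":", 1)
        for allele in alleles.split(","):
            allele = allele.strip()
            if allele:
                pairs.add((gene.strip(), allele))
    if not pairs:
        raise FormatError(f"{context}: no allele marks")
    return frozenset(pairs)


def load_candidate_table(path: str | Path) -> list[CandidateRow]:
    """Read a candidate table TSV with columns ``peptide``, ``score``,
    ``activities`` (";"-separated codes, "-" for unregistered) and
    ``alleles`` ("GENE:A,B|GENE2:C" release marks)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"peptide", "score", "activities", "alleles"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rows: list[CandidateRow] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        context = f"{path}: row {row_no}"
        acts = (row.activities or "").strip()
        activities = frozenset(
            a.strip() for a in acts.split(";") if a.strip() and a.strip() != "-"
        ) if acts not in ("", "-") else frozenset()
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ValidationError(f"{context}: non-numeric score") from None
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"{context}: score {score} outside [0, 1]")
        rows.append(
            CandidateRow(
                peptide=row.peptide.strip().upper(),
                score=score,
                activities=activities,
                alleles=_parse_allele_marks(row.alleles, context),
            )
        )
    return rows


def default_candidate_table() -> list[CandidateRow]:
    """The bundled goat-casein candidate table."""
    ref = resources.files("capripep.data") / "goat_casein_candidates.tsv"
    with resources.as_file(ref) as path:
        return load_candidate_table(path)


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------

@dataclass
class ReplayResult:
    """Filter/annotate/matrix outcome of a candidate-table replay."""

    candidates: list
    per_gene_counts: dict        # gene -> peptide count (any allele of the gene)
    per_allele_counts: dict      # (gene, allele) -> peptide count
    allele_specific: dict        # gene -> {peptide: allele} (single-allele releases)
    matrix: BioactivityMatrix    # rows "gene:allele" x activity codes

    @property
    def total_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_registered(self) -> int:
        return sum(1 for c in self.candidates if c.registered)

    @property
    def n_multifunctional(self) -> int:
        return sum(1 for c in self.candidates if c.multifunctional)


def replay_candidates(
    table: list,
    policy: Optional[FilterPolicy] = None,
    registry: Optional[dict] = None,
) -> ReplayResult:
    """Apply the score/length filter to a candidate table and aggregate.

    Per-gene and per-allele counts include unregistered peptides (a released
    candidate without a database entry is still a released candidate); the
    bioactivity matrix counts only annotated (registered) ones, since an
    unregistered peptide contributes no activity.
    """
    policy = policy or FilterPolicy()
    registry = registry if registry is not None else default_registry()
    kept = [
        row
        for row in table
        if policy.passes_length(row.peptide) and policy.passes_score(row.score)
    ]
    genes = sorted({g for row in kept for g, _ in row.alleles})
    per_gene = {
        g: sum(1 for row in kept if any(gg == g for gg, _ in row.alleles))
        for g in genes
    }
    allele_keys = sorted({ga for row in kept for ga in row.alleles})
    per_allele = {
        ga: sum(1 for row in kept if ga in row.alleles) for ga in allele_keys
    }
    allele_specific: dict[str, dict[str, str]] = {}
    for row in kept:
        for gene in {g for g, _ in row.alleles}:
            marks = [a for g, a in row.alleles if g == gene]
            if len(marks) == 1:
                allele_specific.setdefault(gene, {})[row.peptide] = marks[0]
    annotations: dict[str, list[AnnotatedPeptide]] = {}
    for gene, allele in allele_keys:
        label = f"{gene}:{allele}"
        annotations[label] = [
            AnnotatedPeptide(row.peptide, None, None, row.activities)
            for row in kept
            if (gene, allele) in row.alleles
        ]
    matrix = build_matrix(annotations, registry=sorted(registry))
    return ReplayResult(
        candidates=kept,
        per_gene_counts=per_gene,
        per_allele_counts=per_allele,
        allele_specific=allele_specific,
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and knobs for one full run.  All paths are validated before
    any computation starts."""

    fasta_paths: list
    outdir: Path
    edit_list_paths: list = field(default_factory=list)
    enzyme_table_path: Optional[Path] = None
    db_path: Optional[Path] = None
    registry_path: Optional[Path] = None
    scores_path: Optional[Path] = None
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    mode: str = "complete"
    signal_peptide_trim: int = 0

    def validate(self) -> None:
        for p in [*self.fasta_paths, *self.edit_list_paths,
                  self.enzyme_table_path, self.db_path, self.registry_path,
                  self.scores_path]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.mode not in ("complete", "partial"):
            raise ConfigError(f"unknown digestion mode {self.mode!r}")
        if self.signal_peptide_trim < 0:
            raise ConfigError("signal_peptide_trim must be >= 0")
        Path(self.outdir).mkdir(parents=True, exist_ok=True)

    def digest_hash(self) -> str:
        payload = json.dumps(
            {
                "fasta": [str(p) for p in self.fasta_paths],
                "edits": [str(p) for p in self.edit_list_paths],
                "enzymes": str(self.enzyme_table_path),
                "db": str(self.db_path),
                "registry": str(self.registry_path),
                "scores": str(self.scores_path),
                "policy": vars(self.policy) if hasattr(self.policy, "__dict__")
                else {
                    "threshold": self.policy.threshold,
                    "min_length": self.policy.min_length,
                    "max_length": self.policy.max_length,
                    "keep_rule": self.policy.keep_rule,
                    "missing_score": self.policy.missing_score,
                },
                "mode": self.mode,
                "trim": self.signal_peptide_trim,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """In-memory results of a full run, mirroring the files written."""

    sequences: list
    digests: dict          # label -> DigestResult
    candidates: dict       # label -> list of Candidate
    annotations: dict      # label -> list of AnnotatedPeptide
    profiles: list
    matrix: BioactivityMatrix
    allele_specific: dict  # gene -> {peptide: allele}
    manifest: dict


def _load_edit_config(path: Path) -> tuple[str, str, str, list]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping")
    for key in ("reference", "allele"):
        if key not in doc:
            raise ConfigError(f"{path}: missing key {key!r}")
    return (
        str(doc.get("gene", "")),
        str(doc["reference"]),
        str(doc["allele"]),
        load_edit_list(path),
    )


def _allele_specific_peptides(candidate_sets: dict) -> dict:
    """Peptides released in exactly one allele of a gene.

    ``candidate_sets`` maps (gene, allele) -> set of peptide sequences.
    """
    out: dict[str, dict[str, str]] = {}
    genes = sorted({g for g, _ in candidate_sets})
    for gene in genes:
        members = {a: s for (g, a), s in candidate_sets.items() if g == gene}
        if len(members) < 2:
            continue
        for allele, peptides in members.items():
            others = set().union(
                *(s for a, s in members.items() if a != allele)
            )
            for pep in sorted(peptides - others):
                out.setdefault(gene, {})[pep] = allele
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow and write the report bundle to
    ``config.outdir``.  Raises a stage-named error on any failure."""
    config.validate()
    outdir = Path(config.outdir)

    # --- load sequences -----------------------------------------------------
    sequences: list[ProteinSequence] = []
    for path in config.fasta_paths:
        sequences.extend(read_fasta(path))
    if config.signal_peptide_trim:
        sequences = [s.trimmed(config.signal_peptide_trim) for s in sequences]
    by_id = {s.id: s for s in sequences}

    # --- construct variants -------------------------------------------------
    for path in config.edit_list_paths:
        gene, ref_id, allele, edits = _load_edit_config(Path(path))
        if ref_id not in by_id:
            raise ConfigError(
                f"{path}: reference {ref_id!r} not among loaded sequences"
            )
        variant = apply_edits(by_id[ref_id], edits, new_allele=allele,
                              new_id=f"{ref_id}|{allele}")
        sequences.append(variant)
        by_id[variant.id] = variant

    # --- digest -------------------------------------------------------------
    enzymes = (
        load_enzyme_table(config.enzyme_table_path)
        if config.enzyme_table_path
        else default_enzymes()
    )
    digests = {s.label(): digest(s, enzymes, mode=config.mode) for s in sequences}

    # --- database + profiles ------------------------------------------------
    registry = (
        load_activity_registry(config.registry_path)
        if config.registry_path
        else default_registry()
    )
    db = (
        load_peptide_db(config.db_path, registry=registry)
        if config.db_path
        else default_peptide_db()
    )
    profiles = [compute_profile(s, db) for s in sequences]

    # --- filter + annotate --------------------------------------------------
    scores = load_scores(config.scores_path) if config.scores_path else {}
    candidates = {
        label: filter_candidates(result, scores, config.policy)
        for label, result in digests.items()
    }
    annotations = {
        label: annotate_peptides([c.peptide for c in cands], db)
        for label, cands in candidates.items()
    }
    registry_codes = sorted(set(registry) | set(db.activities()))
    matrix = build_matrix(annotations, registry=registry_codes)

    candidate_sets = {
        (s.gene or s.id, s.allele or s.id): {c.peptide for c in candidates[s.label()]}
        for s in sequences
    }
    allele_specific = _allele_specific_peptides(candidate_sets)

    # --- write bundle -------------------------------------------------------
    label_of = {s.label(): s for s in sequences}
    digest_rows = [
        {
            "source_id": label_of[label].id,
            "gene": label_of[label].gene,
            "allele": label_of[label].allele,
            "peptide": frag.sequence,
            "start": frag.start,
            "end": frag.end,
            "length": len(frag.sequence),
        }
        for label in sorted(digests)
        for frag in digests[label].peptides
    ]
    pd.DataFrame(
        digest_rows,
        columns=["source_id", "gene", "allele", "peptide", "start", "end", "length"],
    ).to_csv(outdir / "digest.tsv", sep="\t", index=False)

    cand_rows = [
        {
            "label": label,
            "peptide": c.peptide,
            "score": c.score,
            "positions": ";".join(f"{a}-{b}" for a, b in c.positions),
        }
        for label in sorted(candidates)
        for c in sorted(candidates[label], key=lambda c: c.peptide)
    ]
    pd.DataFrame(
        cand_rows, columns=["label", "peptide", "score", "positions"]
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    ann_rows = [
        {
            "label": label,
            "peptide": a.peptide,
            "registered": a.registered,
            "activities": ";".join(sorted(a.activities)) or "-",
        }
        for label in sorted(annotations)
        for a in sorted(annotations[label], key=lambda a: a.peptide)
    ]
    pd.DataFrame(
        ann_rows, columns=["label", "peptide", "registered", "activities"]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    write_profiles_tsv(profiles, outdir / "profiles.tsv", outdir / "sigma_A.tsv")
    matrix.to_tsv(outdir / "matrix.tsv")
    matrix.to_long().to_csv(outdir / "matrix_long.tsv", sep="\t", index=False)

    spec_rows = [
        {"gene": gene, "peptide": pep, "allele": allele}
        for gene in sorted(allele_specific)
        for pep, allele in sorted(allele_specific[gene].items())
    ]
    pd.DataFrame(
        spec_rows, columns=["gene", "peptide", "allele"]
    ).to_csv(outdir / "allele_specific.tsv", sep="\t", index=False)

    manifest = {
        "package_version": _pkg_version,
        "config_hash": config.digest_hash(),
        "mode": config.mode,
        "signal_peptide_trim": config.signal_peptide_trim,
        "n_sequences": len(sequences),
        "n_enzymes": len(enzymes),
        "db_records": db.n_records,
        "counts": {
            label: {
                "cut_sites": len(digests[label].cut_sites),
                "fragments_intervals": digests[label].n_intervals,
                "fragments_distinct": digests[label].n_distinct_sequences,
                "candidates": len(candidates[label]),
                "annotated_registered": sum(
                    1 for a in annotations[label] if a.registered
                ),
            }
            for label in sorted(digests)
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    return PipelineReport(
        sequences=sequences,
        digests=digests,
        candidates=candidates,
        annotations=annotations,
        profiles=profiles,
        matrix=matrix,
        allele_specific=allele_specific,
        manifest=manifest,
    )
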