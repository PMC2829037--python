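"""Staged homology filtering of a focal proteome into lineage-specificity sets.

The pipeline classifies every protein-coding gene of a focal species into one
of three mutually exclusive sets:

* **EC** (evolutionarily conserved): a significant hit (E < 1e-5) to any
  sequence outside the focal clade;
* **CLADE_SPECIFIC**: no hit outside the clade, but a hit to a within-clade
  transcript database;
* **SPECIES_SPECIFIC**: no significant hit anywhere outside the focal
  species.

Stage 1 searches outside-clade genomic and transcript databases; stage 2
searches within-clade transcript assemblies; stage 3 rescreens the two
lineage-specific sets against a protein knowledgebase whose records carry
clade-membership taxonomy, transferring false positives outward (toward
broader conservation) via an auditable list of reassignment decisions.
Threshold comparisons are strict (E < cutoff) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .annotation_io import SequenceRecord
from .homology_search import (
    ScoringScheme,
    SearchHit,
    SequenceDatabase,
    find_first_hit,
    search_protein_vs_protein,
)

__all__ = [
    "EC",
    "CLADE_SPECIFIC",
    "SPECIES_SPECIFIC",
    "ClassificationResult",
    "ReassignmentDecision",
    "PipelineOrderError",
    "classify_outside_clade",
    "classify_within_clade",
    "knowledgebase_reassign",
    "apply_set_transfers",
    "classify_proteome",
    "summarize_classification",
    "round_half_up",
]

EC = "EC"
CLADE_SPECIFIC = "CLADE_SPECIFIC"
SPECIES_SPECIFIC = "SPECIES_SPECIFIC"


class PipelineOrderError(RuntimeError):
    """A stage received genes that did not come from the previous stage."""


@dataclass
class ClassificationResult:
    gene_id: str
    label: str
    decided_at_stage: int
    best_hit: SearchHit | None = None


@dataclass
class ReassignmentDecision:
    """One stage-3 transfer, modelling the paper-trail of manual curation."""

    gene_id: str
    from_label: str
    to_label: str
    hit: SearchHit | None
    accepted: bool = True
    rationale: str = ""

    # only outward moves (toward broader conservation) are legal
    _LEGAL = {
        (SPECIES_SPECIFIC, CLADE_SPECIFIC),
        (SPECIES_SPECIFIC, EC),
        (CLADE_SPECIFIC, EC),
    }

    def __post_init__(self) -> None:
        if (self.from_label, self.to_label) not in self._LEGAL:
            raise ValueError(
                f"illegal reassignment {self.from_label} -> {self.to_label}"
            )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round-half-up, matching how printed percentages are reported."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Stage 1: outside-clade filter


def _first_significant_hit(
    protein: SequenceRecord,
    dbs: list[SequenceDatabase],
    scheme: ScoringScheme,
    e_cutoff: float,
    exclude_subject_prefix: str | None = None,
) -> SearchHit | None:
    """First hit under the cutoff across databases (existence semantics).

    Classification only needs the existence of one significant hit, so the
    scan short-circuits on the first passing subject.
    """
    exclude = None
    if exclude_subject_prefix:
        exclude = lambda sid: sid.startswith(exclude_subject_prefix)  # noqa: E731
    for db in dbs:
        hit = find_first_hit(protein, db, scheme, e_cutoff, exclude_subject=exclude)
        if hit is not None:
            return hit
    return None


def classify_outside_clade(
    proteins: dict[str, SequenceRecord],
    dbs: list[SequenceDatabase],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
) -> tuple[dict[str, ClassificationResult], list[str]]:
    """Stage 1: gene -> EC iff it has E < cutoff in ANY outside-clade database.

    Returns the EC results keyed by gene id and the ordered remainder list.
    """
    scheme = scheme or ScoringScheme()
    bad = [db.name for db in dbs if not db.taxon_group.startswith("outside_clade")]
    if bad:
        raise ValueError(f"stage 1 requires outside-clade databases, got: {bad}")
    ec: dict[str, ClassificationResult] = {}
    remainder: list[str] = []
    for gid, protein in proteins.items():
        hit = _first_significant_hit(protein, dbs, scheme, e_cutoff)
        if hit is not None:
            ec[gid] = ClassificationResult(gid, EC, 1, hit)
        else:
            remainder.append(gid)
    return ec, remainder


def classify_within_clade(
    remainder: list[str],
    proteins: dict[str, SequenceRecord],
    dbs: list[SequenceDatabase],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
    focal_species_tag: str | None = None,
) -> tuple[dict[str, ClassificationResult], dict[str, ClassificationResult]]:
    """Stage 2: split the stage-1 remainder by within-clade transcript hits.

    ``focal_species_tag`` excludes subjects from the focal species itself
    (self-hits would make the stage vacuous on real data).
    """
    scheme = scheme or ScoringScheme()
    bad = [db.name for db in dbs if db.taxon_group != "clade_transcript"]
    if bad:
        raise ValueError(f"stage 2 requires clade_transcript databases, got: {bad}")
    missing = [g for g in remainder if g not in proteins]
    if missing:
        raise PipelineOrderError(f"genes not in the proteome: {missing[:5]}")
    clade: dict[str, ClassificationResult] = {}
    species: dict[str, ClassificationResult] = {}
    for gid in remainder:
        hit = _first_significant_hit(
            proteins[gid], dbs, scheme, e_cutoff, exclude_subject_prefix=focal_species_tag
        )
        if hit is not None:
            clade[gid] = ClassificationResult(gid, CLADE_SPECIFIC, 2, hit)
        else:
            species[gid] = ClassificationResult(gid, SPECIES_SPECIFIC, 2, None)
    return clade, species


# ---------------------------------------------------------------------------
# Stage 3: knowledgebase reassignment


def _kb_is_clade(db: SequenceDatabase, subject_id: str) -> bool:
    return db.taxonomy.get(subject_id, "") == "clade"


def knowledgebase_reassign(
    clade_set: dict[str, ClassificationResult],
    species_set: dict[str, ClassificationResult],
    kb: SequenceDatabase,
    proteins: dict[str, SequenceRecord] | None = None,
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
    review: list[ReassignmentDecision] | None = None,
) -> tuple[
    dict[str, ClassificationResult],
    dict[str, ClassificationResult],
    dict[str, ClassificationResult],
    list[ReassignmentDecision],
]:
    """Stage 3: rescreen lineage-specific sets against a protein knowledgebase.

    A hit to a non-clade knowledgebase record moves the gene to EC; a
    species-set hit whose only knowledgebase support is a clade record moves
    it to CLADE_SPECIFIC. In auto mode (``review=None``) every candidate
    transfer is accepted; in review mode only the supplied accepted
    decisions are applied, and a decision naming a gene without a qualifying
    hit is an error. Returns (EC additions, clade set, species set,
    decisions).
    """
    scheme = scheme or ScoringScheme()
    if kb.taxon_group != "knowledgebase":
        raise ValueError("stage 3 requires a knowledgebase database")

    candidates: list[ReassignmentDecision] = []
    if kb.records and proteins is not None:
        for gid, res in list(clade_set.items()) + list(species_set.items()):
            hits = search_protein_vs_protein(proteins[gid], kb, scheme, e_cutoff)
            if not hits:
                continue
            nonclade = [h for h in hits if not _kb_is_clade(kb, h.subject_id)]
            if nonclade:
                candidates.append(
                    ReassignmentDecision(
                        gid, res.label, EC, nonclade[0],
                        rationale="knowledgebase hit outside the clade",
                    )
                )
            elif res.label == SPECIES_SPECIFIC:
                candidates.append(
                    ReassignmentDecision(
                        gid, SPECIES_SPECIFIC, CLADE_SPECIFIC, hits[0],
                        rationale="knowledgebase hit within the clade",
                    )
                )

    if review is None:
        decisions = candidates
    else:
        by_gene = {c.gene_id: c for c in candidates}
        for d in review:
            if d.accepted and d.gene_id not in by_gene and d.hit is None:
                raise ValueError(
                    f"review decision for {d.gene_id} lacks a qualifying hit"
                )
        decisions = [d for d in review if d.accepted]

    ec_new, clade_out, species_out = apply_set_transfers(
        clade_set, species_set, decisions
    )
    return ec_new, clade_out, species_out, decisions


def apply_set_transfers(
    clade_set: dict[str, ClassificationResult],
    species_set: dict[str, ClassificationResult],
    decisions: list[ReassignmentDecision],
) -> tuple[
    dict[str, ClassificationResult],
    dict[str, ClassificationResult],
    dict[str, ClassificationResult],
]:
    """Pure set bookkeeping for accepted transfers; idempotent.

    A decision whose gene already left its source set is a no-op, so
    re-applying an applied decision list changes nothing.
    """
    clade_out = dict(clade_set)
    species_out = dict(species_set)
    ec_new: dict[str, ClassificationResult] = {}
    for d in decisions:
        if not d.accepted:
            continue
        src = clade_out if d.from_label == CLADE_SPECIFIC else species_out
        if d.gene_id not in src:
            continue  # already moved: idempotence
        del src[d.gene_id]
        res = ClassificationResult(d.gene_id, d.to_label, 3, d.hit)
        if d.to_label == EC:
            ec_new[d.gene_id] = res
        else:
            clade_out[d.gene_id] = res
    return ec_new, clade_out, species_out


# ---------------------------------------------------------------------------
# End-to-end driver and summary


def classify_proteome(
    proteins: dict[str, SequenceRecord],
    outside_dbs: list[SequenceDatabase],
    clade_dbs: list[SequenceDatabase],
    kb: SequenceDatabase | None = None,
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
    focal_species_tag: str | None = None,
) -> dict[str, ClassificationResult]:
    """Run all three stages; returns one result per input gene."""
    scheme = scheme or ScoringScheme()
    ec, remainder = classify_outside_clade(proteins, outside_dbs, scheme, e_cutoff)
    clade, species = classify_within_clade(
        remainder, proteins, clade_dbs, scheme, e_cutoff, focal_species_tag
    )
    if kb is not None:
        ec_new, clade, species, _ = knowledgebase_reassign(
            clade, species, kb, proteins, scheme, e_cutoff
        )
        ec.update(ec_new)
    results = {**ec, **clade, **species}
    assert len(results) == len(proteins), "classification must partition the input"
    return results


def summarize_classification(
    results: dict[str, ClassificationResult],
    known_function: dict[str, bool],
    transcript_support: dict[str, bool],
) -> pd.DataFrame:
    """Per-label counts/percentages cross-tabbed by function x support.

    Percentages (of the label total and of the grand total) are rounded
    half-up to one decimal.
    """
    rows = []
    total = len(results)
    for label in (CLADE_SPECIFIC, SPECIES_SPECIFIC, EC):
        gids = [g for g, r in results.items() if r.label == label]
        n = len(gids)
        for known in (False, True):
            for support in (False, True):
                cell = sum(
                    1
                    for g in gids
                    if known_function.get(g, False) == known
                    and transcript_support.get(g, False) == support
                )
                rows.append(
                    {
                        "label": label,
                        "known_function": known,
                        "transcript_support": support,
                        "n_genes": cell,
                        "pct_of_label": round_half_up(100 * cell / n) if n else 0.0,
                    }
                )
        rows.append(
            {
                "label": label,
                "known_function": None,
                "transcript_support": None,
                "n_genes": n,
                "pct_of_label": 100.0 if n else 0.0,
                "pct_of_total": round_half_up(100 * n / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
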