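"""Reciprocal-best-hit assignment of genome proteins to PBS gene families.

A protein is assigned to family F when (a) its best-scoring panel member
passing all thresholds (E-value <= 1e-6, identity >= 30%, coverage >= 70%
on query and target) belongs to F, and (b) that member's best hit among the
genome's proteins is itself a protein whose best family is F. Reciprocity
is checked at the family level rather than 1:1 so that genuine multi-copy
families (two distinct cpcA paralogs, say) are all retained; strict
one-to-one reciprocity can never report a copy number above one.

Database sizes for the Karlin–Altschul E-value follow the search direction:
total panel residues for query->panel searches, total genome residues for
the reciprocal panel->genome search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import (
    AlignmentResult,
    ScoringScheme,
    evalue,
    local_align,
    local_score,
    score_for_evalue,
)
from .records import GeneFamily, ProteinRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """BLASTP-style acceptance thresholds for a family hit."""

    evalue_max: float = 1e-6
    identity_min: float = 0.30
    coverage_min: float = 0.70


@dataclass(frozen=True)
class FamilyAssignment:
    """A protein's reciprocal-best-hit call to a family."""

    protein_id: str
    family_name: str
    evidence: AlignmentResult
    evalue: float
    reciprocal: bool


def _passes(result: AlignmentResult, thresholds: Thresholds) -> bool:
    return (
        result.identity >= thresholds.identity_min
        and result.query_coverage >= thresholds.coverage_min
        and result.target_coverage >= thresholds.coverage_min
    )


def best_family_hit(
    query: ProteinRecord,
    panel: list[GeneFamily],
    scheme: ScoringScheme,
    thresholds: Thresholds = Thresholds(),
    db_size: int | None = None,
) -> FamilyAssignment | None:
    """Best panel family for one query, or None if nothing passes.

    Candidates are ranked by raw score (ties: lower E-value is implied by
    the score, then lexicographic member id). Members whose length ratio to
    the query makes two-sided coverage unattainable are skipped without
    alignment, and the score ranking is cut off at the E-value threshold.
    """
    if not panel:
        raise ValueError("empty reference panel")
    if db_size is None:
        db_size = sum(m.length for fam in panel for m in fam.reference_members)

    scored: list[tuple[float, str, ProteinRecord, GeneFamily]] = []
    for family in panel:
        for member in family.reference_members:
            short, long_ = sorted((query.length, member.length))
            if short / long_ < thresholds.coverage_min:
                continue  # two-sided coverage cannot reach the threshold
            score = local_score(query, member, scheme)
            scored.append((score, member.protein_id, member, family))
    scored.sort(key=lambda item: (-item[0], item[1]))

    min_score = score_for_evalue(thresholds.evalue_max, query.length, db_size, scheme)
    for score, _member_id, member, family in scored:
        if score < min_score:
            break  # all remaining candidates have E > threshold
        result = local_align(query, member, scheme)
        if _passes(result, thresholds):
            return FamilyAssignment(
                protein_id=query.protein_id,
                family_name=family.family_name,
                evidence=result,
                evalue=evalue(score, query.length, db_size, scheme),
                reciprocal=False,
            )
    return None


def reciprocal_best_hits(
    genome: list[ProteinRecord],
    panel: list[GeneFamily],
    scheme: ScoringScheme,
    thresholds: Thresholds = Thresholds(),
) -> list[FamilyAssignment]:
    """Family-level reciprocal-best-hit assignments for one genome.

    Returns only reciprocal assignments, in input protein order. Copy number
    of a family equals the number of proteins assigned to it.
    """
    panel_size = sum(m.length for fam in panel for m in fam.reference_members)
    genome_size = sum(p.length for p in genome)

    candidates: dict[str, FamilyAssignment | None] = {}
    for protein in genome:
        candidates[protein.protein_id] = best_family_hit(
            protein, panel, scheme, thresholds, db_size=panel_size
        )

    n_candidates = sum(1 for c in candidates.values() if c is not None)
    log.info(
        "candidate hits: %d/%d proteins passed thresholds", n_candidates, len(genome)
    )

    # Reciprocal direction: each matched panel member searched back against
    # the genome; cache per member since several proteins may share one.
    back_best: dict[str, str | None] = {}

    def best_genome_hit(member: ProteinRecord) -> str | None:
        if member.protein_id not in back_best:
            best: tuple[float, str] | None = None
            for protein in genome:
                score = local_score(member, protein, scheme)
                key = (-score, protein.protein_id)
                if best is None or key < best:
                    best = key
            back_best[member.protein_id] = best[1] if best else None
        return back_best[member.protein_id]

    members_by_id = {
        m.protein_id: m for fam in panel for m in fam.reference_members
    }

    assignments: list[FamilyAssignment] = []
    for protein in genome:
        cand = candidates[protein.protein_id]
        if cand is None:
            continue
        member = members_by_id[cand.evidence.target_id]
        top_id = best_genome_hit(member)
        top_cand = candidates.get(top_id) if top_id else None
        if top_cand is not None and top_cand.family_name == cand.family_name:
            assignments.append(
                FamilyAssignment(
                    protein_id=cand.protein_id,
                    family_name=cand.family_name,
                    evidence=cand.evidence,
                    evalue=evalue(
                        cand.evidence.raw_score, protein.length, panel_size, scheme
                    ),
                    reciprocal=True,
                )
            )
        else:
            log.info(
                "%s: best hit %s not reciprocal at family level",
                protein.protein_id,
                cand.family_name,
            )
    log.info("reciprocal assignments: %d (genome size %d aa)", len(assignments), genome_size)
    return assignments


def write_assignment_tsv(path: str, assignments: list[FamilyAssignment]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tfamily\tscore\tevalue\tidentity\t"
            "query_coverage\ttarget_coverage\treciprocal\n"
        )
        for a in assignments:
            e = a.evidence
            fh.write(
                f"{a.protein_id}\t{a.family_name}\t{e.raw_score:.0f}\t"
                f"{a.evalue:.3g}\t{e.identity:.4f}\t{e.query_coverage:.4f}\t"
                f"{e.target_coverage:.4f}\t{str(a.reciprocal).lower()}\n"
            )
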