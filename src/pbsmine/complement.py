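"""Per-strain gene complements and the classification rules built on them.

Copy numbers count reciprocal family assignments; the cpcG superfamily is
split into cpcG and cpcL using the hydropathy feature calls (counted
disjointly), and apcE copies are sub-counted by far-red class.

Pigment typing follows the rod composition: type 2 (T2) rods carry
phycocyanin plus phycoerythrin-I (both cpeA and cpeB present), type 1 (T1)
rods carry phycocyanin only. A complement with neither is unclassified.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .orthology import FamilyAssignment
from .seqfeatures import SequenceFeatureCall

log = logging.getLogger(__name__)


@dataclass
class GeneComplement:
    """Copy-number table over families for one strain."""

    strain_id: str
    copy_number: dict[str, int] = field(default_factory=dict)
    subclass_counts: dict[str, int] = field(default_factory=dict)
    feature_calls: list[SequenceFeatureCall] = field(default_factory=list)

    def count(self, family: str) -> int:
        return self.copy_number.get(family, 0)


@dataclass(frozen=True)
class PigmentType:
    strain_id: str
    ptype: str  # T1 | T2 | unclassified
    peb_only: bool


@dataclass(frozen=True)
class LyasePattern:
    """Copy-number anomalies among the lyase families."""

    strain_id: str
    extra_homologs: tuple[str, ...]  # lyase families with >= 2 copies
    cpcS_absent: bool


LYASE_FAMILIES = ("cpcE", "cpcF", "cpcS", "cpcT", "cpeF", "cpeS", "cpeT", "cpeU", "cpeZ")


def tabulate_complement(
    strain_id: str,
    assignments: list[FamilyAssignment],
    features: list[SequenceFeatureCall],
) -> GeneComplement:
    """Copy numbers per family with the cpcG/cpcL and apcE splits applied.

    ``features`` carry the resolved family name (cpcL for hydrophobic-tailed
    cpcG-superfamily members) and the apcE class per copy.
    """
    resolved = {f.protein_id: f for f in features}
    counts: Counter[str] = Counter()
    subclass: Counter[str] = Counter()
    for a in assignments:
        call = resolved.get(a.protein_id)
        name = call.resolved_name if call is not None else a.family_name
        counts[name] += 1
        if a.family_name == "apcE":
            klass = call.klass if call is not None else "ambiguous"
            subclass[f"apcE_{klass}"] += 1
    return GeneComplement(
        strain_id=strain_id,
        copy_number=dict(counts),
        subclass_counts=dict(subclass),
        feature_calls=list(features),
    )


def classify_pigment_type(complement: GeneComplement) -> PigmentType:
    """Rod-composition pigment type of one strain.

    A lone cpe subunit (cpeA without cpeB or vice versa) is biologically
    suspect and yields unclassified with a warning rather than T2.
    """
    cpeA, cpeB = complement.count("cpeA"), complement.count("cpeB")
    cpcA, cpcB = complement.count("cpcA"), complement.count("cpcB")
    peb_only = (cpeA + cpeB > 0) and (
        complement.count("pecE") == 0 and complement.count("pecF") == 0
    )
    if cpeA >= 1 and cpeB >= 1:
        ptype = "T2"
    elif cpeA + cpeB > 0:
        log.warning(
            "%s: lone phycoerythrin subunit (cpeA=%d, cpeB=%d); unclassified",
            complement.strain_id, cpeA, cpeB,
        )
        ptype = "unclassified"
    elif cpcA >= 1 and cpcB >= 1:
        ptype = "T1"
    else:
        ptype = "unclassified"
    return PigmentType(complement.strain_id, ptype, peb_only)


def lyase_pattern(complement: GeneComplement) -> LyasePattern:
    """Flag lyase families with extra homologs and explicit cpcS absence."""
    extra = tuple(
        fam for fam in LYASE_FAMILIES if complement.count(fam) >= 2
    )
    return LyasePattern(
        strain_id=complement.strain_id,
        extra_homologs=extra,
        cpcS_absent=complement.count("cpcS") == 0,
    )
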