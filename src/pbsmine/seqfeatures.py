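"""Reference-anchored sequence feature analysis.

Covers the classifiers the complement tables depend on:

* conserved-cysteine assessment against canonical-reference numbering
  (chromophore attachment sites, e.g. Cys-85 of the phycocyanin alpha
  subunit);
* far-red apcE detection: a VIPEDV-like motif combined with loss of the
  phytochrome-binding cysteine;
* cpcG vs cpcL discrimination by a Kyte–Doolittle hydropathy window in the
  C-terminal region (cpcL carries a membrane-anchoring hydrophobic tail);
* pairwise global identity matrices.

Residue numbering is mapped through a global alignment to the canonical
reference rather than by fixed indexing, because family members differ in
length (apcE spans roughly 780-1140 residues across strains).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import ResidueMap, ScoringScheme, global_align
from .errors import ClassificationError
from .records import GeneFamily, MotifPattern, ProteinRecord

log = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy values; X (unknown) scores neutral.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: Defaults of the transmembrane-style cpcL criterion (window length,
#: window-mean threshold, C-terminal span the window center must fall in).
HYDRO_WINDOW = 19
HYDRO_THRESHOLD = 1.6
CTERM_SPAN = 60

MIN_MEMBER_LENGTH = 10  # shorter members are excluded from conservation stats


@dataclass(frozen=True)
class CysConservation:
    """Presence of an expected residue at one reference site across members."""

    family_name: str
    reference_position: int
    expected_residue: str
    conserved_fraction: float
    presence: dict[str, bool]  # protein_id -> flag


@dataclass(frozen=True)
class ApcEClassification:
    protein_id: str
    klass: str  # conventional | far_red | ambiguous
    motif_hit: tuple[int, int, str] | None
    phytochrome_cys_present: bool


@dataclass(frozen=True)
class SequenceFeatureCall:
    """Per-protein classifier output attached to a family assignment."""

    protein_id: str
    family_name: str
    resolved_name: str  # family with cpcG/cpcL split applied
    klass: str | None = None  # apcE class or cpcG/cpcL class
    motif_hit: tuple[int, int, str] | None = None
    phytochrome_cys_present: bool | None = None
    max_cterm_window: float | None = None


def scan_motif(
    seq: ProteinRecord, pattern: MotifPattern
) -> list[tuple[int, int, str]]:
    """All windows matching the motif, left to right.

    Anchor positions must match their residue set exactly; at most
    ``pattern.max_mismatch`` of the remaining positions may miss. Returned
    spans are 0-based half-open with the matched substring.
    """
    if len(pattern) == 0:
        raise ValueError("empty motif pattern")
    hits: list[tuple[int, int, str]] = []
    k = len(pattern)
    s = seq.sequence
    for start in range(0, len(s) - k + 1):
        mismatches = 0
        ok = True
        for offset, allowed in enumerate(pattern.pattern):
            residue = s[start + offset]
            if residue in allowed:
                continue
            if offset in pattern.anchors:
                ok = False
                break
            mismatches += 1
            if mismatches > pattern.max_mismatch:
                ok = False
                break
        if ok:
            hits.append((start, start + k, s[start : start + k]))
    return hits


def conserved_residue_check(
    family: GeneFamily,
    members: list[ProteinRecord],
    site: tuple[int, str],
    scheme: ScoringScheme,
) -> CysConservation:
    """Check one annotated reference site across family members.

    Each member is globally aligned to the canonical reference; the flag is
    true iff the site maps (no gap) and carries the expected residue.
    Members shorter than 10 residues are excluded from the denominator.
    """
    position, residue = site
    if (position, residue) not in family.conserved_sites:
        raise ValueError(
            f"{family.family_name}: {residue}{position} is not an annotated site"
        )
    presence: dict[str, bool] = {}
    for member in members:
        if member.length < MIN_MEMBER_LENGTH:
            log.warning(
                "%s shorter than %d residues; excluded from conservation",
                member.protein_id,
                MIN_MEMBER_LENGTH,
            )
            continue
        _, residue_map = global_align(member, family.canonical_reference, scheme)
        mapped = residue_map.query_position(position)
        presence[member.protein_id] = (
            mapped is not None and member.sequence[mapped - 1] == residue
        )
    fraction = (
        sum(presence.values()) / len(presence) if presence else float("nan")
    )
    return CysConservation(
        family_name=family.family_name,
        reference_position=position,
        expected_residue=residue,
        conserved_fraction=fraction,
        presence=presence,
    )


def _phytochrome_cys_present(
    seq: ProteinRecord, family: GeneFamily, scheme: ScoringScheme
) -> bool:
    if not family.conserved_sites:
        raise ValueError(f"{family.family_name}: no annotated phytochrome site")
    position, residue = family.conserved_sites[0]
    _, residue_map = global_align(seq, family.canonical_reference, scheme)
    mapped = residue_map.query_position(position)
    return mapped is not None and seq.sequence[mapped - 1] == residue


def classify_apcE(
    seq: ProteinRecord, family: GeneFamily, scheme: ScoringScheme
) -> ApcEClassification:
    """Classify an apcE copy as conventional, far-red, or ambiguous.

    far_red requires the far-red motif AND loss of the phytochrome-binding
    cysteine; conventional requires the cysteine AND no motif. Conflicting
    evidence (both or neither) is reported as ambiguous, never coerced.
    """
    if not family.motifs:
        raise ValueError(f"{family.family_name}: no motif annotated")
    hits = scan_motif(seq, family.motifs[0])
    motif_hit = hits[0] if hits else None
    cys = _phytochrome_cys_present(seq, family, scheme)
    if motif_hit is not None and not cys:
        klass = "far_red"
    elif motif_hit is None and cys:
        klass = "conventional"
    else:
        klass = "ambiguous"
    return ApcEClassification(seq.protein_id, klass, motif_hit, cys)


def hydropathy_profile(
    seq: ProteinRecord,
    window: int = HYDRO_WINDOW,
    scale: dict[str, float] = KYTE_DOOLITTLE,
) -> np.ndarray:
    """Sliding-window mean hydropathy, one value per window center."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if seq.length < window:
        raise ValueError(
            f"{seq.protein_id}: length {seq.length} shorter than window {window}"
        )
    values = np.array([scale[r] for r in seq.sequence])
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def classify_cpcG_cpcL(
    seq: ProteinRecord,
    window: int = HYDRO_WINDOW,
    threshold: float = HYDRO_THRESHOLD,
    cterm_span: int = CTERM_SPAN,
    scale: dict[str, float] = KYTE_DOOLITTLE,
) -> tuple[str, float]:
    """Split the cpcG superfamily into rod-core (cpcG) and rod-membrane (cpcL).

    cpcL iff some hydropathy window mean >= threshold has its center within
    the C-terminal ``cterm_span`` residues. Returns the class and the
    maximum C-terminal window mean (the classifier's evidence).
    """
    if seq.length < window:
        raise ClassificationError(
            f"{seq.protein_id}: too short ({seq.length} aa) for the "
            f"{window}-residue hydropathy window"
        )
    profile = hydropathy_profile(seq, window, scale)
    half = window // 2
    centers = np.arange(half, seq.length - half)  # 0-based center positions
    in_cterm = centers >= seq.length - cterm_span
    if not in_cterm.any():
        return "cpcG", float("-inf")
    max_window = float(profile[in_cterm].max())
    return ("cpcL" if max_window >= threshold else "cpcG"), max_window


def identity_matrix(
    members: list[ProteinRecord], scheme: ScoringScheme
) -> np.ndarray:
    """Symmetric matrix of pairwise global identities (diagonal 1.0)."""
    if len(members) < 2:
        raise ValueError("identity matrix needs at least two members")
    n = len(members)
    matrix = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            result, _ = global_align(members[i], members[j], scheme)
            matrix[i, j] = matrix[j, i] = result.identity
    return matrix
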