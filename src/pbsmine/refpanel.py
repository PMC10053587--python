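"""Synthetic reference panel for the PBS gene families.

The published reference set (CyanoBase/BioCyc proteins of Synechocystis
PCC 6803, Synechococcus PCC 7942 and WH8102) is not redistributable here,
so the shipped panel consists of synthetic stand-in sequences: one
deterministic pseudo-random protein per family at a realistic length, with
the documented conserved chromophore-binding cysteines planted at their
canonical positions, a phytochrome-binding cysteine and the far-red
VIPEDV-like motif annotation on apcE, and a hydrophilic C-terminal region
on the cpcG reference (the cpcG/cpcL discriminant). Families are mutually
unrelated by construction, which makes family assignment unambiguous.

The panel is fixed: it is generated from a hard-coded seed and does not
change with the dataset seed.
"""

from __future__ import annotations

import numpy as np

from .records import FAMILY_CATEGORIES, GeneFamily, MotifPattern, ProteinRecord
from .seqfeatures import scan_motif

PANEL_SEED = 20230315

#: Background amino-acid frequencies (approximate bacterial proteome usage).
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.089, "R": 0.049, "N": 0.040, "D": 0.052, "C": 0.012,
    "Q": 0.040, "E": 0.061, "G": 0.074, "H": 0.021, "I": 0.058,
    "L": 0.099, "K": 0.049, "M": 0.023, "F": 0.039, "P": 0.047,
    "S": 0.059, "T": 0.054, "W": 0.013, "Y": 0.031, "V": 0.070,
}

#: Polar/charged residues used for hydrophilic C-terminal regions.
POLAR_RESIDUES = "DENQKRSTGH"

#: Reference lengths per family (residues).
FAMILY_LENGTHS: dict[str, int] = {
    "apcA": 161, "apcB": 161, "apcD": 161, "apcF": 169,
    "cpcA": 162, "cpcB": 172, "cpeA": 164, "cpeB": 177,
    "mpeA": 164, "mpeB": 177, "rpcA": 162, "rpcB": 172,
    "apcC": 67, "apcE": 800, "cpcC": 290, "cpcD": 80, "cpcG": 250,
    "cpeC": 290, "mpeC": 290, "mpeD": 288, "mpeE": 286, "mpeF": 284,
    "mpeG": 282,
    "cpcE": 270, "cpcF": 210, "cpcS": 195, "cpcT": 200, "cpeF": 430,
    "cpeS": 190, "cpeT": 196, "cpeU": 230, "cpeZ": 215,
    "rpcE": 268, "rpcF": 208, "rpcG": 490, "rpcT": 198,
    "pcyA": 248, "pebA": 240, "pebB": 245, "pecE": 252, "pecF": 255,
}

#: Conserved chromophore-attachment cysteines, 1-based reference numbering.
CONSERVED_CYS: dict[str, tuple[int, ...]] = {
    "apcA": (81,), "apcB": (81,), "apcD": (81,), "apcF": (81,),
    "cpcA": (85,), "cpcB": (83, 110, 154),
    "cpeA": (82, 139), "cpeB": (51, 62, 83, 168),
}

#: Position of the phytochrome-binding cysteine on the apcE reference.
APCE_PHYTOCHROME_CYS = 195

#: Far-red-specific motif: hydrophobic flanks around an anchored PED core.
FAR_RED_MOTIF = MotifPattern.from_strings(
    "far_red_motif",
    pattern=["ILMV", "ILMV", "P", "E", "D", "ILMV"],
    anchors=[2, 3, 4],
    max_mismatch=1,
)

#: apcA glutamate baseline used by the composition comparison: the panel
#: reference carries exactly these glutamate positions and no others.
APCA_GLUTAMATE_POSITIONS = (12, 55, 98, 140)  # 1-based


def _draw_sequence(rng: np.random.Generator, length: int,
                   pool: str | None = None) -> str:
    if pool is None:
        letters = np.array(list(BACKGROUND_FREQS))
        probs = np.array(list(BACKGROUND_FREQS.values()))
        probs = probs / probs.sum()
        return "".join(rng.choice(letters, size=length, p=probs))
    return "".join(rng.choice(list(pool), size=length))


def _scrub_motif(sequence: str) -> str:
    """Destroy accidental far-red motif occurrences (anchor P -> G)."""
    probe = ProteinRecord("probe", "", sequence)
    while True:
        hits = scan_motif(probe, FAR_RED_MOTIF)
        if not hits:
            return probe.sequence
        start, _, _ = hits[0]
        chars = list(probe.sequence)
        chars[start + 2] = "G"  # break the anchored proline
        probe = ProteinRecord("probe", "", "".join(chars))


def build_reference_panel() -> list[GeneFamily]:
    """Build the fixed synthetic panel, deterministically."""
    rng = np.random.default_rng(PANEL_SEED)
    families: list[GeneFamily] = []
    for category, names in FAMILY_CATEGORIES.items():
        for name in names:
            length = FAMILY_LENGTHS[name]
            chars = list(_draw_sequence(rng, length))
            if name == "cpcG":
                # hydrophilic C-terminal region: the rod-core linker must not
                # trip the transmembrane-style cpcL criterion
                tail = _draw_sequence(rng, 60, POLAR_RESIDUES)
                chars[length - 60 :] = list(tail)
            if name == "apcA":
                # fixed glutamate baseline for the composition comparison
                chars = [c if c != "E" else "Q" for c in chars]
                for pos in APCA_GLUTAMATE_POSITIONS:
                    chars[pos - 1] = "E"
            sites = [(pos, "C") for pos in CONSERVED_CYS.get(name, ())]
            if name == "apcE":
                sites = [(APCE_PHYTOCHROME_CYS, "C")]
            for pos, residue in sites:
                chars[pos - 1] = residue
            sequence = "".join(chars)
            if name == "apcE":
                sequence = _scrub_motif(sequence)
            canonical = ProteinRecord(f"{name}_ref", "panel", sequence)
            members = [canonical]
            if name == "apcA":
                # a second, slightly diverged member exercises the
                # multi-member search path
                alt = list(sequence)
                positions = rng.choice(length, size=length // 10, replace=False)
                letters = list("ACDFGHIKLMNPQRSTVWY")  # never glutamate
                for pos in positions:
                    if pos + 1 in APCA_GLUTAMATE_POSITIONS or pos + 1 in CONSERVED_CYS["apcA"]:
                        continue
                    choices = [c for c in letters if c != alt[pos]]
                    alt[pos] = choices[int(rng.integers(len(choices)))]
                members.append(ProteinRecord(f"{name}_ref2", "panel", "".join(alt)))
            families.append(
                GeneFamily(
                    family_name=name,
                    category=category,
                    reference_members=members,
                    canonical_reference=canonical,
                    conserved_sites=sites,
                    motifs=[FAR_RED_MOTIF] if name == "apcE" else [],
                    notes="synthetic stand-in reference",
                )
            )
    return families
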