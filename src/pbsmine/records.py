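"""Core domain records: proteins, gene features, families, strain metadata.

Coordinates follow GFF3 conventions: 1-based, inclusive on both ends.
Residue alphabets are the 20 standard amino acids plus ``X`` (unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(STANDARD_RESIDUES + "X")

#: Gene families searched for, grouped as in the reference panel.
FAMILY_CATEGORIES: dict[str, tuple[str, ...]] = {
    "PBP": (
        "apcA", "apcB", "apcD", "apcF", "cpcA", "cpcB", "cpeA", "cpeB",
        "mpeA", "mpeB", "rpcA", "rpcB",
    ),
    "linker": (
        "apcC", "apcE", "cpcC", "cpcD", "cpcG", "cpeC",
        "mpeC", "mpeD", "mpeE", "mpeF", "mpeG",
    ),
    "lyase": (
        "cpcE", "cpcF", "cpcS", "cpcT", "cpeF", "cpeS", "cpeT", "cpeU",
        "cpeZ", "rpcE", "rpcF", "rpcG", "rpcT",
    ),
    "bilin_synthesis": ("pcyA", "pebA", "pebB", "pecE", "pecF"),
}

#: All family symbols the panel is expected to cover.
EXPECTED_FAMILIES: tuple[str, ...] = tuple(
    name for names in FAMILY_CATEGORIES.values() for name in names
)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence belonging to one strain."""

    protein_id: str
    strain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValidationError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus linked to the protein it encodes (1-based inclusive)."""

    gene_id: str
    protein_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class MotifPattern:
    """A short degenerate motif: ordered allowed-residue sets.

    ``anchors`` index positions that must match their set exactly; across the
    remaining positions up to ``max_mismatch`` misses are tolerated.
    """

    name: str
    pattern: tuple[frozenset[str], ...]
    anchors: frozenset[int] = frozenset()
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValidationError(f"{self.name}: negative max_mismatch")
        if any(i < 0 or i >= len(self.pattern) for i in self.anchors):
            raise ValidationError(f"{self.name}: anchor outside pattern")

    @classmethod
    def from_strings(
        cls,
        name: str,
        pattern: list[str],
        anchors: list[int] | None = None,
        max_mismatch: int = 0,
    ) -> "MotifPattern":
        return cls(
            name=name,
            pattern=tuple(frozenset(p) for p in pattern),
            anchors=frozenset(anchors or ()),
            max_mismatch=max_mismatch,
        )

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass
class GeneFamily:
    """A named PBS gene family with its reference sequences and annotations.

    ``conserved_sites`` are (position, residue) pairs in 1-based
    canonical-reference numbering; for apcE the single annotated site is the
    phytochrome-binding cysteine.
    """

    family_name: str
    category: str
    reference_members: list[ProteinRecord]
    canonical_reference: ProteinRecord
    conserved_sites: list[tuple[int, str]] = field(default_factory=list)
    motifs: list[MotifPattern] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in FAMILY_CATEGORIES:
            raise ValidationError(
                f"{self.family_name}: unknown category {self.category!r}"
            )
        ids = [m.protein_id for m in self.reference_members]
        if self.canonical_reference.protein_id not in ids:
            raise ValidationError(
                f"{self.family_name}: canonical reference not among members"
            )
        for pos, res in self.conserved_sites:
            if not 1 <= pos <= self.canonical_reference.length:
                raise ValidationError(
                    f"{self.family_name}: conserved site {pos} beyond "
                    f"reference length {self.canonical_reference.length}"
                )
            if self.canonical_reference.sequence[pos - 1] != res:
                raise ValidationError(
                    f"{self.family_name}: canonical reference lacks {res} "
                    f"at position {pos}"
                )


@dataclass(frozen=True)
class StrainMetadata:
    """Morphology and thermal grouping of one strain."""

    strain_id: str
    morphology: str
    group: str

    def __post_init__(self) -> None:
        if self.morphology not in ("filamentous", "unicellular"):
            raise ValidationError(f"bad morphology {self.morphology!r}")
        if self.group not in ("thermophile", "mesophile"):
            raise ValidationError(f"bad group {self.group!r}")
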