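"""Synthetic 19-strain dataset generator with full ground truth.

Each strain specification transcribes one row of the published complement
tables: copy numbers of phycobiliprotein, linker, lyase and bilin-synthesis
genes, the far-red/conventional split of apcE copies, the cpcL homologs of
the cpcG superfamily, and the genomic cluster layouts. ``build_dataset``
turns the specifications into per-strain protein FASTA + GFF3 plus a
manifest of the planted truth, so every pipeline stage can be checked
end-to-end against what was generated.

Planted sequence features:

* every PBS protein is a BLOSUM62-biased substitution mutant of its family
  reference at a strain/family-specific target identity, with conserved
  cysteines frozen;
* far-red apcE copies carry a literal VIPEDV motif and lose the
  phytochrome-binding cysteine; conventional copies keep it and no motif;
* cpcL copies carry a 21-residue hydrophobic C-terminal tail; cpcG copies
  stay hydrophilic in the C-terminal region;
* thermophile apcA carries two extra glutamate substitutions (~1.2
  percentage points) against a frozen glutamate baseline — the planted
  Table-2-style thermostability composition effect;
* 30 decoy proteins per genome (10 per mesophile pseudo-genome) drawn from
  the background residue distribution, unrelated to any family.

Gene coordinates honour the layout templates: intra-cluster intergenic
gaps <= 200 bp, inter-cluster gaps >= 5000 bp. Two mesophile pseudo-genomes
(high-identity mutants of the panel references, no composition shift)
support the thermophile/mesophile composition comparison without any
external download.

All randomness derives from one dataset seed; per-strain streams are
seeded by (seed, crc32(strain_id)) so strain content is independent of
which subset of strains is built.
"""

from __future__ import annotations

import json
import os
import zlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .organization import label_for_families
from .panel_io import write_fasta, write_gff, write_panel, write_strain_metadata
from .records import GeneFamily, GeneFeature, ProteinRecord, StrainMetadata
from .refpanel import (
    APCA_GLUTAMATE_POSITIONS,
    APCE_PHYTOCHROME_CYS,
    POLAR_RESIDUES,
    BACKGROUND_FREQS,
    build_reference_panel,
)
from .seqfeatures import classify_apcE, classify_cpcG_cpcL
from .align import ScoringScheme

HYDROPHOBIC_TAIL_POOL = "ILVFA"
TAIL_LENGTH = 21
FAR_RED_MOTIF_SEQ = "VIPEDV"
FAR_RED_MOTIF_AT = 300  # 1-based position of the planted motif on apcE

#: Extra glutamate substitutions planted in thermophile apcA copies.
APCA_GLUTAMATE_SHIFT = 2

#: Per-family target identities to the panel reference, per copy. The first
#: copy of a family uses the first value, the second copy the second, and so
#: on (the last value repeats). Values reflect the published inter-strain
#: identity ranges: near-identical cpeA, high apcA/apcB conservation,
#: strongly diverged second cpcA/cpcB paralogs, weakly conserved cpcD.
IDENTITY_TARGETS: dict[str, tuple[float, ...]] = {
    "apcA": (0.85,), "apcB": (0.85,), "apcD": (0.82,), "apcF": (0.82,),
    "cpcA": (0.85, 0.62), "cpcB": (0.85, 0.66),
    "cpeA": (0.95,), "cpeB": (0.85,),
    "apcC": (0.82,), "apcE": (0.75,), "cpcC": (0.62, 0.55), "cpcD": (0.55,),
    "cpcG": (0.72,), "cpcL": (0.78,), "cpeC": (0.70,),
    "cpcE": (0.70, 0.65), "cpcF": (0.70, 0.65), "cpcS": (0.70,),
    "cpcT": (0.70, 0.65),
    "cpeF": (0.72,), "cpeS": (0.70,), "cpeT": (0.70,), "cpeU": (0.70,),
    "cpeZ": (0.70,),
    "pcyA": (0.80,), "pebA": (0.75,), "pebB": (0.75,),
}

MESOPHILE_IDENTITY = {"Synechocystis_PCC6803": 0.95, "Synechococcus_PCC7942": 0.93}

Layout = tuple[tuple[str, str], ...]  # ((family_token, strand), ...)


@dataclass(frozen=True)
class StrainSpec:
    """One strain's planted ground truth: layouts are the single source."""

    strain_id: str
    morphology: str
    group: str  # thermophile | mesophile
    layouts: tuple[Layout, ...]
    apcE_classes: tuple[str, ...] = ()
    n_decoys: int = 30

    def complement(self) -> dict[str, int]:
        counts: Counter[str] = Counter()
        for layout in self.layouts:
            for token, _strand in layout:
                counts[token] += 1
        return dict(counts)

    def __post_init__(self) -> None:
        n_apcE = self.complement().get("apcE", 0)
        if len(self.apcE_classes) != n_apcE:
            raise SpecError(
                f"{self.strain_id}: {n_apcE} apcE copies but "
                f"{len(self.apcE_classes)} classes"
            )

    def cluster_labels(self) -> list[str]:
        return [
            label_for_families([t for t, _ in layout]) for layout in self.layouts
        ]

    def pigment_type(self) -> str:
        c = self.complement()
        if c.get("cpeA", 0) >= 1 and c.get("cpeB", 0) >= 1:
            return "T2"
        if c.get("cpcA", 0) >= 1 and c.get("cpcB", 0) >= 1:
            return "T1"
        return "unclassified"


def _clusters(*groups: list) -> tuple[Layout, ...]:
    layouts = []
    for group in groups:
        layout = []
        for token in group:
            if isinstance(token, tuple):
                layout.append(token)
            else:
                layout.append((token, "+"))
        layouts.append(tuple(layout))
    return tuple(layouts)


def _apc_core(n_apcE: int) -> list[list]:
    return (
        [["apcA", "apcB", "apcC"], ["apcD"], ["apcF"], ["pcyA"]]
        + [["apcE"]] * n_apcE
    )


def _spec(strain_id, morphology, group, pc_layouts, n_apcE=1,
          apcE_classes=None, n_decoys=30) -> StrainSpec:
    return StrainSpec(
        strain_id=strain_id,
        morphology=morphology,
        group=group,
        layouts=_clusters(*(_apc_core(n_apcE) + pc_layouts)),
        apcE_classes=tuple(apcE_classes or ["conventional"] * n_apcE),
        n_decoys=n_decoys,
    )


def _leptolyngbya_like(strain_id: str, pc_extra: list[list],
                       pe_cluster: list[list]) -> StrainSpec:
    return _spec(
        strain_id, "filamentous", "thermophile",
        pc_extra + pe_cluster + [["pebA", "pebB"]],
        n_apcE=2, apcE_classes=["conventional", "far_red"],
    )


def _thermostichus(strain_id: str, n_apcE: int) -> StrainSpec:
    return _spec(
        strain_id, "unicellular", "thermophile",
        [
            ["cpcB", "cpcA", "cpcD", "cpcE", "cpcF", "cpcG"],
            ["cpcB", "cpcA", "cpcC", "cpcE", ("cpcT", "-")],
            ["cpcF"], ["cpcT"], ["cpcS"],
        ],
        n_apcE=n_apcE,
    )


def _thermosynechococcus(strain_id: str, has_cpcS: bool = True) -> StrainSpec:
    pc = [
        ["cpcB", "cpcA", "cpcC", "cpcD", "cpcE", "cpcF", "cpcG"],
        ["cpcG", "cpcG"],
        ["cpcT"],
    ]
    if has_cpcS:
        pc.append(["cpcS"])
    return _spec(strain_id, "unicellular", "thermophile", pc)


def default_strain_specs() -> list[StrainSpec]:
    """The 19 thermophile strains plus the two mesophile pseudo-genomes."""
    ocullatella_pc = [
        ["cpcB", "cpcA", "cpcC", "cpcC", "cpcD", "cpcE", "cpcF"],
        ["cpcG", "cpcG", "cpcL", "cpcG"],
        ["cpcS"], ["cpcT"],
    ]
    specs = [
        _leptolyngbya_like(
            "Leptolyngbya_JSC-1",
            [
                ["cpcB", "cpcA", "cpcC", "cpcC", "cpcD"],
                ["cpcB", "cpcA", "cpcE", "cpcF"],
                ["cpcG"], ["cpcL"], ["cpcL"], ["cpcS"], ["cpcT"],
            ],
            [["cpeB", "cpeA", "cpeZ", "cpeS", "cpeT", "cpeU", "cpeF"], ["cpeC"]],
        ),
        _leptolyngbya_like(
            "Leptothermofonsia_E412",
            [
                ["cpcB", "cpcA", "cpcC", "cpcC", "cpcD"],
                ["cpcB", "cpcA", "cpcE"],
                ["cpcF"], ["cpcG"], ["cpcS"], ["cpcT"],
            ],
            [["cpeB", "cpeA", "cpeC", "cpeZ", "cpeS", "cpeF"], ["cpeT"], ["cpeU"]],
        ),
        _spec(
            "Ocullathermofonsia_A174", "filamentous", "thermophile",
            ocullatella_pc + [["cpcL"]],
            n_apcE=2, apcE_classes=["conventional", "far_red"],
        ),
        _spec("Thermoleptolyngbya_A183", "filamentous", "thermophile",
              ocullatella_pc),
        _spec("Thermoleptolyngbya_O-77", "filamentous", "thermophile",
              ocullatella_pc),
        _spec(
            "Trichothermofonsia_B231", "filamentous", "thermophile",
            [
                ["cpcB", "cpcA", "cpcC", "cpcC", "cpcD", "cpcE", "cpcF", "cpcG"],
                ["cpcS"], ["cpcT"],
            ],
        ),
        _spec(
            "Synechococcus_C9", "unicellular", "thermophile",
            [
                ["cpcB", "cpcA", "cpcC"], ["cpcD", "cpcE"],
                ["cpcC"], ["cpcG"], ["cpcG"], ["cpcF"], ["cpcS"], ["cpcT"],
            ],
        ),
        _thermostichus("Thermostichus_60AY4M2", n_apcE=2),
        _thermostichus("Thermostichus_63AY4M2", n_apcE=1),
        _thermostichus("Thermostichus_65AY6A5", n_apcE=2),
        _thermostichus("Thermostichus_65AY6Li", n_apcE=2),
        _thermostichus("Thermostichus_JA-2-3Ba", n_apcE=1),
        _thermostichus("Thermostichus_JA-3-3Ab", n_apcE=2),
        _thermosynechococcus("Thermosynechococcus_PCC6715", has_cpcS=False),
        _thermosynechococcus("Thermosynechococcus_CL-1"),
        _thermosynechococcus("Thermosynechococcus_TA-1"),
        _thermosynechococcus("Thermosynechococcus_BP-1"),
        _thermosynechococcus("Thermosynechococcus_E542"),
        _thermosynechococcus("Thermosynechococcus_NIES-2134"),
        # Mesophile pseudo-genomes for the composition comparison.
        _spec(
            "Synechocystis_PCC6803", "unicellular", "mesophile",
            [
                ["cpcB", "cpcA", "cpcC", "cpcC", "cpcD"],
                ["cpcG"], ["cpcG"], ["cpcE", "cpcF"], ["cpcS"], ["cpcT"],
            ],
            n_decoys=10,
        ),
        _spec(
            "Synechococcus_PCC7942", "unicellular", "mesophile",
            [
                ["cpcB", "cpcA", "cpcC", "cpcD"],
                ["cpcG"], ["cpcE", "cpcF"], ["cpcS"], ["cpcT"],
            ],
            n_decoys=10,
        ),
    ]
    return specs


THERMOPHILE_COUNT = 19


# --- mutation --------------------------------------------------------------

_BLOSUM_SAMPLERS: dict[str, tuple[list[str], np.ndarray]] | None = None


def _blosum_samplers() -> dict[str, tuple[list[str], np.ndarray]]:
    """BLOSUM62-biased substitution distributions, one per residue."""
    global _BLOSUM_SAMPLERS
    if _BLOSUM_SAMPLERS is None:
        matrix = ScoringScheme().matrix
        letters = list(BACKGROUND_FREQS)
        samplers = {}
        for a in letters:
            others = [b for b in letters if b != a]
            weights = np.array([np.exp(matrix[a, b] / 2.0) for b in others])
            samplers[a] = (others, weights / weights.sum())
        _BLOSUM_SAMPLERS = samplers
    return _BLOSUM_SAMPLERS


def mutate_to_identity(
    reference: ProteinRecord,
    target_identity: float,
    frozen: set[int],
    rng: np.random.Generator,
    *,
    protein_id: str,
    strain_id: str,
    planted: dict[str, int] | None = None,
    pool_exclude: frozenset[str] = frozenset(),
    region_pools: tuple[tuple[int, int, str], ...] = (),
) -> ProteinRecord:
    """Substitution-only mutant of ``reference`` at a target global identity.

    ``frozen`` positions (0-based) are never touched. ``planted`` forces a
    number of substitutions to a given residue (composition shifts);
    ``pool_exclude`` removes residues from the random substitution pool;
    ``region_pools`` restricts substitutions inside (start, end) 0-based
    half-open spans to a residue pool (hydrophilic C-terminal regions).
    Realized identity is exactly ``1 - k/L`` with ``k = round((1-t)*L)``.
    """
    if not 0.4 <= target_identity <= 1.0:
        raise SpecError(f"{protein_id}: target identity {target_identity} out of range")
    length = reference.length
    n_subs = round((1.0 - target_identity) * length)
    available = [i for i in range(length) if i not in frozen]
    if n_subs > len(available):
        raise SpecError(
            f"{protein_id}: {len(frozen)} frozen positions exceed the "
            f"{n_subs}-substitution budget for target {target_identity}"
        )
    planted = planted or {}
    n_planted = sum(planted.values())
    if n_planted > n_subs:
        raise SpecError(f"{protein_id}: planted substitutions exceed budget")

    chars = list(reference.sequence)
    samplers = _blosum_samplers()

    def pool_at(i: int) -> str | None:
        for start, end, pool in region_pools:
            if start <= i < end:
                return pool
        return None

    chosen: list[int] = []
    taken: set[int] = set()
    for residue, count in sorted(planted.items()):
        eligible = [i for i in available if i not in taken and chars[i] != residue]
        idx = rng.choice(len(eligible), size=count, replace=False)
        for j in sorted(int(x) for x in idx):
            chars[eligible[j]] = residue
            taken.add(eligible[j])
            chosen.append(eligible[j])
    remaining = [i for i in available if i not in taken]
    idx = rng.choice(len(remaining), size=n_subs - n_planted, replace=False)
    for j in sorted(int(x) for x in idx):
        i = remaining[j]
        original = chars[i]
        pool = pool_at(i)
        if pool is not None:
            options = [c for c in pool if c != original and c not in pool_exclude]
            chars[i] = options[int(rng.integers(len(options)))]
        else:
            others, probs = samplers[original]
            mask = np.array([c not in pool_exclude for c in others])
            probs = probs * mask
            probs = probs / probs.sum()
            chars[i] = others[int(rng.choice(len(others), p=probs))]
    return ProteinRecord(protein_id, strain_id, "".join(chars))


# --- strain construction ---------------------------------------------------


def _copy_target(token: str, copy_index: int, spec: StrainSpec) -> float:
    if spec.group == "mesophile":
        return MESOPHILE_IDENTITY.get(spec.strain_id, 0.95)
    targets = IDENTITY_TARGETS.get(token, (0.75,))
    return targets[min(copy_index, len(targets) - 1)]


def _build_protein(
    token: str,
    copy_index: int,
    klass: str | None,
    spec: StrainSpec,
    families: dict[str, GeneFamily],
    scheme: ScoringScheme,
    rng: np.random.Generator,
) -> ProteinRecord:
    """One planted PBS protein; retries draws until its class verifies."""
    base_family = "cpcG" if token == "cpcL" else token
    family = families[base_family]
    reference = family.canonical_reference
    chars = list(reference.sequence)
    frozen = {pos - 1 for pos, _ in family.conserved_sites}
    region_pools: tuple[tuple[int, int, str], ...] = ()
    planted: dict[str, int] = {}
    pool_exclude: frozenset[str] = frozenset()
    length = reference.length

    if token == "cpcL":
        tail = rng.choice(list(HYDROPHOBIC_TAIL_POOL), size=TAIL_LENGTH)
        chars[length - TAIL_LENGTH :] = list(tail)
        frozen |= set(range(length - TAIL_LENGTH, length))
        region_pools = ((length - 60, length - TAIL_LENGTH, POLAR_RESIDUES),)
    elif token == "cpcG":
        region_pools = ((length - 60, length, POLAR_RESIDUES),)
    elif token == "apcE":
        cys0 = APCE_PHYTOCHROME_CYS - 1
        if klass == "far_red":
            start = FAR_RED_MOTIF_AT - 1
            chars[start : start + len(FAR_RED_MOTIF_SEQ)] = list(FAR_RED_MOTIF_SEQ)
            chars[cys0] = "S"
            frozen = {cys0} | set(range(start, start + len(FAR_RED_MOTIF_SEQ)))
        else:
            frozen = {cys0}
    elif token == "apcA":
        frozen |= {pos - 1 for pos in APCA_GLUTAMATE_POSITIONS}
        pool_exclude = frozenset("E")
        if spec.group == "thermophile":
            planted = {"E": APCA_GLUTAMATE_SHIFT}

    template = ProteinRecord(f"{token}_template", spec.strain_id, "".join(chars))
    protein_id = f"{token}_{copy_index + 1:02d}"
    target = _copy_target(token, copy_index, spec)

    for _attempt in range(8):
        protein = mutate_to_identity(
            template, target, frozen, rng,
            protein_id=protein_id, strain_id=spec.strain_id,
            planted=planted, pool_exclude=pool_exclude,
            region_pools=region_pools,
        )
        if token in ("cpcG", "cpcL"):
            observed, _ = classify_cpcG_cpcL(protein)
            if observed != token:
                continue
        elif token == "apcE":
            observed = classify_apcE(protein, families["apcE"], scheme).klass
            if observed != (klass or "conventional"):
                continue
        return protein
    raise SpecError(f"{spec.strain_id}/{protein_id}: planted class failed to verify")


def build_strain(
    spec: StrainSpec,
    panel: list[GeneFamily],
    rng: np.random.Generator,
    scheme: ScoringScheme | None = None,
) -> tuple[list[ProteinRecord], list[GeneFeature], dict]:
    """Generate one strain: proteins, gene features, and its truth record."""
    scheme = scheme or ScoringScheme()
    families = {f.family_name: f for f in panel}
    for token in spec.complement():
        if ("cpcG" if token == "cpcL" else token) not in families:
            raise SpecError(f"{spec.strain_id}: layout family {token} not in panel")

    proteins: list[ProteinRecord] = []
    features: list[GeneFeature] = []
    copy_counter: Counter[str] = Counter()
    apcE_iter = iter(spec.apcE_classes)
    position = 1000
    gene_number = 0

    for layout in spec.layouts:
        for token, strand in layout:
            copy_index = copy_counter[token]
            copy_counter[token] += 1
            klass = next(apcE_iter) if token == "apcE" else None
            protein = _build_protein(
                token, copy_index, klass, spec, families, scheme, rng
            )
            proteins.append(protein)
            gene_number += 1
            gene_length = protein.length * 3 + 3
            features.append(
                GeneFeature(
                    gene_id=f"gene_{gene_number:04d}",
                    protein_id=protein.protein_id,
                    contig="scaffold_1",
                    start=position,
                    end=position + gene_length - 1,
                    strand=strand,
                )
            )
            position += gene_length + int(rng.integers(60, 181))
        position += int(rng.integers(6000, 9001))

    letters = np.array(list(BACKGROUND_FREQS))
    probs = np.array(list(BACKGROUND_FREQS.values()))
    probs = probs / probs.sum()
    decoy_position = 1000
    for i in range(spec.n_decoys):
        length = int(rng.integers(120, 321))
        sequence = "".join(rng.choice(letters, size=length, p=probs))
        decoy = ProteinRecord(f"decoy_{i + 1:03d}", spec.strain_id, sequence)
        proteins.append(decoy)
        gene_number += 1
        gene_length = length * 3 + 3
        features.append(
            GeneFeature(
                gene_id=f"gene_{gene_number:04d}",
                protein_id=decoy.protein_id,
                contig="scaffold_2",
                start=decoy_position,
                end=decoy_position + gene_length - 1,
                strand="+" if i % 2 == 0 else "-",
            )
        )
        decoy_position += gene_length + int(rng.integers(200, 401))

    complement = dict(spec.complement())
    truth = {
        "strain_id": spec.strain_id,
        "morphology": spec.morphology,
        "group": spec.group,
        "complement": complement,
        "apcE_classes": list(spec.apcE_classes),
        "pigment_type": spec.pigment_type(),
        "cluster_labels": spec.cluster_labels(),
        "n_decoys": spec.n_decoys,
    }
    return proteins, features, truth


def strain_seed(dataset_seed: int, strain_id: str) -> list[int]:
    """Stable per-strain seed material derived from the dataset seed."""
    return [dataset_seed, zlib.crc32(strain_id.encode())]


def build_dataset(
    out_dir: str,
    seed: int,
    specs: list[StrainSpec] | None = None,
    scheme: ScoringScheme | None = None,
) -> dict:
    """Generate the full dataset tree and return the truth manifest.

    Layout: ``<out_dir>/<strain>/{proteins.faa, genes.gff3}`` plus
    ``panel/``, ``metadata.tsv`` and ``manifest.json``. Byte-identical for
    identical seeds.
    """
    specs = specs if specs is not None else default_strain_specs()
    ids = [s.strain_id for s in specs]
    duplicates = [i for i, n in Counter(ids).items() if n > 1]
    if duplicates:
        raise SpecError(f"duplicate strain ids: {duplicates}")

    os.makedirs(out_dir, exist_ok=True)
    panel = build_reference_panel()
    write_panel(os.path.join(out_dir, "panel"), panel)

    manifest: dict = {"seed": seed, "strains": {}}
    metadata = []
    for spec in specs:
        rng = np.random.default_rng(strain_seed(seed, spec.strain_id))
        proteins, features, truth = build_strain(spec, panel, rng, scheme)
        strain_dir = os.path.join(out_dir, spec.strain_id)
        os.makedirs(strain_dir, exist_ok=True)
        write_fasta(os.path.join(strain_dir, "proteins.faa"), proteins)
        write_gff(os.path.join(strain_dir, "genes.gff3"), features)
        manifest["strains"][spec.strain_id] = truth
        metadata.append(StrainMetadata(spec.strain_id, spec.morphology, spec.group))

    write_strain_metadata(os.path.join(out_dir, "metadata.tsv"), metadata)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
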