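"""End-to-end orchestration: genome in, complement tables and clusters out.

``profile_strain`` runs the per-genome stages in order — reciprocal-best-hit
family assignment, per-protein feature classification (apcE class, cpcG/cpcL
split), complement tabulation, pigment typing, lyase pattern, and gene
cluster detection when coordinates are available. ``profile_dataset`` maps
this over a dataset directory and ``compare_composition`` runs the
thermophile/mesophile amino-acid composition tests on the profiled strains.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .complement import (
    GeneComplement,
    LyasePattern,
    PigmentType,
    classify_pigment_type,
    lyase_pattern,
    tabulate_complement,
)
from .composition import CompositionVector, compare_groups, composition
from .config import PipelineConfig
from .errors import ClassificationError
from .organization import GeneCluster, detect_clusters, pbs_loci, write_cluster_tsv
from .orthology import FamilyAssignment, reciprocal_best_hits, write_assignment_tsv
from .panel_io import (
    check_links,
    load_panel,
    load_strain_metadata,
    read_fasta,
    read_gff,
)
from .records import GeneFamily, GeneFeature, ProteinRecord, StrainMetadata
from .seqfeatures import SequenceFeatureCall, classify_apcE, classify_cpcG_cpcL

log = logging.getLogger(__name__)

#: PBP subunits entering the thermophile/mesophile composition comparison.
COMPARED_FAMILIES = ("apcA", "apcB", "cpcA", "cpcB", "cpeA", "cpeB")


@dataclass
class StrainProfile:
    strain_id: str
    assignments: list[FamilyAssignment]
    feature_calls: list[SequenceFeatureCall]
    complement: GeneComplement
    pigment: PigmentType
    lyases: LyasePattern
    clusters: list[GeneCluster] | None = None
    family_compositions: dict[str, CompositionVector] = field(default_factory=dict)


def _feature_calls(
    proteins_by_id: dict[str, ProteinRecord],
    assignments: list[FamilyAssignment],
    panel_by_name: dict[str, GeneFamily],
    config: PipelineConfig,
) -> list[SequenceFeatureCall]:
    calls: list[SequenceFeatureCall] = []
    for a in assignments:
        protein = proteins_by_id[a.protein_id]
        resolved = a.family_name
        klass = None
        motif_hit = None
        cys = None
        max_window = None
        if a.family_name == "cpcG":
            try:
                klass, max_window = classify_cpcG_cpcL(
                    protein,
                    window=config.hydro_window,
                    threshold=config.hydro_threshold,
                    cterm_span=config.cterm_span,
                )
                resolved = klass
            except ClassificationError as exc:
                log.warning("%s", exc)
                klass = "unclassified"
        elif a.family_name == "apcE":
            result = classify_apcE(protein, panel_by_name["apcE"], config.scheme)
            klass = result.klass
            motif_hit = result.motif_hit
            cys = result.phytochrome_cys_present
        calls.append(
            SequenceFeatureCall(
                protein_id=a.protein_id,
                family_name=a.family_name,
                resolved_name=resolved,
                klass=klass,
                motif_hit=motif_hit,
                phytochrome_cys_present=cys,
                max_cterm_window=max_window,
            )
        )
    return calls


def _mean_compositions(
    proteins_by_id: dict[str, ProteinRecord],
    feature_calls: list[SequenceFeatureCall],
    strain_id: str,
) -> dict[str, CompositionVector]:
    """Per-family mean composition: one value per strain and subunit.

    Strains with several copies contribute the mean of their copies so each
    strain enters the rank test exactly once.
    """
    grouped: dict[str, list[CompositionVector]] = {}
    for call in feature_calls:
        if call.family_name not in COMPARED_FAMILIES:
            continue
        vector = composition(proteins_by_id[call.protein_id])
        grouped.setdefault(call.family_name, []).append(vector)
    means = {}
    for family, vectors in grouped.items():
        percent = {
            residue: sum(v.percent[residue] for v in vectors) / len(vectors)
            for residue in vectors[0].percent
        }
        means[family] = CompositionVector(f"{strain_id}|{family}", percent)
    return means


def profile_strain(
    strain_id: str,
    proteins: list[ProteinRecord],
    features: list[GeneFeature] | None,
    panel: list[GeneFamily],
    config: PipelineConfig,
) -> StrainProfile:
    """Run all per-genome stages for one strain."""
    log.info("%s: profiling %d proteins", strain_id, len(proteins))
    panel_by_name = {f.family_name: f for f in panel}
    proteins_by_id = {p.protein_id: p for p in proteins}
    assignments = reciprocal_best_hits(
        proteins, panel, config.scheme, config.thresholds
    )
    calls = _feature_calls(proteins_by_id, assignments, panel_by_name, config)
    complement = tabulate_complement(strain_id, assignments, calls)
    pigment = classify_pigment_type(complement)
    lyases = lyase_pattern(complement)
    clusters = None
    if features is not None:
        check_links(features, proteins)
        loci = pbs_loci(features, assignments, calls)
        clusters = detect_clusters(loci, max_gap=config.cluster_max_gap)
    return StrainProfile(
        strain_id=strain_id,
        assignments=assignments,
        feature_calls=calls,
        complement=complement,
        pigment=pigment,
        lyases=lyases,
        clusters=clusters,
        family_compositions=_mean_compositions(proteins_by_id, calls, strain_id),
    )


def profile_dataset(
    dataset_dir: str,
    config: PipelineConfig,
    strains: list[str] | None = None,
    panel: list[GeneFamily] | None = None,
) -> dict[str, StrainProfile]:
    """Profile every strain in a dataset directory.

    A strain without a genes.gff3 still gets sequence-level results; the
    organization stage is skipped with a warning.
    """
    if panel is None:
        panel = load_panel(os.path.join(dataset_dir, "panel"))
    metadata = load_strain_metadata(os.path.join(dataset_dir, "metadata.tsv"))
    profiles: dict[str, StrainProfile] = {}
    for row in metadata:
        if strains is not None and row.strain_id not in strains:
            continue
        strain_dir = os.path.join(dataset_dir, row.strain_id)
        proteins = read_fasta(
            os.path.join(strain_dir, "proteins.faa"), strain_id=row.strain_id
        )
        gff_path = os.path.join(strain_dir, "genes.gff3")
        features = None
        if os.path.exists(gff_path):
            features = read_gff(gff_path)
        else:
            log.warning("%s: no genes.gff3; organization stage skipped", row.strain_id)
        profiles[row.strain_id] = profile_strain(
            row.strain_id, proteins, features, panel, config
        )
    return profiles


def compare_composition(
    profiles: dict[str, StrainProfile],
    metadata: list[StrainMetadata],
    config: PipelineConfig,
    families: tuple[str, ...] = COMPARED_FAMILIES,
) -> pd.DataFrame:
    """Thermophile vs mesophile per-residue rank tests over PBP subunits."""
    group_of = {m.strain_id: m.group for m in metadata}
    tables = []
    for family in families:
        thermo, meso = [], []
        for strain_id, profile in profiles.items():
            vector = profile.family_compositions.get(family)
            if vector is None:
                continue
            (thermo if group_of.get(strain_id) == "thermophile" else meso).append(
                vector
            )
        tables.append(compare_groups(family, thermo, meso, config.alphas))
    non_empty = [t for t in tables if not t.empty]
    return pd.concat(non_empty or tables[:1], ignore_index=True)


# --- output writing --------------------------------------------------------


def write_profiles(
    out_dir: str, profiles: dict[str, StrainProfile], config: PipelineConfig
) -> None:
    """Write complement/feature/cluster tables and per-strain JSON."""
    os.makedirs(out_dir, exist_ok=True)
    families = sorted({f for p in profiles.values() for f in p.complement.copy_number})
    rows = []
    for strain_id, profile in profiles.items():
        row = {"strain_id": strain_id, "pigment_type": profile.pigment.ptype}
        row.update({f: profile.complement.count(f) for f in families})
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "complement.tsv"),
                              sep="\t", index=False)

    with open(os.path.join(out_dir, "feature_calls.tsv"), "w") as fh:
        fh.write("strain_id\tprotein_id\tfamily\tresolved\tclass\t"
                 "motif_span\tphytochrome_cys\tmax_cterm_window\n")
        for strain_id, profile in profiles.items():
            for c in profile.feature_calls:
                span = (f"{c.motif_hit[0]}-{c.motif_hit[1]}" if c.motif_hit else "")
                window = ("" if c.max_cterm_window is None
                          else f"{c.max_cterm_window:.2f}")
                fh.write(
                    f"{strain_id}\t{c.protein_id}\t{c.family_name}\t"
                    f"{c.resolved_name}\t{c.klass or ''}\t{span}\t"
                    f"{'' if c.phytochrome_cys_present is None else c.phytochrome_cys_present}\t"
                    f"{window}\n"
                )

    for strain_id, profile in profiles.items():
        strain_dir = os.path.join(out_dir, strain_id)
        os.makedirs(strain_dir, exist_ok=True)
        write_assignment_tsv(
            os.path.join(strain_dir, "assignments.tsv"), profile.assignments
        )
        if profile.clusters is not None:
            write_cluster_tsv(
                os.path.join(strain_dir, "clusters.tsv"), strain_id, profile.clusters
            )
        summary = {
            "strain_id": strain_id,
            "pigment_type": profile.pigment.ptype,
            "peb_only": profile.pigment.peb_only,
            "copy_number": profile.complement.copy_number,
            "apcE_subclasses": profile.complement.subclass_counts,
            "extra_lyase_homologs": list(profile.lyases.extra_homologs),
            "cpcS_absent": profile.lyases.cpcS_absent,
            "cluster_labels": (
                None if profile.clusters is None
                else [c.label for c in profile.clusters]
            ),
        }
        with open(os.path.join(strain_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

    provenance = {
        "tool": "pbsmine",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": yaml_config_dict(config),
    }
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def yaml_config_dict(config: PipelineConfig) -> dict:
    import yaml

    return yaml.safe_load(config.to_yaml())
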