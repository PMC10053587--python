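"""Genomic organization: PBS loci extraction and gene-cluster detection.

A cluster is a maximal run of PBS-assigned genes on one contig in which
every intergenic distance (next.start - prev.end - 1, coordinates 1-based
inclusive) is at most ``max_gap``. Strand changes do not split a cluster —
an oppositely transcribed gene positionally inside a cluster (the cpcT
case next to the second Thermostichus PC cluster) stays a member with its
strand recorded.

Cluster labels follow the compact operon convention: the first member's
full family name, then bare suffixes while the 3-letter prefix is shared
(``cpcB-A-C-D-E-F-G``), restarting the full name on a prefix change.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .orthology import FamilyAssignment
from .records import GeneFeature
from .seqfeatures import SequenceFeatureCall


@dataclass(frozen=True)
class PBSLocus:
    """One PBS-assigned gene on a contig."""

    family_name: str
    gene_id: str
    protein_id: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class GeneCluster:
    contig: str
    members: tuple[PBSLocus, ...]
    gaps: tuple[int, ...]  # intergenic distances between consecutive members

    @property
    def label(self) -> str:
        return render_label(self)

    @property
    def machine_label(self) -> str:
        return render_label(self, mark_strand=True)


def pbs_loci(
    features: list[GeneFeature],
    assignments: list[FamilyAssignment],
    feature_calls: list[SequenceFeatureCall] | None = None,
) -> list[PBSLocus]:
    """PBS-assigned loci sorted by (contig, start).

    Family names are the resolved ones (cpcL split from cpcG) when feature
    calls are supplied. An assignment whose protein has no gene feature is
    a consistency error.
    """
    by_protein = {f.protein_id: f for f in features}
    resolved = {c.protein_id: c.resolved_name for c in feature_calls or []}
    loci = []
    for a in assignments:
        feature = by_protein.get(a.protein_id)
        if feature is None:
            raise ValidationError(
                f"assignment {a.protein_id} ({a.family_name}) has no gene feature"
            )
        loci.append(
            PBSLocus(
                family_name=resolved.get(a.protein_id, a.family_name),
                gene_id=feature.gene_id,
                protein_id=a.protein_id,
                contig=feature.contig,
                start=feature.start,
                end=feature.end,
                strand=feature.strand,
            )
        )
    loci.sort(key=lambda l: (l.contig, l.start))
    return loci


def detect_clusters(loci: list[PBSLocus], max_gap: int = 1000) -> list[GeneCluster]:
    """Partition sorted loci into maximal runs with intergenic gaps <= max_gap.

    Singleton genes are emitted as size-1 clusters, so cluster membership is
    a partition of the loci.
    """
    clusters: list[GeneCluster] = []
    run: list[PBSLocus] = []
    gaps: list[int] = []
    for locus in loci:
        if run and locus.contig == run[-1].contig:
            gap = locus.start - run[-1].end - 1
            if gap <= max_gap:
                run.append(locus)
                gaps.append(gap)
                continue
        if run:
            clusters.append(GeneCluster(run[0].contig, tuple(run), tuple(gaps)))
        run, gaps = [locus], []
    if run:
        clusters.append(GeneCluster(run[0].contig, tuple(run), tuple(gaps)))
    return clusters


def label_for_families(names: list[str], strands: list[str] | None = None,
                       mark_strand: bool = False) -> str:
    """Compact operon-style label for an ordered run of family names."""
    if not names:
        raise ValueError("empty cluster")
    lead_strand = strands[0] if strands else "+"
    parts: list[str] = []
    previous_prefix = None
    for i, name in enumerate(names):
        prefix = name[:3]
        if previous_prefix == prefix:
            parts.append(name[3:] or name)
        else:
            parts.append(name)
        previous_prefix = prefix
        if mark_strand and strands and strands[i] != lead_strand:
            parts[-1] += "(-)"
    return "-".join(parts)


def render_label(cluster: GeneCluster, mark_strand: bool = False) -> str:
    """Label of a detected cluster.

    With ``mark_strand`` (the machine-readable form), members transcribed
    opposite to the cluster's first member carry a trailing ``(-)`` marker.
    """
    return label_for_families(
        [m.family_name for m in cluster.members],
        [m.strand for m in cluster.members],
        mark_strand=mark_strand,
    )


def write_cluster_tsv(path: str, strain_id: str, clusters: list[GeneCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tcontig\tlabel\tmachine_label\tmembers\tgaps\n")
        for c in clusters:
            members = ",".join(
                f"{m.family_name}:{m.start}-{m.end}({m.strand})" for m in c.members
            )
            gaps = ",".join(str(g) for g in c.gaps)
            fh.write(
                f"{strain_id}\t{c.contig}\t{c.label}\t{c.machine_label}\t{members}\t{gaps}\n"
            )
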