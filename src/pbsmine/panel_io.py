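"""Readers and writers for the formats the pipeline touches.

Protein FASTA and the reference panel are read through Bio.SeqIO; GFF3 is
handled by a small strict reader/writer restricted to the 9-column gene lines
this pipeline produces and consumes (ID and protein_id attributes).

Panel directory layout::

    panel/
      panel.tsv        one row per family: family, category, canonical,
                       conserved_sites (JSON), motifs (JSON), notes
      <family>.faa     reference members of that family

Strain metadata is a TSV with columns strain_id, morphology, group.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable

from Bio import SeqIO

from .errors import FormatError, ValidationError
from .records import (
    ALLOWED_RESIDUES,
    EXPECTED_FAMILIES,
    GeneFamily,
    GeneFeature,
    MotifPattern,
    ProteinRecord,
    StrainMetadata,
)

log = logging.getLogger(__name__)


def _residue_error_line(path: str, bad_id: str) -> int | None:
    """Locate the first offending line of a malformed FASTA record."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                token = line[1:].split()[0] if line[1:].strip() else ""
                in_record = token == bad_id
            elif in_record:
                residues = set(line.strip().upper())
                if residues - ALLOWED_RESIDUES:
                    return lineno
    return None


def read_fasta(path: str, strain_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records, preserving order.

    Sequences are uppercased; the record id is the header token up to the
    first whitespace. Illegal residues raise :class:`FormatError` naming the
    offending line.
    """
    records: list[ProteinRecord] = []
    for seq_rec in SeqIO.parse(path, "fasta"):
        if not seq_rec.id:
            raise FormatError(f"{path}: FASTA header without an identifier")
        sequence = str(seq_rec.seq).upper()
        try:
            rec = ProteinRecord(seq_rec.id, strain_id, sequence)
        except ValidationError as exc:
            lineno = _residue_error_line(path, seq_rec.id)
            where = f" (line {lineno})" if lineno else ""
            raise FormatError(f"{path}{where}: {exc}") from exc
        records.append(rec)
    return records


def write_fasta(path: str, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# --- GFF3 ------------------------------------------------------------------

_GFF_COLUMNS = 9


def read_gff(path: str) -> list[GeneFeature]:
    """Read gene/CDS features from a GFF3 file, sorted by (contig, start).

    The protein link is the ``protein_id`` attribute when present, else the
    feature ``ID`` (matching the FASTA header token). Coordinates are kept
    1-based inclusive.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLUMNS:
                raise FormatError(f"{path} line {lineno}: expected 9 columns")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            attr_map: dict[str, str] = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, _, value = item.partition("=")
                    attr_map[key.strip()] = value.strip()
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise FormatError(f"{path} line {lineno}: feature without ID")
            protein_id = attr_map.get("protein_id", gene_id)
            try:
                features.append(
                    GeneFeature(gene_id, protein_id, contig, start, end, strand)
                )
            except ValidationError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    features.sort(key=lambda f: (f.contig, f.start, f.gene_id))
    return features


def write_gff(path: str, features: Iterable[GeneFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id};protein_id={f.protein_id}"
            fh.write(
                f"{f.contig}\tpbsmine\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def check_links(
    features: Iterable[GeneFeature], proteins: Iterable[ProteinRecord]
) -> None:
    """Reject gene features whose protein link dangles."""
    known = {p.protein_id for p in proteins}
    missing = sorted({f.protein_id for f in features} - known)
    if missing:
        raise ValidationError(
            f"gene features reference unknown proteins: {', '.join(missing[:5])}"
        )


# --- Reference panel -------------------------------------------------------


def write_panel(panel_dir: str, families: Iterable[GeneFamily]) -> None:
    os.makedirs(panel_dir, exist_ok=True)
    rows = []
    for fam in families:
        write_fasta(os.path.join(panel_dir, f"{fam.family_name}.faa"),
                    fam.reference_members)
        motifs = [
            {
                "name": m.name,
                "pattern": ["".join(sorted(s)) for s in m.pattern],
                "anchors": sorted(m.anchors),
                "max_mismatch": m.max_mismatch,
            }
            for m in fam.motifs
        ]
        rows.append(
            "\t".join(
                [
                    fam.family_name,
                    fam.category,
                    fam.canonical_reference.protein_id,
                    json.dumps([[p, r] for p, r in fam.conserved_sites]),
                    json.dumps(motifs),
                    fam.notes,
                ]
            )
        )
    with open(os.path.join(panel_dir, "panel.tsv"), "w") as fh:
        fh.write("family\tcategory\tcanonical\tconserved_sites\tmotifs\tnotes\n")
        fh.write("\n".join(rows) + "\n")


def load_panel(panel_dir: str) -> list[GeneFamily]:
    """Load the reference panel, validating sites against canonical members.

    Expected family symbols absent from the panel are reported with a warning
    rather than an error: marine-type families legitimately have no
    freshwater reference in some panels.
    """
    table = os.path.join(panel_dir, "panel.tsv")
    if not os.path.exists(table):
        raise FormatError(f"{panel_dir}: no panel.tsv")
    families: list[GeneFamily] = []
    seen: set[str] = set()
    with open(table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["family", "category", "canonical"]:
            raise FormatError(f"{table}: unexpected header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 6:
                raise FormatError(f"{table} line {lineno}: expected 6 columns")
            name, category, canonical_id, sites_json, motifs_json, notes = cols
            if name in seen:
                raise ValidationError(f"duplicate family {name!r} in panel")
            seen.add(name)
            members = read_fasta(os.path.join(panel_dir, f"{name}.faa"))
            by_id = {m.protein_id: m for m in members}
            if canonical_id not in by_id:
                raise ValidationError(
                    f"{name}: canonical member {canonical_id!r} not in FASTA"
                )
            sites = [(int(p), str(r)) for p, r in json.loads(sites_json)]
            motifs = [
                MotifPattern.from_strings(
                    m["name"], m["pattern"], m.get("anchors"), m.get("max_mismatch", 0)
                )
                for m in json.loads(motifs_json)
            ]
            families.append(
                GeneFamily(
                    family_name=name,
                    category=category,
                    reference_members=members,
                    canonical_reference=by_id[canonical_id],
                    conserved_sites=sites,
                    motifs=motifs,
                    notes=notes,
                )
            )
    absent = sorted(set(EXPECTED_FAMILIES) - seen)
    if absent:
        log.warning("panel lacks reference entries for: %s", ", ".join(absent))
    return families


# --- Strain metadata -------------------------------------------------------


def write_strain_metadata(path: str, rows: Iterable[StrainMetadata]) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\tmorphology\tgroup\n")
        for row in rows:
            fh.write(f"{row.strain_id}\t{row.morphology}\t{row.group}\n")


def load_strain_metadata(path: str) -> list[StrainMetadata]:
    rows: list[StrainMetadata] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["strain_id", "morphology", "group"]:
            raise FormatError(f"{path}: unexpected metadata header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path} line {lineno}: expected 3 columns")
            try:
                rows.append(StrainMetadata(*cols))
            except ValidationError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return rows
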