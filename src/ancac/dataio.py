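"""Dataset model and I/O.

The in-memory model mirrors a NUCOCOG-style ortholog collection: organisms,
clusters of orthologous groups (COGs), and member sequences carrying both the
protein and its coding nucleotide sequence (CDS).  Datasets are read from a
small XML dialect (documented in ``docs/methods.md``; the original database's
schema is not public, so the dialect here is this package's own definition) or
from per-COG FASTA files, and are decorated with taxonomy lineages and
organism traits loaded from flat TSV tables.

Writers cover the tool's outputs: ranking tables, per-COG member listings and
FASTA exports.
"""

from __future__ import annotations

import csv
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import DataError, IntegrityError

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureCounts
    from .scoring import ScoreRow
    from .select import Selection

log = logging.getLogger("ancac")

#: Taxonomic ranks supported throughout the package, most to least inclusive.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: Valid oxygen-requirement classes for an organism.
OXYGEN_CLASSES = ("aerobe", "anaerobe", "facultative", "unknown")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("X*")
NT_ALPHABET = frozenset("ACGTN")

_COG_RE = re.compile(r"^[A-Za-z]+[0-9]+$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One ortholog-group member: a protein and (optionally) its CDS."""

    organism_id: str
    cog_id: str
    protein_gi: str
    gene_gi: str
    aa_seq: str
    nt_seq: str = ""

    def validate(self) -> None:
        if not self.aa_seq:
            raise IntegrityError(
                f"sequence {self.protein_gi} ({self.organism_id}): empty protein sequence")
        bad = set(self.aa_seq) - AA_ALPHABET
        if bad:
            raise DataError(
                f"sequence {self.protein_gi}: invalid amino-acid character(s) {sorted(bad)}")
        if self.nt_seq:
            if len(self.nt_seq) < 3:
                raise IntegrityError(
                    f"sequence {self.protein_gi}: CDS shorter than one codon")
            bad = set(self.nt_seq) - NT_ALPHABET
            if bad:
                raise DataError(
                    f"sequence {self.protein_gi}: invalid nucleotide character(s) {sorted(bad)}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.organism_id, self.protein_gi)


@dataclass
class OrganismRecord:
    """An organism with its ranked lineage and optional physiology traits."""

    organism_id: str
    display_name: str = ""
    lineage: dict[str, str] = field(default_factory=dict)
    oxygen_class: str = "unknown"
    ogt_celsius: float | None = None

    def validate(self) -> None:
        for rank in self.lineage:
            if rank not in RANKS:
                raise DataError(f"organism {self.organism_id}: unknown rank {rank!r}")
        if self.oxygen_class not in OXYGEN_CLASSES:
            raise DataError(
                f"organism {self.organism_id}: oxygen class {self.oxygen_class!r} invalid")
        if self.ogt_celsius is not None and not (0 <= self.ogt_celsius <= 130):
            raise DataError(
                f"organism {self.organism_id}: OGT {self.ogt_celsius} outside [0, 130] degC")


@dataclass
class CogRecord:
    """A cluster of orthologous groups: id, functional description, members."""

    cog_id: str
    description: str = ""
    member_ids: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class Dataset:
    """A full ortholog collection plus lazily cached per-sequence counts."""

    source: str = "cog"
    organisms: dict[str, OrganismRecord] = field(default_factory=dict)
    cogs: dict[str, CogRecord] = field(default_factory=dict)
    sequences: list[SequenceRecord] = field(default_factory=list)
    counts: dict[tuple[str, str], "FeatureCounts"] = field(default_factory=dict)
    has_taxonomy: bool = False
    has_traits: bool = False

    def add_sequence(self, rec: SequenceRecord) -> None:
        rec.validate()
        if rec.organism_id not in self.organisms:
            raise IntegrityError(
                f"sequence {rec.protein_gi} references unknown organism {rec.organism_id!r}")
        cog = self.cogs.get(rec.cog_id)
        if cog is None:
            raise IntegrityError(
                f"sequence {rec.protein_gi} references unknown COG {rec.cog_id!r}")
        if rec.key in cog.member_ids or any(s.key == rec.key for s in self.sequences):
            raise IntegrityError(
                f"duplicate sequence {rec.key} in dataset")
        cog.member_ids.add(rec.key)
        self.sequences.append(rec)

    def validate(self) -> None:
        if not self.sequences:
            raise DataError("dataset contains no sequences")
        seen: set[tuple[str, str]] = set()
        for rec in self.sequences:
            rec.validate()
            if rec.organism_id not in self.organisms:
                raise IntegrityError(
                    f"sequence {rec.protein_gi} references unknown organism {rec.organism_id!r}")
            if rec.cog_id not in self.cogs:
                raise IntegrityError(
                    f"sequence {rec.protein_gi} references unknown COG {rec.cog_id!r}")
            if rec.key in seen:
                raise IntegrityError(f"duplicate (organism, protein GI) pair {rec.key}")
            seen.add(rec.key)
        for cog in self.cogs.values():
            if not cog.member_ids <= seen:
                missing = sorted(cog.member_ids - seen)
                raise IntegrityError(f"COG {cog.cog_id}: unresolvable members {missing}")

    def sequences_of_cog(self, cog_id: str) -> list[SequenceRecord]:
        if cog_id not in self.cogs:
            raise DataError(f"unknown COG {cog_id!r}")
        return [s for s in self.sequences if s.cog_id == cog_id]

    def attach_taxonomy(self, lineages: Mapping[str, Mapping[str, str]]) -> None:
        """Attach lineages loaded with :func:`load_taxonomy`; unknown ids ignored."""
        n = 0
        for org_id, lineage in lineages.items():
            org = self.organisms.get(org_id)
            if org is not None:
                org.lineage = dict(lineage)
                n += 1
        if n == 0:
            log.warning("taxonomy table matched no organism in the dataset")
        self.has_taxonomy = n > 0

    def attach_traits(self, traits: Mapping[str, tuple[str, float | None]]) -> None:
        n = 0
        for org_id, (oxygen, ogt) in traits.items():
            org = self.organisms.get(org_id)
            if org is not None:
                org.oxygen_class = oxygen
                org.ogt_celsius = ogt
                n += 1
        if n == 0:
            log.warning("trait table matched no organism in the dataset")
        self.has_traits = n > 0


def datasets_equal(a: Dataset, b: Dataset) -> bool:
    """Equality over the XML-carried content, ignoring sequence order.

    Lineages and traits live in the separate taxonomy/trait tables rather
    than the dataset XML, so they (like cached counts) do not enter the
    comparison.
    """
    if a.source != b.source or a.organisms.keys() != b.organisms.keys():
        return False
    for key in a.organisms:
        if a.organisms[key].display_name != b.organisms[key].display_name:
            return False
    if a.cogs.keys() != b.cogs.keys():
        return False
    for key in a.cogs:
        x, y = a.cogs[key], b.cogs[key]
        if (x.description, x.member_ids) != (y.description, y.member_ids):
            return False
    sa = sorted(a.sequences, key=lambda s: s.key)
    sb = sorted(b.sequences, key=lambda s: s.key)
    return sa == sb


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _norm_aa(seq: str) -> str:
    return "".join(seq.split()).upper()


def _norm_nt(seq: str) -> str:
    return "".join(seq.split()).upper().replace("U", "T")


def parse_nucocog_xml(path: str | Path, source: str | None = None) -> Dataset:
    """Parse an ortholog dataset from the package's XML dialect.

    The dialect is ``<dataset source=...>`` containing ``<organism id name/>``
    elements followed by ``<cog id desc>`` elements, each holding ``<seq org
    protein_gi gene_gi><aa>...</aa><nt>...</nt></seq>`` members.  Unknown
    attributes are ignored so that enriched files remain readable.  CDS
    sequences are uppercased and RNA ``U`` is normalized to ``T``.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise DataError(f"malformed XML in {path}: {exc} (line {exc.position[0]})") from exc
    root = tree.getroot()
    ds = Dataset(source=source or root.get("source", "cog"))
    if ds.source not in ("cog", "arcog", "combined"):
        raise DataError(f"unknown dataset source {ds.source!r}")
    for el in root.iter("organism"):
        org_id = el.get("id")
        if not org_id:
            raise DataError(f"{path}: <organism> element without id attribute")
        ds.organisms[org_id] = OrganismRecord(org_id, el.get("name", org_id))
    for cog_el in root.iter("cog"):
        cog_id = cog_el.get("id")
        if not cog_id or not _COG_RE.match(cog_id):
            raise DataError(f"{path}: bad COG id {cog_id!r}")
        ds.cogs[cog_id] = CogRecord(cog_id, cog_el.get("desc", ""))
        for seq_el in cog_el.iter("seq"):
            rec = SequenceRecord(
                organism_id=seq_el.get("org", ""),
                cog_id=cog_id,
                protein_gi=seq_el.get("protein_gi", ""),
                gene_gi=seq_el.get("gene_gi", ""),
                aa_seq=_norm_aa(seq_el.findtext("aa") or ""),
                nt_seq=_norm_nt(seq_el.findtext("nt") or ""),
            )
            ds.add_sequence(rec)
    ds.validate()
    return ds


def write_nucocog_xml(dataset: Dataset, path: str | Path) -> None:
    """Serialize a dataset back to the XML dialect (deterministic ordering)."""
    root = ET.Element("dataset", source=dataset.source)
    for org_id in sorted(dataset.organisms):
        org = dataset.organisms[org_id]
        ET.SubElement(root, "organism", id=org.organism_id, name=org.display_name)
    by_cog: dict[str, list[SequenceRecord]] = {c: [] for c in dataset.cogs}
    for rec in dataset.sequences:
        by_cog[rec.cog_id].append(rec)
    for cog_id in sorted(dataset.cogs):
        cog = dataset.cogs[cog_id]
        cog_el = ET.SubElement(root, "cog", id=cog.cog_id, desc=cog.description)
        for rec in sorted(by_cog[cog_id], key=lambda s: s.key):
            seq_el = ET.SubElement(cog_el, "seq", org=rec.organism_id,
                                   protein_gi=rec.protein_gi, gene_gi=rec.gene_gi)
            ET.SubElement(seq_el, "aa").text = rec.aa_seq
            ET.SubElement(seq_el, "nt").text = rec.nt_seq
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=False)
    with open(path, "a") as fh:
        fh.write("\n")


def parse_fasta_bundle(protein_dir: str | Path, cds_dir: str | Path,
                       manifest: str | Path, source: str = "cog") -> Dataset:
    """Build a dataset from per-COG FASTA files.

    ``protein_dir`` holds one protein FASTA per COG (``<COGID>.faa``, headers
    ``organism_id|protein_gi|gene_gi``); ``cds_dir`` the matching CDS FASTA
    (``<COGID>.fna``).  ``manifest`` is a TSV mapping organism_id to display
    name.  A protein without a CDS partner is kept protein-only with a
    warning, mirroring partially paired collections.
    """
    protein_dir, cds_dir = Path(protein_dir), Path(cds_dir)
    ds = Dataset(source=source)
    with open(manifest) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"manifest line {line!r}: expected organism_id<TAB>name")
            ds.organisms[parts[0]] = OrganismRecord(parts[0], parts[1])

    def split_header(header: str, where: str) -> tuple[str, str, str]:
        fields = header.split("|")
        if len(fields) != 3 or not all(fields):
            raise DataError(
                f"{where}: header {header!r} does not match organism_id|protein_gi|gene_gi")
        return fields[0], fields[1], fields[2]

    for faa in sorted(protein_dir.glob("*.faa")):
        cog_id = faa.stem
        if not _COG_RE.match(cog_id):
            raise DataError(f"{faa}: file name is not a COG id")
        ds.cogs[cog_id] = CogRecord(cog_id)
        cds_path = cds_dir / f"{cog_id}.fna"
        cds: dict[tuple[str, str], str] = {}
        if cds_path.exists():
            for rec in SeqIO.parse(str(cds_path), "fasta"):
                org, pgi, _ = split_header(rec.id, str(cds_path))
                cds[(org, pgi)] = _norm_nt(str(rec.seq))
        for rec in SeqIO.parse(str(faa), "fasta"):
            org, pgi, ggi = split_header(rec.id, str(faa))
            nt = cds.get((org, pgi), "")
            if not nt:
                log.warning("protein %s (%s, %s) has no CDS partner; kept protein-only",
                            pgi, org, cog_id)
            ds.add_sequence(SequenceRecord(org, cog_id, pgi, ggi,
                                           _norm_aa(str(rec.seq)), nt))
    ds.validate()
    return ds


def load_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a flat lineage TSV (organism_id + the seven supported ranks).

    Empty cells are allowed except ``species``; missing ranks are simply
    absent from the returned lineage maps.
    """
    lineages: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "organism_id" not in reader.fieldnames:
            raise DataError(f"{path}: missing organism_id column")
        missing_cols = [r for r in RANKS if r not in reader.fieldnames]
        if missing_cols:
            raise DataError(f"{path}: missing rank column(s) {missing_cols}")
        for row in reader:
            org_id = (row["organism_id"] or "").strip()
            if not org_id:
                continue
            if org_id in lineages:
                raise DataError(f"{path}: duplicate organism_id {org_id!r}")
            lineage = {rank: row[rank].strip() for rank in RANKS
                       if (row.get(rank) or "").strip()}
            if "species" not in lineage:
                raise DataError(f"{path}: organism {org_id!r} has no species")
            lineages[org_id] = lineage
    return lineages


def load_traits(path: str | Path) -> dict[str, tuple[str, float | None]]:
    """Load an organism trait TSV: organism_id, oxygen_class, ogt (degC).

    Unrecognized oxygen strings map to ``unknown`` with a warning; a blank
    OGT cell means the value is absent, any other non-numeric cell is an
    error.
    """
    traits: dict[str, tuple[str, float | None]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"organism_id", "oxygen_class", "ogt"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DataError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            org_id = (row["organism_id"] or "").strip()
            if not org_id:
                continue
            oxygen = (row["oxygen_class"] or "").strip().lower()
            if oxygen not in OXYGEN_CLASSES:
                log.warning("organism %s: oxygen class %r not recognized, using 'unknown'",
                            org_id, oxygen)
                oxygen = "unknown"
            raw_ogt = (row["ogt"] or "").strip()
            if raw_ogt:
                try:
                    ogt: float | None = float(raw_ogt)
                except ValueError:
                    raise DataError(
                        f"{path}: organism {org_id!r} has non-numeric OGT {raw_ogt!r}") from None
            else:
                ogt = None
            traits[org_id] = (oxygen, ogt)
    return traits


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.4f}"


def write_ranking_tsv(rows: Iterable["ScoreRow"], path: str | Path,
                      normalized: bool = False) -> None:
    """Write a ranking table as TSV.

    Scores are rendered with 4 decimal places; when a normalization mode was
    active the selected/total feature counts backing the score are included
    as extra columns.
    """
    rows = list(rows)
    subgrouped = any(r.subgroup is not None for r in rows)
    header = ["#", "group"]
    if subgrouped:
        header.append("subgroup")
    header.append("APSF")
    if normalized:
        header += ["score", "Number of selected features", "Total number of features"]
    header += ["n_sequences", "n_skipped", "description"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for i, row in enumerate(rows, 1):
            out: list[str] = [str(i), row.group_label]
            if subgrouped:
                out.append(row.subgroup or "")
            out.append(_fmt(row.apsf))
            if normalized:
                out += [_fmt(row.score), str(row.selected_feature_count),
                        str(row.total_feature_count)]
            out += [str(row.n_sequences), str(row.n_skipped), row.description]
            writer.writerow(out)


def write_members_tsv(dataset: Dataset, cog_id: str, path: str | Path,
                      selection: "Selection | None" = None) -> None:
    """List a COG's member sequences (the per-COG drill-down table)."""
    records = dataset.sequences_of_cog(cog_id)
    if selection is not None:
        records = [r for r in records if r.organism_id in selection.organism_ids]
    desc = dataset.cogs[cog_id].description
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["domain", "protein_gi", "gene_gi", "cog", "organism"])
        for rec in sorted(records, key=lambda r: r.key):
            org = dataset.organisms[rec.organism_id]
            writer.writerow([desc, rec.protein_gi, rec.gene_gi, rec.cog_id,
                             org.display_name or org.organism_id])


def export_fasta(dataset: Dataset, path: str | Path, kind: str = "protein",
                 cog_ids: Iterable[str] | None = None,
                 selection: "Selection | None" = None) -> int:
    """Export sequences of a COG subset / organism selection as FASTA.

    Returns the number of records written.  ``kind`` is ``protein`` or
    ``cds``; protein-only records are silently omitted from CDS exports.
    """
    if kind not in ("protein", "cds"):
        raise DataError(f"unknown export kind {kind!r}")
    wanted = set(cog_ids) if cog_ids is not None else None
    if wanted is not None:
        unknown = wanted - set(dataset.cogs)
        if unknown:
            raise DataError(f"unknown COG(s) {sorted(unknown)}")
    records = []
    for rec in sorted(dataset.sequences, key=lambda r: (r.cog_id,) + r.key):
        if wanted is not None and rec.cog_id not in wanted:
            continue
        if selection is not None and rec.organism_id not in selection.organism_ids:
            continue
        seq = rec.aa_seq if kind == "protein" else rec.nt_seq
        if not seq:
            continue
        records.append(_BioRecord(Seq(seq),
                                  id=f"{rec.organism_id}|{rec.protein_gi}|{rec.gene_gi}",
                                  description=rec.cog_id))
    SeqIO.write(records, str(path), "fasta")
    return len(records)
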