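"""Genome data model, format I/O and the representative-species filter.

The pipeline's genomic inputs are deliberately minimal: gene coordinates and
order (GFF3), coding/protein sequences (FASTA, headers starting with the gene
identifier), all-vs-all similarity hits (12-column tabular search output) and
a species metadata table (TSV).  This module parses and validates those
formats and defines the in-memory types every downstream stage consumes.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "Gene",
    "Genome",
    "SpeciesRecord",
    "Hit",
    "GffParseError",
    "ValidationError",
    "read_gff",
    "write_gff",
    "read_fasta",
    "read_hits",
    "read_species_table",
    "write_species_table",
    "select_representatives",
]


class GffParseError(ValueError):
    """Raised for malformed GFF3 or hit-table input; message names the line."""


class ValidationError(ValueError):
    """Raised when parsed input violates a data-model invariant."""


@dataclass(frozen=True)
class Gene:
    """A single gene on a replicon.

    Coordinates are 1-based inclusive (GFF3 convention); ``index`` is the
    0-based rank of the gene along its replicon after sorting by
    (start, end, gene_id).
    """

    gene_id: str
    species_id: str
    replicon_id: str
    index: int
    start: int
    end: int
    strand: str = "+"
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def with_family(self, family_id: str | None) -> "Gene":
        return replace(self, family_id=family_id)


@dataclass
class Genome:
    """All replicons of one species as ordered, stranded gene lists."""

    species_id: str
    replicons: dict[str, list[Gene]] = field(default_factory=dict)

    def genes(self) -> Iterable[Gene]:
        for replicon in self.replicons.values():
            yield from replicon

    def gene_index(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes()}

    def annotate_families(self, families: Mapping[str, str]) -> "Genome":
        """Return a copy with ``family_id`` filled in from a gene→family map."""
        out = Genome(self.species_id)
        for rep_id, genes in self.replicons.items():
            out.replicons[rep_id] = [g.with_family(families.get(g.gene_id)) for g in genes]
        return out


@dataclass(frozen=True)
class SpeciesRecord:
    species_id: str
    genus: str
    order_name: str
    strain: str


@dataclass(frozen=True)
class Hit:
    """One row of a 12-column tabular similarity search.

    Coverage values are derived from the alignment length and the query /
    subject sequence lengths when those lengths are supplied to
    :func:`read_hits`; otherwise they default to 1.0.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    query_cov: float = 1.0
    subject_cov: float = 1.0
    self_hit: bool = False


# ---------------------------------------------------------------------------
# GFF3


def _order_genes(raw: list[tuple[str, str, int, int, str]], species_id: str,
                 replicon_id: str) -> list[Gene]:
    raw_sorted = sorted(raw, key=lambda r: (r[2], r[3], r[0]))
    return [
        Gene(gene_id=gid, species_id=species_id, replicon_id=replicon_id,
             index=i, start=start, end=end, strand=strand)
        for i, (gid, _rep, start, end, strand) in enumerate(raw_sorted)
    ]


def read_gff(path: str | Path, *, species_attr: str = "species",
             default_species: str | None = None,
             feature_types: Sequence[str] = ("gene", "CDS")) -> list[Genome]:
    """Parse a GFF3 file into one :class:`Genome` per species.

    The species of each feature is taken from the attribute named by
    ``species_attr``; if absent the file-level ``default_species`` applies
    (defaulting to the file stem, the one-file-per-species convention).
    Gene order within each replicon is by start coordinate, ties broken by
    end coordinate then gene identifier; indices restart at 0 per replicon.
    """
    path = Path(path)
    if default_species is None:
        default_species = path.stem
    # (species, replicon) -> raw rows
    buckets: dict[tuple[str, str], list[tuple[str, str, int, int, str]]] = {}
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GffParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attr_map = _parse_attributes(attrs, path, lineno)
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise GffParseError(f"{path}:{lineno}: feature lacks an ID attribute")
            if gene_id in seen_ids:
                raise ValidationError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen_ids.add(gene_id)
            species = attr_map.get(species_attr, default_species)
            if strand not in {"+", "-"}:
                strand = "+"
            buckets.setdefault((species, seqid), []).append(
                (gene_id, seqid, start, end, strand)
            )
    genomes: dict[str, Genome] = {}
    for (species, replicon_id), raw in buckets.items():
        genome = genomes.setdefault(species, Genome(species))
        genome.replicons[replicon_id] = _order_genes(raw, species, replicon_id)
    return list(genomes.values())


def _parse_attributes(attrs: str, path: Path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise GffParseError(f"{path}:{lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = value
    return out


def write_gff(genomes: Iterable[Genome], path: str | Path, *,
              species_attr: str = "species") -> None:
    """Write genomes back to GFF3 (gene features, round-trip compatible)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for genome in genomes:
            for rep_id in genome.replicons:
                for g in genome.replicons[rep_id]:
                    attrs = f"ID={g.gene_id};{species_attr}={g.species_id}"
                    fh.write(
                        f"{rep_id}\tceseek\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA and hit tables


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by the first whitespace-delimited header token."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_hits(path: str | Path,
              lengths: Mapping[str, int] | None = None) -> list[Hit]:
    """Read a 12-column tabular hit file (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Self-hits (query == subject) are retained but flagged.  If ``lengths``
    maps sequence ids to their lengths, query/subject coverages are computed
    as alignment length over sequence length (capped at 1).
    """
    hits: list[Hit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise GffParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            try:
                pident = float(fields[2])
                aln_len = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise GffParseError(f"{path}:{lineno}: unparseable numeric field") from None
            qcov = scov = 1.0
            if lengths is not None:
                if q in lengths and lengths[q] > 0:
                    qcov = min(1.0, aln_len / lengths[q])
                if s in lengths and lengths[s] > 0:
                    scov = min(1.0, aln_len / lengths[s])
            hits.append(Hit(q, s, pident, aln_len, evalue, bitscore,
                            qcov, scov, self_hit=(q == s)))
    return hits


# ---------------------------------------------------------------------------
# Species metadata and the representative filter


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"species_id", "genus", "order_name", "strain"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{path}: species table needs columns {sorted(required)}"
            )
        return [
            SpeciesRecord(row["species_id"], row["genus"], row["order_name"], row["strain"])
            for row in reader
        ]


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["species_id", "genus", "order_name", "strain"])
        for r in records:
            writer.writerow([r.species_id, r.genus, r.order_name, r.strain])


def select_representatives(records: Sequence[SpeciesRecord],
                           seed: int) -> list[SpeciesRecord]:
    """Apply the representative-species filter.

    Three rules, in order: (i) one strain per species (lexicographically
    first strain id); (ii) any genus left with more than five species is
    down-sampled to exactly two, drawn without replacement from a seeded
    random stream; (iii) any order left with fewer than six species is
    dropped entirely.  Output preserves input order and is reproducible for
    a fixed seed.
    """
    if not records:
        raise ValidationError("species table is empty")

    # (i) one strain per species
    by_species: dict[str, SpeciesRecord] = {}
    for rec in records:
        cur = by_species.get(rec.species_id)
        if cur is None or rec.strain < cur.strain:
            by_species[rec.species_id] = rec
    kept = [r for r in records if by_species.get(r.species_id) is r]

    # (ii) genus down-sampling; genera visited in sorted order for determinism
    rng = random.Random(seed)
    by_genus: dict[str, list[SpeciesRecord]] = {}
    for rec in kept:
        by_genus.setdefault(rec.genus, []).append(rec)
    keep_ids: set[str] = set()
    for genus in sorted(by_genus):
        members = by_genus[genus]
        if len(members) > 5:
            chosen = rng.sample(sorted(m.species_id for m in members), 2)
            keep_ids.update(chosen)
        else:
            keep_ids.update(m.species_id for m in members)
    kept = [r for r in kept if r.species_id in keep_ids]

    # (iii) drop small orders
    order_counts: dict[str, int] = {}
    for rec in kept:
        order_counts[rec.order_name] = order_counts.get(rec.order_name, 0) + 1
    return [r for r in kept if order_counts[r.order_name] >= 6]
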