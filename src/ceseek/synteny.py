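"""Synteny-based assignment of orthologs among duplicated gene copies.

Concerted evolution and lineage-specific duplication both make a species'
paralogs cluster together in the gene tree; genomic context tells them
apart.  Copies of a family in different species are declared syntenic
orthologs when they share enough flanking-gene families (at least three by
default), and the connected components of that evidence graph — *synteny
types* — represent ancestral loci.  Two distinct types spanning several
species imply one duplication before speciation, the pattern expected under
concerted evolution and not under independent duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genome_io import Gene, Genome, Hit, ValidationError

__all__ = [
    "OrthologPair",
    "SyntenyType",
    "SyntenyConflict",
    "reciprocal_best_hits",
    "flank_profile",
    "assign_syntenic_orthologs",
]


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal best hit between genes of two species."""

    gene_a: str
    gene_b: str
    bitscore: float


@dataclass
class SyntenyType:
    """A cross-species set of copies occupying one conserved genomic context."""

    type_id: str
    family_id: str
    members: dict[str, str]  # species_id -> gene_id
    evidence: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.members)

    def min_evidence(self) -> int:
        return min(self.evidence.values()) if self.evidence else 0


@dataclass(frozen=True)
class SyntenyConflict:
    """Same-species copies found in one component with tied link strengths."""

    family_id: str
    species_id: str
    genes: tuple[str, ...]


def reciprocal_best_hits(hits: Iterable[Hit], species_of: Mapping[str, str],
                         species_a: str, species_b: str) -> list[OrthologPair]:
    """Reciprocal best hits between two species.

    Each gene's best cross-species hit is chosen by bitscore, ties broken by
    higher percent identity, then lexicographically smaller subject id; a
    pair is emitted iff the choice is mutual.
    """
    best: dict[str, tuple[float, float, str]] = {}
    for h in hits:
        if h.self_hit:
            continue
        sq = species_of.get(h.query_id)
        ss = species_of.get(h.subject_id)
        if {sq, ss} != {species_a, species_b} or sq == ss:
            continue
        # rank: maximize bitscore, then identity, then prefer smaller subject id
        rank = (h.bitscore, h.pct_identity)
        cur = best.get(h.query_id)
        if (cur is None or rank > (cur[0], cur[1])
                or (rank == (cur[0], cur[1]) and h.subject_id < cur[2])):
            best[h.query_id] = (h.bitscore, h.pct_identity, h.subject_id)
    pairs: list[OrthologPair] = []
    for gene, (bits, _ident, partner) in sorted(best.items()):
        back = best.get(partner)
        if back is not None and back[2] == gene and gene < partner:
            pairs.append(OrthologPair(gene, partner, bits))
    return pairs


def flank_profile(genome: Genome, gene: Gene, w: int = 5) -> list[str]:
    """Families of up to ``w`` genes on each side of ``gene`` on its replicon.

    Strand-agnostic; replicon ends truncate the window (no wraparound).
    Neighbours without a family assignment and neighbours from the focal
    gene's own family are excluded.
    """
    replicon = genome.replicons.get(gene.replicon_id)
    if replicon is None:
        raise ValidationError(
            f"gene {gene.gene_id}: replicon {gene.replicon_id!r} not in genome"
        )
    i = gene.index
    window = replicon[max(0, i - w): i] + replicon[i + 1: i + 1 + w]
    return [
        g.family_id for g in window
        if g.family_id is not None and g.family_id != gene.family_id
    ]


def assign_syntenic_orthologs(genomes: Sequence[Genome], target_family: str,
                              w: int = 5, min_flank: int = 3,
                              ) -> tuple[list[SyntenyType], list[SyntenyConflict]]:
    """Group the copies of ``target_family`` into synteny types.

    Copies from different species are linked when their flank profiles share
    at least ``min_flank`` families; synteny types are the connected
    components with >= 2 species.  A component holding two copies of the
    same species is split by iteratively removing its weakest link; when the
    weakest links tie, the offending species' copies are dropped from the
    component and reported as a conflict rather than silently resolved.
    """
    copies: list[tuple[Genome, Gene]] = []
    for genome in genomes:
        for gene in genome.genes():
            if gene.family_id == target_family:
                copies.append((genome, gene))
    if not copies:
        raise ValidationError(f"family {target_family!r} has no located copies")

    profiles = {
        gene.gene_id: set(flank_profile(genome, gene, w=w))
        for genome, gene in copies
    }
    species = {gene.gene_id: gene.species_id for _genome, gene in copies}

    graph = nx.Graph()
    graph.add_nodes_from(sorted(profiles))
    ids = sorted(profiles)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if species[a] == species[b]:
                continue
            shared = len(profiles[a] & profiles[b])
            if shared >= min_flank:
                graph.add_edge(a, b, weight=shared)

    conflicts: list[SyntenyConflict] = []
    _resolve_same_species(graph, species, target_family, conflicts)

    types: list[SyntenyType] = []
    components = sorted((sorted(c) for c in nx.connected_components(graph)),
                        key=lambda c: c[0])
    k = 0
    for comp in components:
        comp_species = {species[g] for g in comp}
        if len(comp_species) < 2:
            continue
        k += 1
        members = {species[g]: g for g in comp}
        evidence = {
            (min(a, b), max(a, b)): graph.edges[a, b]["weight"]
            for a, b in graph.subgraph(comp).edges
        }
        types.append(SyntenyType(f"T{k}", target_family, members, evidence))
    return types, conflicts


def _resolve_same_species(graph: nx.Graph, species: Mapping[str, str],
                          family_id: str,
                          conflicts: list[SyntenyConflict]) -> None:
    """Break same-species co-occurrence inside components, in place."""
    while True:
        offending = None
        for comp in sorted((sorted(c) for c in nx.connected_components(graph)),
                           key=lambda c: c[0]):
            seen: dict[str, str] = {}
            for g in comp:
                sp = species[g]
                if sp in seen:
                    offending = (comp, sp)
                    break
                seen[sp] = g
            if offending:
                break
        if offending is None:
            return
        comp, sp = offending
        edges = sorted(graph.subgraph(comp).edges(data="weight"),
                       key=lambda e: (e[2], e[0], e[1]))
        min_w = edges[0][2]
        weakest = [e for e in edges if e[2] == min_w]
        if len(weakest) == 1:
            a, b, _w = weakest[0]
            graph.remove_edge(a, b)
        else:
            genes = tuple(sorted(g for g in comp if species[g] == sp))
            conflicts.append(SyntenyConflict(family_id, sp, genes))
            graph.remove_nodes_from(genes)
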