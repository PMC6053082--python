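"""Gene-family inference by Markov clustering of a similarity graph.

Families are built the way ortholog-clustering pipelines do it: all-vs-all
similarity hits are filtered and turned into a weighted undirected graph,
Markov clustering (MCL) is run at several inflation indices (granularities),
and the resulting partitions are merged.  The merge is a union of
co-membership: two genes end up in the same merged family if any single
inflation put them together.  The merged families feed a recall-oriented
initial screen; precision is recovered downstream by the synteny and
bootstrap-support filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .genome_io import Hit, ValidationError

__all__ = [
    "FamilySet",
    "build_graph",
    "mcl",
    "merge_family_sets",
    "cluster_families",
    "write_families",
    "read_families",
]

#: weight assigned to an E-value of exactly 0 (and cap for -log10 weights)
WEIGHT_CAP = 200.0


@dataclass
class FamilySet:
    """A disjoint partition of gene ids into families.

    ``assignments`` maps gene_id -> family_id.  ``provenance`` records the
    inflation indices used and any convergence warnings.
    """

    assignments: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, fam in self.assignments.items():
            out.setdefault(fam, []).append(gene)
        for members in out.values():
            members.sort()
        return out

    def members(self, family_id: str) -> list[str]:
        return sorted(g for g, f in self.assignments.items() if f == family_id)

    def __len__(self) -> int:
        return len(set(self.assignments.values()))


def build_graph(hits: Iterable[Hit], max_evalue: float = 1e-5,
                min_coverage: float = 0.5) -> nx.Graph:
    """Build the weighted similarity graph from hit records.

    A hit row survives iff its E-value is at most ``max_evalue`` and both
    coverages are at least ``min_coverage``.  Edge weight is -log10(E-value)
    capped at 200 (E-value 0 maps to the cap); reciprocal/duplicate rows for
    the same unordered pair are averaged.  Self-hits never become edges.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.self_hit or h.query_id == h.subject_id:
            continue
        if h.evalue > max_evalue:
            continue
        if h.query_cov < min_coverage or h.subject_cov < min_coverage:
            continue
        if h.evalue <= 0.0:
            w = WEIGHT_CAP
        else:
            w = min(WEIGHT_CAP, -np.log10(h.evalue))
        key = (h.query_id, h.subject_id) if h.query_id < h.subject_id else (
            h.subject_id, h.query_id)
        sums[key] = sums.get(key, 0.0) + w
        counts[key] = counts.get(key, 0) + 1
    graph = nx.Graph()
    for (a, b), total in sums.items():
        graph.add_edge(a, b, weight=total / counts[(a, b)])
    return graph


def mcl(graph: nx.Graph, inflation: float, max_iter: int = 200,
        tol: float = 1e-6, prune: float = 1e-8) -> FamilySet:
    """Markov clustering of the similarity graph at one inflation index.

    The column-stochastic transition matrix (self-loops of weight 1 added)
    is alternately expanded (squared) and inflated (entrywise power,
    columns renormalised); entries below ``prune`` are zeroed each round.
    Families are the connected components of the converged matrix's nonzero
    structure.  Inflation 1 disables the inflation operator, so clustering
    degenerates to the connected components of the expanded matrix.
    """
    if inflation <= 0:
        raise ValueError("inflation must be positive")
    if graph.number_of_nodes() == 0:
        raise ValidationError("mcl requires a non-empty graph")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    np.fill_diagonal(M, 1.0)  # self-loops keep singleton columns stochastic
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        if inflation != 1:
            M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M)
    for i, j in zip(rows.tolist(), cols.tolist()):
        if i != j:
            support.add_edge(i, j)
    components = sorted(
        (sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)),
        key=lambda c: c[0],
    )
    assignments = {
        gene: f"F{k:05d}" for k, comp in enumerate(components, start=1) for gene in comp
    }
    provenance = {"inflations": [inflation], "converged": converged}
    return FamilySet(assignments, provenance)


def merge_family_sets(sets: Sequence[FamilySet]) -> FamilySet:
    """Merge clusterings: union of co-membership across all input sets.

    Two genes share a merged family iff they co-occur in the same family in
    at least one input set; merged families are the connected components of
    the pooled co-membership graph.
    """
    if not sets:
        raise ValidationError("no family sets to merge")
    universe = set(sets[0].assignments)
    for fs in sets[1:]:
        if set(fs.assignments) != universe:
            raise ValidationError("family sets cover different gene universes")
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for fs in sets:
        for members in fs.families().values():
            anchor = members[0]
            for other in members[1:]:
                graph.add_edge(anchor, other)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    assignments = {
        gene: f"F{k:05d}" for k, comp in enumerate(components, start=1) for gene in comp
    }
    provenance = {
        "inflations": sorted({i for fs in sets for i in fs.provenance.get("inflations", [])}),
        "converged": all(fs.provenance.get("converged", True) for fs in sets),
        "merge": "union-of-co-membership",
    }
    return FamilySet(assignments, provenance)


def cluster_families(hits: Iterable[Hit],
                     inflations: Sequence[float] = (1, 1.5, 2, 4, 6),
                     max_evalue: float = 1e-5, min_coverage: float = 0.5,
                     **mcl_kwargs) -> FamilySet:
    """Convenience wrapper: graph construction, MCL per inflation, merge."""
    graph = build_graph(hits, max_evalue=max_evalue, min_coverage=min_coverage)
    if graph.number_of_nodes() == 0:
        return FamilySet({}, {"inflations": list(inflations), "converged": True})
    return merge_family_sets([mcl(graph, i, **mcl_kwargs) for i in inflations])


def write_families(families: FamilySet, path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tgene_id\n")
        for fam, members in sorted(families.families().items()):
            for gene in members:
                fh.write(f"{fam}\t{gene}\n")


def read_families(path) -> FamilySet:
    assignments: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family_id"):
            raise ValidationError(f"{path}: expected family_id\\tgene_id header")
        for line in fh:
            fam, gene = line.rstrip("\n").split("\t")
            assignments[gene] = fam
    return FamilySet(assignments, {"source": str(path)})
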