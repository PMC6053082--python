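"""Shared fixtures: small simulated datasets and tree-building helpers."""

from __future__ import annotations

import random

import dendropy
import pytest

from ceseek.ce_call import DatedSpeciesTree
from ceseek.pipeline import analyze_order
from ceseek.simulate import SimConfig, simulate_dataset
from ceseek.tree_infer import SupportTree, canonical_bipartition, iter_bipartitions

#: the simulator seeds at which the end-to-end recovery claims are made
E2E_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def sim_ancestral():
    """One ancestral-duplication dataset per stated seed."""
    return {seed: simulate_dataset(SimConfig(scenario="ancestral_dup", seed=seed))
            for seed in E2E_SEEDS}


@pytest.fixture(scope="session")
def pipeline_ancestral(sim_ancestral):
    out = {}
    for seed, ds in sim_ancestral.items():
        dated = DatedSpeciesTree.from_newick(ds.species_tree_newick(), is_path=False)
        out[seed] = analyze_order(ds.genomes, ds.sequences, ds.hits,
                                  dated_tree=dated, seed=seed)
    return out


def random_unrooted_tree(rng: random.Random, n_leaves: int,
                         n_species: int | None = None) -> SupportTree:
    """Random binary tree; leaf labels '<species>_g<i>' drawn over a species
    pool so that some species carry several paralogs."""
    n_species = n_species or max(2, n_leaves // 2)
    labels = [f"s{rng.randrange(n_species)}_g{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace()
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=label)
        node.edge.length = rng.uniform(0.1, 1.0)
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(0.1, 1.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return SupportTree(tree)


def topology_bipartitions(stree: SupportTree) -> set[frozenset]:
    """Canonical internal bipartitions — the unrooted topology fingerprint."""
    all_labels = frozenset(stree.leaf_labels())
    return {canonical_bipartition(side, all_labels)
            for side, _ in iter_bipartitions(stree)}
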