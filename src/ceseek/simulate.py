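"""Forward simulator for concerted-evolution test datasets.

The simulator produces a complete labelled dataset in the pipeline's own
input formats: a dated (ultrametric) species tree, per-species genomes with
a focal gene embedded in conserved flanking-gene neighbourhoods, coding
sequences evolved under Jukes–Cantor, an all-vs-all hit table derived from
pairwise identities, and a truth table recording which species experienced
gene conversion and which genomic context each copy occupies.

Four scenarios span the evolutionary hypotheses the pipeline must tell
apart:

* ``ancestral_dup`` — one duplication before the species radiation, then
  recurrent whole-gene conversion (copy-1 overwriting copy-2) as a Poisson
  process per lineage; the concerted-evolution signal.
* ``ancestral_dup_no_conv`` — the same duplication but no conversion;
  paralogs diverge independently.
* ``no_dup`` — a single-copy gene; the negative control.
* ``lineage_specific_dup`` — an independent tandem duplication on every
  terminal branch; paralogs cluster in the gene tree exactly as under
  concerted evolution, but the copies share a single genomic context, the
  pattern the synteny filter must reject.

The hit-table E-values and bitscores are synthetic stand-ins computed from
pairwise identity; the clustering module consumes them exactly as it would
real search output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .genome_io import Gene, Genome, Hit, SpeciesRecord, write_gff, write_species_table

__all__ = ["SimConfig", "SimDataset", "simulate_dataset", "evolve_sequence"]

SCENARIOS = ("ancestral_dup", "no_dup", "lineage_specific_dup", "ancestral_dup_no_conv")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
#: minimum pairwise identity for a row to appear in the synthetic hit table
MIN_REPORT_IDENTITY = 0.4


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults emulate an order-level prokaryote sample of the kind the
    pipeline targets: 8 species radiating over 500 Ma, a duplication at the
    radiation root, frequent whole-gene conversion (0.05 events per lineage
    per Ma, so homogenisation recurs every ~20 Ma), and a substitution rate
    (0.001 per site per Ma) that leaves deep orthologs clearly alignable
    yet well diverged.
    """

    n_species: int = 8
    tree_newick: str | None = None  # fixed topology overrides the Yule draw
    birth_rate: float = 1.0
    root_age_ma: float = 500.0
    dup_time_ma: float | None = None  # defaults to the root age
    conv_rate: float = 0.05      # conversion events / lineage / Ma
    sub_rate: float = 0.001      # substitutions / site / Ma (JC69)
    seq_len_codons: int = 300
    n_flank: int = 5
    scenario: str = "ancestral_dup"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; pick from {SCENARIOS}")
        if self.conv_rate < 0 or self.sub_rate < 0 or self.birth_rate <= 0:
            raise ValueError("rates must be non-negative (birth rate positive)")
        if self.dup_time_ma is None:
            self.dup_time_ma = self.root_age_ma
        if self.dup_time_ma > self.root_age_ma:
            raise ValueError("dup_time_ma must not exceed root_age_ma")
        if self.seq_len_codons < 10:
            raise ValueError("seq_len_codons must be >= 10")
        if self.n_species < 4:
            raise ValueError("need at least 4 species")


@dataclass
class SimDataset:
    """In-memory simulated dataset plus writers for the pipeline formats."""

    config: SimConfig
    species_tree: dendropy.Tree
    genomes: list[Genome]
    sequences: dict[str, str]
    hits: list[Hit]
    truth: dict
    species_records: list[SpeciesRecord] = field(default_factory=list)

    def species_tree_newick(self) -> str:
        return self.species_tree.as_string(
            schema="newick", suppress_rooting=True,
            real_value_format_specifier=".10f").strip()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "species_tree.nwk", "w") as fh:
            fh.write(self.species_tree_newick() + "\n")
        with open(out / "genes.fna", "w") as fh:
            for gene_id in sorted(self.sequences):
                fh.write(f">{gene_id}\n{self.sequences[gene_id]}\n")
        write_gff(sorted(self.genomes, key=lambda g: g.species_id),
                  out / "genomes.gff")
        with open(out / "hits.tsv", "w") as fh:
            for h in self.hits:
                mism = round(h.aln_length * (1 - h.pct_identity / 100.0))
                fh.write("\t".join(map(str, [
                    h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                    h.aln_length, mism, 0, 1, h.aln_length, 1, h.aln_length,
                    f"{h.evalue:.3e}", f"{h.bitscore:.1f}"])) + "\n")
        write_species_table(self.species_records, out / "species.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence evolution


def evolve_sequence(seq: str | np.ndarray, branch_length_ma: float,
                    sub_rate: float, rng: np.random.Generator) -> str | np.ndarray:
    """Evolve a nucleotide sequence under JC69 for a given time.

    Each site substitutes with probability p = (3/4)(1 - exp(-4 r t / 3));
    a substituted site takes one of the three alternative bases uniformly.
    Accepts and returns either a string or a uint8 index array.
    """
    as_str = isinstance(seq, str)
    idx = _to_idx(seq) if as_str else seq.copy()
    t = branch_length_ma * sub_rate
    p = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    if p > 0:
        hit = rng.random(idx.shape[0]) < p
        n = int(hit.sum())
        if n:
            idx[hit] = (idx[hit] + rng.integers(1, 4, size=n)) % 4
    return _to_str(idx) if as_str else idx


def _to_idx(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.searchsorted(_BASES, raw)
    return idx.astype(np.uint8)


def _to_str(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode()


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Random in-frame coding sequence without stop codons."""
    codons = []
    while len(codons) < n_codons:
        codon = _to_str(rng.integers(0, 4, size=3).astype(np.uint8))
        if codon not in _STOPS:
            codons.append(codon)
    return _to_idx("".join(codons))


# ---------------------------------------------------------------------------
# Species tree


def _yule_dated_tree(cfg: SimConfig, rng: np.random.Generator) -> dendropy.Tree:
    """A pure-birth dated tree conditioned on n tips and root age.

    Non-root split times are drawn iid from the Yule density conditioned on
    the root age and joined in random (hence Yule-distributed) topology;
    ages are exact so the tree is ultrametric to machine precision.
    """
    n, t0, lam = cfg.n_species, cfg.root_age_ma, cfg.birth_rate
    if n == 2:
        ages = []
    else:
        # inverse-CDF draw of split times measured forward from the root
        u = rng.random(n - 2)
        s = -np.log1p(-u * (1.0 - math.exp(-lam * t0))) / lam
        ages = sorted((t0 - si for si in s), reverse=False)
    tns = dendropy.TaxonNamespace()
    nodes: list[tuple[dendropy.Node, float]] = []
    for i in range(n):
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=f"sp{i + 1:02d}")
        nodes.append((node, 0.0))
    for age in list(ages) + [t0]:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        (na, aa), (nb, ab) = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = age - aa
        nb.edge.length = age - ab
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, age))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0][0])
    tree.is_rooted = True
    return tree


def _node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    ages: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            child = node.child_nodes()[0]
            ages[node] = ages[child] + (child.edge.length or 0.0)
    return ages


# ---------------------------------------------------------------------------
# Dataset assembly


def simulate_dataset(cfg: SimConfig, out_dir: str | Path | None = None) -> SimDataset:
    """Simulate one dataset under the configured scenario.

    Returns the in-memory dataset; if ``out_dir`` is given the pipeline
    input files (Newick, FASTA, GFF3, hit TSV, species TSV, truth JSON)
    are written there as well.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.tree_newick is not None:
        tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
    else:
        tree = _yule_dated_tree(cfg, rng)
    ages = _node_ages(tree)
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    L = cfg.seq_len_codons * 3
    sequences: dict[str, str] = {}
    truth_species: dict[str, dict] = {sp: {"converted": False, "event_ages": []}
                                      for sp in species}
    syntype_of: dict[str, str] = {}
    family_of: dict[str, str] = {}

    # focal gene: copy histories down the species tree
    has_copy2 = cfg.scenario != "no_dup"
    ancestral = _random_cds(cfg.seq_len_codons, rng)
    focal: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in species}
    if cfg.scenario in ("ancestral_dup", "ancestral_dup_no_conv"):
        conv = cfg.conv_rate if cfg.scenario == "ancestral_dup" else 0.0
        # the duplication is ancestral to every sampled species: copies start
        # identical at the root split (stem divergence above the root is not
        # modelled; dup_time_ma below the root age is clamped to the root)
        _evolve_duplicated(tree, ages, ancestral, conv, cfg.sub_rate, rng,
                           focal, truth_species)
    elif cfg.scenario == "no_dup":
        _evolve_single(tree, ages, ancestral, cfg.sub_rate, rng, focal)
    else:  # lineage_specific_dup
        _evolve_tandem(tree, ages, ancestral, cfg.sub_rate, rng, focal)

    # flanking-gene families: single-copy, conserved across all species
    flank_sets = {"FL": cfg.n_flank, "FR": cfg.n_flank}
    if has_copy2 and cfg.scenario != "lineage_specific_dup":
        flank_sets.update({"GL": cfg.n_flank, "GR": cfg.n_flank})
    flank_seqs: dict[str, dict[str, np.ndarray]] = {}
    for prefix in sorted(flank_sets):
        for k in range(1, flank_sets[prefix] + 1):
            fam = f"{prefix}{k}"
            anc = _random_cds(cfg.seq_len_codons, rng)
            states: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in species}
            _evolve_single(tree, ages, anc, cfg.sub_rate, rng, states, key=fam)
            flank_seqs[fam] = {sp: states[sp][fam] for sp in species}

    # genomes: ordered gene lists with conserved neighbourhoods
    genomes: list[Genome] = []
    for sp in species:
        layout: list[tuple[str, str]] = []  # (locus name, truth family)
        fl = [f"FL{k}" for k in range(cfg.n_flank, 0, -1)]
        fr = [f"FR{k}" for k in range(1, cfg.n_flank + 1)]
        if cfg.scenario == "lineage_specific_dup":
            layout += [(f, f) for f in fl]
            layout += [("cp1", "FOCAL"), ("cp2", "FOCAL")]
            layout += [(f, f) for f in fr]
        else:
            layout += [(f, f) for f in fl]
            layout += [("cp1", "FOCAL")]
            layout += [(f, f) for f in fr]
            if has_copy2:
                gl = [f"GL{k}" for k in range(cfg.n_flank, 0, -1)]
                gr = [f"GR{k}" for k in range(1, cfg.n_flank + 1)]
                layout += [(f, f) for f in gl]
                layout += [("cp2", "FOCAL")]
                layout += [(f, f) for f in gr]
        genome = Genome(sp)
        genes = []
        for i, (locus, fam) in enumerate(layout):
            gene_id = f"{sp}_{locus}"
            start = 1 + i * (L + 100)
            genes.append(Gene(gene_id, sp, "chr1", i, start, start + L - 1, "+"))
            family_of[gene_id] = fam
            if locus in ("cp1", "cp2"):
                sequences[gene_id] = _to_str(focal[sp][locus])
                syntype_of[gene_id] = (
                    "type1" if locus == "cp1" or cfg.scenario == "lineage_specific_dup"
                    else "type2")
            else:
                sequences[gene_id] = _to_str(flank_seqs[fam][sp])
        genome.replicons["chr1"] = genes
        genomes.append(genome)

    hits = _identity_hits(sequences)
    records = [SpeciesRecord(sp, f"Genus_{sp}", "SimOrder", "strain1")
               for sp in species]
    truth = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "species": truth_species,
        "syntype_of": syntype_of,
        "family_of": family_of,
        "focal_family_members": sorted(g for g, f in family_of.items() if f == "FOCAL"),
    }
    dataset = SimDataset(cfg, tree, genomes, sequences, hits, truth, records)
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset


def _branch_events(length: float, rate: float, rng: np.random.Generator) -> list[float]:
    """Offsets (from the old end of the branch) of Poisson events."""
    n = rng.poisson(rate * length)
    return sorted(rng.uniform(0.0, length, size=int(n)).tolist()) if n else []


def _evolve_duplicated(tree, ages, ancestral, conv_rate, sub_rate, rng,
                       out, truth_species) -> None:
    """Joint (copy-1, copy-2) evolution with conversion copy-1 -> copy-2."""
    states = {tree.seed_node: (ancestral.copy(), ancestral.copy())}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        c1, c2 = states[parent]
        c1, c2 = c1.copy(), c2.copy()
        top_age = ages[parent]
        length = top_age - ages[node]
        offsets = _branch_events(length, conv_rate, rng) if conv_rate > 0 else []
        pos = 0.0
        for off in offsets:
            c1 = evolve_sequence(c1, off - pos, sub_rate, rng)
            c2 = evolve_sequence(c2, off - pos, sub_rate, rng)
            c2 = c1.copy()  # whole-gene homogenisation
            pos = off
        c1 = evolve_sequence(c1, length - pos, sub_rate, rng)
        c2 = evolve_sequence(c2, length - pos, sub_rate, rng)
        states[node] = (c1, c2)
        if node.is_leaf():
            sp = node.taxon.label
            event_ages = [top_age - off for off in offsets]
            truth_species[sp]["converted"] = bool(offsets)
            truth_species[sp]["event_ages"] = [round(a, 6) for a in event_ages]
            out[sp]["cp1"] = c1
            out[sp]["cp2"] = c2


def _evolve_single(tree, ages, ancestral, sub_rate, rng, out, key: str = "cp1") -> None:
    states = {tree.seed_node: ancestral.copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        length = ages[parent] - ages[node]
        seq = evolve_sequence(states[parent], length, sub_rate, rng)
        states[node] = seq
        if node.is_leaf():
            out[node.taxon.label][key] = seq


def _evolve_tandem(tree, ages, ancestral, sub_rate, rng, out) -> None:
    """Single-copy evolution with an independent duplication on each
    terminal branch at a uniform time; no conversion."""
    states = {tree.seed_node: ancestral.copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        length = ages[parent] - ages[node]
        if not node.is_leaf():
            states[node] = evolve_sequence(states[parent], length, sub_rate, rng)
            continue
        dup_offset = float(rng.uniform(0.0, length))
        seq = evolve_sequence(states[parent], dup_offset, sub_rate, rng)
        c1 = evolve_sequence(seq, length - dup_offset, sub_rate, rng)
        c2 = evolve_sequence(seq, length - dup_offset, sub_rate, rng)
        sp = node.taxon.label
        out[sp]["cp1"] = c1
        out[sp]["cp2"] = c2


def _identity_hits(sequences: dict[str, str]) -> list[Hit]:
    """All-vs-all hit rows from pairwise identity (equal-length sequences).

    bitscore proxy = identity x length; E-value proxy = 10^(-identity x
    length / 10).  Pairs below MIN_REPORT_IDENTITY are not reported, the
    analogue of a search tool's score cutoff.
    """
    ids = sorted(sequences)
    arrays = {g: _to_idx(sequences[g]) for g in ids}
    hits: list[Hit] = []
    for i, a in enumerate(ids):
        for b in ids[i:]:
            if len(arrays[a]) != len(arrays[b]):
                continue
            L = len(arrays[a])
            ident = float((arrays[a] == arrays[b]).mean())
            if a == b:
                hits.append(Hit(a, a, 100.0, L, 0.0, ident * L, self_hit=True))
                continue
            if ident < MIN_REPORT_IDENTITY:
                continue
            evalue = 10.0 ** (-ident * L / 10.0)
            bits = ident * L
            hits.append(Hit(a, b, 100.0 * ident, L, evalue, bits))
            hits.append(Hit(b, a, 100.0 * ident, L, evalue, bits))
    return hits
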