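"""Concerted-evolution calling, recurrence, duration and the dS/dN check.

A species' paralogs are called concertedly evolving when (i) they form a
same-species clan with bootstrap support of at least 70 and (ii) every
paralog has syntenic orthologs across species, with the paralogs occupying
at least two distinct synteny types.  The distinct-type requirement encodes
"duplication before speciation": copies of one family sitting in two
conserved genomic contexts shared across species cannot come from
independent lineage-specific duplications.

A family is *recurrent* when calls are made in at least five species.  The
minimum duration of the process is the age of the most recent common
ancestor of the calling species on a user-supplied dated (ultrametric)
species tree, in Ma: homogenisation observed in species that diverged T Ma
ago must have been maintained for at least T Ma.

Nei–Gojobori (1986) synonymous/non-synonymous counting is provided to test
the purifying-selection alternative: under selective convergence paralogs
would be similar at non-synonymous sites but divergent at synonymous sites,
whereas gene conversion homogenises both.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import dendropy

from .clan_scan import ParalogClanEvent
from .genome_io import Genome
from .synteny import SyntenyType

__all__ = [
    "CEEvent",
    "CEGeneReport",
    "DatedSpeciesTree",
    "Diagnostic",
    "NG86Result",
    "call_ce",
    "recurrence_filter",
    "estimate_duration",
    "ng86_identity",
    "codon_syn_sites",
]

MIN_SUPPORT_DEFAULT = 70
MIN_RECURRENCE_SPECIES = 5

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# standard genetic code (table 1); stops marked "*"
from Bio.Data import CodonTable as _BioCodonTable  # noqa: E402

_CODON_TABLE: dict[str, str] = dict(
    _BioCodonTable.unambiguous_dna_by_id[1].forward_table
)
_CODON_TABLE.update({stop: "*" for stop in _STOPS})


@dataclass(frozen=True)
class CEEvent:
    """A per-species concerted-evolution call."""

    family_id: str
    species_id: str
    paralogs: tuple[str, ...]
    support: int
    syntype_ids: tuple[str, ...]
    tandem: bool = False


@dataclass(frozen=True)
class Diagnostic:
    """Why a clan-positive species was not called (one reason each)."""

    family_id: str
    species_id: str
    reason: str  # low_support | no_synteny | same_type


@dataclass
class CEGeneReport:
    """Per-family roll-up of concerted-evolution calls."""

    family_id: str
    species: list[str]
    recurrent: bool
    order_name: str = ""
    duration_ma: float | None = None
    complex_annotation: str = ""
    tandem: bool = False

    @property
    def n_species(self) -> int:
        return len(self.species)


class DatedSpeciesTree:
    """A rooted ultrametric species tree with node ages in Ma."""

    def __init__(self, tree: dendropy.Tree, tolerance: float = 1e-6):
        tree.is_rooted = True
        tree.calc_node_ages(ultrametricity_precision=tolerance)
        self.tree = tree

    @classmethod
    def from_newick(cls, source: str | Path, tolerance: float = 1e-6,
                    is_path: bool = True) -> "DatedSpeciesTree":
        kwargs = {"path": str(source)} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
        return cls(tree, tolerance=tolerance)

    def species(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def mrca_age(self, species: Iterable[str]) -> float:
        wanted = sorted(set(species))
        missing = sorted(set(wanted) - self.species())
        if missing:
            raise ValueError(f"species absent from dated tree: {missing}")
        if len(wanted) < 2:
            raise ValueError("MRCA age needs at least 2 species")
        node = self.tree.mrca(taxon_labels=wanted)
        return float(node.age)

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)


# ---------------------------------------------------------------------------
# Calling


def call_ce(clans: Sequence[ParalogClanEvent], syntypes: Sequence[SyntenyType],
            min_support: int = MIN_SUPPORT_DEFAULT,
            genomes: Sequence[Genome] | None = None,
            ) -> tuple[list[CEEvent], list[Diagnostic]]:
    """Combine clan events and synteny types into per-species CE calls.

    Species failing a criterion are excluded from the events but tallied in
    the diagnostics with a single reason (checked in order: support, synteny
    membership, type distinctness).  A clan without a support value counts
    as unsupported.  When ``genomes`` are supplied, species whose paralogs
    are adjacent on one replicon are flagged tandem (surfaced, not excluded).
    """
    type_of: dict[str, str] = {}
    for st in syntypes:
        for gene in st.members.values():
            type_of[gene] = st.type_id
    gene_pos = {}
    if genomes is not None:
        for genome in genomes:
            for g in genome.genes():
                gene_pos[g.gene_id] = (g.replicon_id, g.index)

    events: list[CEEvent] = []
    diagnostics: list[Diagnostic] = []
    for clan in sorted(clans, key=lambda c: c.species_id):
        if clan.support is None or clan.support < min_support:
            diagnostics.append(Diagnostic(clan.family_id, clan.species_id, "low_support"))
            continue
        paralogs = tuple(sorted(clan.leaves))
        if any(g not in type_of for g in paralogs):
            diagnostics.append(Diagnostic(clan.family_id, clan.species_id, "no_synteny"))
            continue
        types = tuple(sorted({type_of[g] for g in paralogs}))
        if len(types) < 2:
            diagnostics.append(Diagnostic(clan.family_id, clan.species_id, "same_type"))
            continue
        tandem = False
        if gene_pos and all(g in gene_pos for g in paralogs):
            positions = sorted(gene_pos[g] for g in paralogs)
            tandem = any(
                a[0] == b[0] and b[1] - a[1] == 1
                for a, b in zip(positions, positions[1:])
            )
        events.append(CEEvent(clan.family_id, clan.species_id, paralogs,
                              clan.support, types, tandem))
    return events, diagnostics


def recurrence_filter(events: Sequence[CEEvent],
                      min_species: int = MIN_RECURRENCE_SPECIES,
                      order_of: Mapping[str, str] | None = None,
                      ) -> list[CEGeneReport]:
    """Roll CE events up to per-family reports with the recurrence flag.

    Families with at least one event are reported even when not recurrent;
    families with no events never enter the event stream and are absent.
    """
    by_family: dict[str, list[CEEvent]] = {}
    for ev in events:
        by_family.setdefault(ev.family_id, []).append(ev)
    reports: list[CEGeneReport] = []
    for family_id in sorted(by_family):
        fam_events = by_family[family_id]
        species = sorted({ev.species_id for ev in fam_events})
        orders = sorted({order_of[s] for s in species if s in order_of}) if order_of else []
        reports.append(CEGeneReport(
            family_id=family_id,
            species=species,
            recurrent=len(species) >= min_species,
            order_name=", ".join(orders),
            tandem=any(ev.tandem for ev in fam_events),
        ))
    return reports


def estimate_duration(report: CEGeneReport, dated: DatedSpeciesTree) -> float:
    """Minimum duration (Ma) = MRCA age of the species with CE calls."""
    if len(report.species) < 2:
        raise ValueError("duration needs CE calls in at least 2 species")
    return dated.mrca_age(report.species)


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) synonymous-site counting


class NG86Result(NamedTuple):
    S: float   # synonymous sites (averaged over the two sequences)
    N: float   # non-synonymous sites
    sd: float  # synonymous differences
    nd: float  # non-synonymous differences
    pS: float  # sd / S
    pN: float  # nd / N


def codon_syn_sites(codon: str) -> float:
    """Fractional count of synonymous sites in one codon.

    Each position contributes the fraction of its three possible point
    mutations that preserve the encoded amino acid; mutations creating a
    stop codon count as non-synonymous.
    """
    codon = codon.upper()
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if _CODON_TABLE[mutant] == aa and mutant not in _STOPS:
                s += 1.0 / 3.0
    return s


def _codon_path_differences(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) step counts over all minimal
    substitution paths between two codons; paths through stop codons are
    excluded unless every path is (then all are used)."""
    diff_positions = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_positions):
        cur = ca
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != cb:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:  # all minimal paths pass through a stop codon
        for order in itertools.permutations(diff_positions):
            cur = ca
            steps = []
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for before, after in steps:
            if _CODON_TABLE[before] == _CODON_TABLE[after]:
                sd += 1.0
            else:
                nd += 1.0
    k = len(paths)
    return sd / k, nd / k


def ng86_identity(cds_a: str, cds_b: str) -> NG86Result:
    """Nei–Gojobori proportions of synonymous and non-synonymous differences.

    Both sequences must be in-frame, gapless, of equal length divisible by
    3 and free of stop codons.  ``pS`` near ``pN`` (and both small) between
    paralogs is the signature of ongoing gene conversion; purifying
    selection alone would leave synonymous sites divergent.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"stop codon at position {i + 1}")
        if any(ch not in _BASES for ch in ca + cb):
            raise ValueError(f"non-ACGT base in codon at position {i + 1}")
        s_sites_a += codon_syn_sites(ca)
        s_sites_b += codon_syn_sites(cb)
        d_s, d_n = _codon_path_differences(ca, cb)
        sd += d_s
        nd += d_n
    S = (s_sites_a + s_sites_b) / 2.0
    N = len(a) - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    return NG86Result(S, N, sd, nd, pS, pN)
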