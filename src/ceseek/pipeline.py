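"""End-to-end driver: hits + genomes + sequences -> CE gene reports.

The analysis unit is the taxonomic order: all genomes handed to
:func:`analyze_order` are assumed to belong to one order and are analysed
jointly.  The driver reproduces the two-round design of the detection
procedure — a fast screen (point-estimate trees, support ignored) selects
candidate families, and only candidates get the expensive bootstrapped
trees, synteny typing and the final support-gated calls.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ce_call import (CEEvent, CEGeneReport, DatedSpeciesTree, Diagnostic,
                      call_ce, estimate_duration, recurrence_filter)
from .clan_scan import ParalogClanEvent, find_species_clans, initial_selection
from .family_clustering import FamilySet, cluster_families
from .genome_io import Genome, Hit
from .synteny import SyntenyConflict, SyntenyType, assign_syntenic_orthologs
from .tree_infer import (Alignment, SupportTree, bootstrap_support,
                         jc_distance_matrix, nj)

__all__ = ["PipelineResult", "analyze_order"]


@dataclass
class PipelineResult:
    families: FamilySet
    candidates: list[str]
    screen_events: dict[str, list[ParalogClanEvent]]
    events: list[CEEvent]
    diagnostics: list[Diagnostic]
    reports: list[CEGeneReport]
    syntypes: dict[str, list[SyntenyType]] = field(default_factory=dict)
    conflicts: list[SyntenyConflict] = field(default_factory=list)
    trees: dict[str, SupportTree] = field(default_factory=dict)
    skipped_families: list[str] = field(default_factory=list)

    def ce_species(self, family_id: str) -> set[str]:
        return {e.species_id for e in self.events if e.family_id == family_id}


def _family_seed(base_seed: int, family_id: str) -> int:
    return (base_seed * 100003 + zlib.crc32(family_id.encode())) % (2 ** 31)


def analyze_order(genomes: Sequence[Genome], sequences: Mapping[str, str],
                  hits: Sequence[Hit], *,
                  dated_tree: DatedSpeciesTree | None = None,
                  seed: int = 0,
                  inflations: Sequence[float] = (1, 1.5, 2, 4, 6),
                  n_boot: int = 500,
                  min_support: int = 70,
                  min_species: int = 5,
                  window: int = 5,
                  min_flank: int = 3,
                  max_evalue: float = 1e-5,
                  min_coverage: float = 0.5) -> PipelineResult:
    """Run the full detection pipeline on one order's worth of genomes.

    ``sequences`` must hold aligned (equal-length, gap-free or gapped)
    CDS rows per gene; families whose member sequences have unequal
    lengths are skipped and listed in ``skipped_families``.
    """
    species_of = {g.gene_id: genome.species_id
                  for genome in genomes for g in genome.genes()}
    families = cluster_families(hits, inflations=inflations,
                                max_evalue=max_evalue, min_coverage=min_coverage)
    annotated = [g.annotate_families(families.assignments) for g in genomes]
    fam_members = families.families()

    # round 1: fast screen on point-estimate trees, supports ignored
    screen_events: dict[str, list[ParalogClanEvent]] = {}
    skipped: list[str] = []
    for fam in sorted(fam_members):
        members = [m for m in fam_members[fam] if m in sequences]
        if len(members) < 4:
            continue
        per_species: dict[str, int] = {}
        for m in members:
            sp = species_of.get(m)
            if sp:
                per_species[sp] = per_species.get(sp, 0) + 1
        if not per_species or max(per_species.values()) < 2:
            continue
        try:
            aln = Alignment({m: sequences[m] for m in members})
        except ValueError:
            skipped.append(fam)
            continue
        D, labels = jc_distance_matrix(aln)
        point = nj(D, labels)
        events = find_species_clans(point, family_id=fam)
        if events:
            screen_events[fam] = events
    candidates = initial_selection(screen_events, min_species=min_species)

    # round 2: bootstrapped trees, synteny types, support-gated calls
    all_events: list[CEEvent] = []
    all_diags: list[Diagnostic] = []
    syntypes: dict[str, list[SyntenyType]] = {}
    conflicts: list[SyntenyConflict] = []
    trees: dict[str, SupportTree] = {}
    for fam in candidates:
        members = [m for m in fam_members[fam] if m in sequences]
        aln = Alignment({m: sequences[m] for m in members})
        stree = bootstrap_support(aln, n_reps=n_boot,
                                  seed=_family_seed(seed, fam))
        trees[fam] = stree
        clans = find_species_clans(stree, family_id=fam)
        types, fam_conflicts = assign_syntenic_orthologs(
            annotated, fam, w=window, min_flank=min_flank)
        syntypes[fam] = types
        conflicts.extend(fam_conflicts)
        events, diags = call_ce(clans, types, min_support=min_support,
                                genomes=annotated)
        all_events.extend(events)
        all_diags.extend(diags)

    reports = recurrence_filter(all_events, min_species=min_species)
    if dated_tree is not None:
        for report in reports:
            if len(report.species) >= 2:
                report.duration_ma = estimate_duration(report, dated_tree)
    return PipelineResult(
        families=families,
        candidates=candidates,
        screen_events=screen_events,
        events=all_events,
        diagnostics=all_diags,
        reports=reports,
        syntypes=syntypes,
        conflicts=conflicts,
        trees=trees,
        skipped_families=skipped,
    )
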