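# Methods

## The decision rule

`ceseek` calls a species *concertedly evolving* for a gene family when two
independent lines of evidence agree:

1. **Phylogeny.** The species' complete set of paralogs forms a clan — one
   side of an edge bipartition of the unrooted gene tree — with bootstrap
   support ≥ 70 on the defining edge. Monophyly is deliberately tested in
   its unrooted form: gene trees from distance or likelihood methods carry
   no meaningful root, and a clan test gives identical answers under any
   rooting (verified by a root-invariance test).
2. **Synteny.** Every paralog belongs to a synteny type (a cross-species
   set of copies sharing ≥ `min_flank` = 3 flanking gene families within a
   window of `w` = 5 genes per side) spanning ≥ 2 species, and the paralogs
   occupy ≥ 2 *distinct* types. Distinctness encodes "duplication before
   speciation": two conserved contexts shared across species cannot be
   produced by independent per-lineage duplications.

A family is *recurrent* when ≥ 5 species are called — deliberately a count
of species, not of conversion events, since a single deep conversion
followed by vertical descent would also leave similar paralogs in related
species; requiring five independent lineages makes sustained, repeated
homogenisation the parsimonious reading. The *minimum duration* is the age
of the most recent common ancestor of the calling species (not of all
species analysed) on a dated ultrametric species tree: homogenisation seen
in species that split T Ma ago must have persisted for at least T Ma. Both
thresholds (support 70, five species) are conventional cut-offs exposed as
parameters.

Species whose clans fail a criterion are tallied with a single reason
(`low_support`, `no_synteny`, `same_type`); the reasons partition all
clan-positive, call-negative species, so nothing is silently dropped.
Adjacent (tandem) paralogs are flagged but not excluded — tandem location
weakens the case for ancient duplication and readers should see it.

## Two-round design

Gene families come from Markov clustering of the hit graph at inflation
indices 1, 1.5, 2, 4, 6, merged by **union of co-membership**. The merge
rule is intentionally recall-oriented: a union can only lump, never split,
so a true family fragmented at one granularity is still screened, and the
synteny and support gates downstream supply the precision. Inflation 1
disables the inflation operator and degenerates to connected components of
the expanded matrix — the coarsest partition in the merge. MCL numerics:
self-loop weight 1 before column normalisation, pruning threshold 1e-8,
convergence tolerance 1e-6, at most 200 iterations; non-convergence is
surfaced as a provenance flag, not an error.

Round one builds plain neighbor-joining trees (Jukes–Cantor distances) and
keeps families with clans in ≥ 5 species, ignoring support. Round two
spends the bootstrap (default 500 replicates) only on those candidates.

## Tree inference

The internal tree route is a self-contained distance pipeline: JC69
distances with gap/N sites excluded pairwise, a saturation ceiling of 5.0
substitutions/site where the observed difference p ≥ 3/4 (the JC transform
is undefined there), canonical NJ agglomeration with deterministic
tie-breaking and negative branch estimates clamped to zero. The decision
rule consumes only topology and support, so a richer substitution model
would change little; externally built maximum-likelihood trees can be
imported from Newick (supports on internal node labels; fractions in [0,1]
are rescaled to percentages). Bootstrap supports are bipartition
frequencies over column resamples from a seeded generator; identical seeds
give byte-identical trees.

## Synteny typing

Flank profiles are strand-agnostic and compared as sets, so inversions that
preserve neighbourhood content still count as shared context; replicon ends
truncate the window and there is no wraparound. A component containing two
copies from the same species is contradictory (a type models one ancestral
locus, ≤ 1 copy per species); it is split by removing its weakest link
(lowest shared-flank count). When the weakest links tie there is no
principled winner, so both offending copies are dropped from the component
and the case is reported as a conflict rather than silently resolved.

## The simulator as study design

`simulate_dataset` emulates an order-level sample: a pure-birth (Yule)
dated species tree conditioned on the number of tips and root age, one
focal gene embedded in conserved single-copy flanking families, JC69
sequence evolution, and an all-vs-all hit table derived from pairwise
identities. Defaults: 8 species, 500 Ma root, 300 codons, 5 flanking genes
per side, substitution rate 0.001/site/Ma (deep orthologs ~55% diverged —
well past trivial similarity, safely below saturation), conversion rate
0.05/lineage/Ma under the positive scenario (an expected homogenisation
every ~20 Ma, i.e. the "frequent conversion" regime in which recurrent
concerted evolution is detectable at all). The duplication is ancestral:
copies start identical at the root split; a configured duplication age
below the root is clamped to the root, since a post-radiation duplication
would not be shared by all species.

Truth labels: a species counts as *converted* when ≥ 1 conversion event
fell on its terminal branch — i.e. homogenisation after its last
speciation, which is what a within-species clan evidences. Conversion is
whole-gene and directional (copy-1 overwrites copy-2); direction does not
affect the monophyly signal and keeps labels simple.

What the simulator does **not** model — and hence what passing tests do not
show about real data: partial conversion tracts, genomic rearrangement or
flank turnover (synteny is perfectly conserved, so synteny recall on real
genomes will be lower), indels and alignment error (sequences are gap-free
and pre-aligned by construction), rate variation across sites and lineages,
horizontal transfer, and gene loss. The hit-table E-values/bitscores are
synthetic identity-derived stand-ins with a reporting cutoff at 40%
identity, mimicking a search tool's score threshold.

## Species selection

The representative filter keeps one strain per species (lexicographically
first strain identifier — an arbitrary but reproducible rule), samples
exactly two species from any genus with more than five (seeded, without
replacement, genera visited in sorted order), then drops orders left with
fewer than six species. The order of rules matters and is fixed; the
operation is idempotent and byte-reproducible for a fixed seed.

## Nei–Gojobori counting

Synonymous site counts per codon are the fraction of the three possible
point mutations at each position that preserve the amino acid; mutations
creating a stop codon count as non-synonymous, and S is averaged over the
two sequences. Differences between codons are classified by averaging over
all minimal substitution paths, excluding paths through stop codons unless
every path is (then all are used). Inputs must be in-frame, gapless and
stop-free; violations raise. S + N equals the sequence length by
construction.

## Reference catalogue

`ceseek/data/tables_1_2.tsv` transcribes the published catalogue of 26
prokaryotic genes under long-lasting recurrent concerted evolution (19
bacterial, 7 archaeal) with species counts, minimum durations and complex
annotations. Three ammonia-oxidation genes without a characterised complex
(amoD, amoE, haoB) carry the shared `pathway_group` label "ammonia
oxidation", as do their operon neighbours, so that "same complex and/or
pathway" counting reflects pathway-level co-membership; the archaeal
histone row's complex is "Archaeal histone" and glnB's is "GlnB". The
summary median uses the midpoint convention for even row counts. The mean
over the table (1009.1 Ma) reflects the rounded per-gene durations as
printed and is reported as such.

## Problem sizes and determinism

Simulation studies in the test suite and acceptance script use 8-species,
300-codon datasets with 500 bootstrap replicates, three replicate datasets
per scenario — sizes chosen so the full study re-runs in seconds while
every stage (clustering, bootstrap, synteny, calling) operates above its
decision thresholds. All stochastic steps draw from explicit seeds;
per-family bootstrap seeds are derived from the run seed and the family
identifier, so results are independent of family processing order.
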