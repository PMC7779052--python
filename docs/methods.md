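# Methods

This note documents the models, rules and numerical choices behind
`pangene-forge`, and what the synthetic benchmark does and does not show.

## Pangene construction

A species with `G` assemblies carries each gene in up to one copy per
assembly.  Within-species clusters of homologous sequences are typed by a
strict precedence: *singleton* (one member), *genotype-specific* (all
members from one assembly), *multi-copy* (some assembly holds ≥ 2 members),
else *single-copy*.

**Consensus.**  Over a one-row-per-assembly alignment, each column
contributes the modal non-gap residue; a column where gaps strictly
outnumber residues is dropped (a tie keeps the column).  A modal tie among
residues is broken by assembly annotation quality: BUSCO complete
descending, then fragmented descending, then missing ascending, then
assembly id — the residue of the best-ranked assembly holding a tied
residue wins.  Consequences worth knowing: the consensus never contains a
gap, is never longer than the alignment, and is invariant to row order
(only the ranking, not the order, breaks ties).  An alignment whose every
column is gap-dominated raises a "degenerate consensus" error rather than
emitting an empty sequence.

**Distances.**  Pairwise distances use the observed proportion of differing
residues `p` over mutually ungapped columns, corrected as
`d = −b ln(1 − p/b)` with `b = 19/20`, the 20-state generalisation of the
Jukes–Cantor model.  `X` is treated as mismatching everything, itself
included — conservative and deterministic.  Pairs with `p ≥ b`, or with no
comparable columns at all, are reported at a finite saturation cap of 10.0
rather than infinity, so that the summed-distance argmin used for
representative selection stays well defined; because the correction is
strictly monotone in `p`, argmin decisions are insensitive to the exact
constant whenever the compared pairs share their comparable-column sets.

**Representative selection.**  In a multi-copy cluster, each multi-member
assembly keeps the candidate whose summed distance to all members of the
*other* assemblies is smallest; genotype-specific clusters keep the member
with the smallest mean distance to the rest, verbatim (a one-row consensus
would be the sequence itself, so no consensus step is run).  All ties break
to the lexicographically smallest sequence id.

**Singleton rescue.**  A singleton survives only with at least one hit in
each of ≥ 2 species other than its own; hit multiplicity within one species
is irrelevant.  Note the structural consequence: in a two-species dataset no
singleton can ever be rescued.

**Nomenclature and compartments.**  Pangenes are numbered densely from
`000001` in cluster-id order, giving reproducible ids run-to-run.  A pangene
is *core* iff every assembly of the species contributes a `rep` member,
else *dispensable*; for a single-assembly species everything is vacuously
core.

## Alignment

The contract is "aligned rows in, consensus out": externally produced
alignments (e.g. MAFFT output as aligned FASTA) are the production path.
The bundled fallback is a progressive profile–profile Needleman–Wunsch
(Gotoh affine gaps, BLOSUM62, gap open −11 / extend −1, guide order = input
order, profile columns scored by mean pairwise substitution score with −4
for gap-vs-residue).  It is adequate for the closely related sequences
inside within-species clusters and keeps the test suite hermetic; it is not
a general aligner.

## Gene families

The similarity graph weights each undirected pair by the mean over available
directions of `min(−log10 E, 200)` with E-values floored at 1e−200 (the
classic TribeMCL weighting); self-hits are dropped.  Markov clustering adds
self-loops at each node's maximum incident edge weight (1.0 for isolated
nodes), column-normalises, and alternates expansion (matrix square) with
inflation (entrywise power + renormalisation), pruning entries below 1e−8,
until the largest entry change is below 1e−6 (cap 200 iterations; a
non-converged state is interpreted as-is with a warning).  Clusters are the
connected components of the thresholded limit matrix; every node lands in
exactly one family.  The four stringency levels map to inflations 1.2, 2, 3
and 5.  Higher inflation empirically never merges clusters on our fuzz sets,
but strict nesting of level k+1 inside level k is *not* guaranteed by the
algorithm and is treated only as a trend.

Family ids are `GP` + six digits, assigned per level by decreasing size and
then smallest member — purely presentational but reproducible.

**Naming.**  Release-to-release transfer restricts each new family to ids of
species shared between releases and transfers the name of the old family
holding the largest share iff that share is ≥ 51% (a tie for the largest
share is ambiguous: no transfer).  The denominator is the new family
restricted to shared ids — of the defensible conventions this is the one
that makes the rule independent of species added in the new release.
Auto-naming then considers only InterPro signatures of entry type *family*
that are specific (carried by no sequence of any other family at that
level) and cover ≥ 51% of members; the highest-coverage signature wins,
ties to the smallest signature accession.

**Domain queries.**  `AND`/`OR`/`NOT` are set intersection/union/complement
over carrier sets; `NOT` complements within the annotated universe, and
`ONLY(S…)` selects sequences whose full, non-empty signature set is a
subset of the listed signatures — a sequence with no annotations never
matches `ONLY`.

## Homology

RBH takes the best subject per query by (bitscore ↓, E-value ↑, subject id)
and keeps mutually best pairs.  Tree-based homology labels each internal
node by the species-overlap rule — duplication iff ≥ 2 child subtrees share
a species, generalised over all child pairs for multifurcations — which
deliberately replaces reconciliation-against-a-species-tree scoring; it
needs no species tree and is exact on the synthetic benchmark, but on real
data it over-calls duplications under incomplete lineage sorting or gene
loss.  Outputs record `source=tree,method=species_overlap` so downstream
users can tell the provenance.  Unrooted trees are rooted on the edge
minimising the duplication count, ties broken by the most balanced leaf
split and then a deterministic edge index.  Orthologs are cross-species
pairs with a speciation LCA; in-paralogs are same-species pairs whose LCA
subtree contains only that species; all other pairs are unreported.  A toy
neighbour-joining builder over the package's distance matrices keeps the
pipeline self-contained; externally built trees (Newick, support values
ignored) are the production path.

## Synthetic benchmark (synthsim)

Each family starts from a random ancestral protein (default 120 residues);
divergence is substitution-only (per-site rate 0.02 by default, applied once
per species and once more per assembly), so family members stay equal
length and the internal aligner faces no indels.  Each assembly copy is
deleted with probability 0.2 (PAV) and duplicated with probability 0.1, the
duplicate receiving one extra round of divergence at twice the base rate.
BUSCO "complete" scores are drawn uniformly from [85, 100] so the ranking
logic is genuinely exercised.  Hits are synthesized from true family
co-membership with E-value `10^(−1.8·identity)` — tests stay hermetic, and
the FASTA can be exported for real-engine integration runs.

Default sizes (3 species × 3 assemblies × 50 families) were chosen as the
smallest configuration in which all cluster types, both compartments and
both homolog classes occur with comfortable margins; the acceptance script
uses the same configuration.

What passing does **not** show: robustness to indels and misalignment, to
spurious similarity between unrelated families (hits exist only within
families, so cross-species clustering is easier than with real search
output), to fragmented gene models, or to deep paralogy predating
speciation.  Those require real data and external aligners/search engines
through the same file interfaces.

## Determinism

Everything downstream of the inputs is deterministic: sorted iteration
orders, lexicographic tie-breaks, and a seed recorded in the run manifest.
Two runs of `run-all` on identical inputs produce byte-identical manifests
(outputs are content-hashed).  The only randomness in the package is the
simulator's, fully governed by its seed.

## Known limitations

* Jukes–Cantor bit-parity with EMBOSS distmat's exact protein variant is
  unverified; monotonicity makes the selection steps insensitive to the
  choice, but reported distance *values* may differ slightly from distmat.
* The internal aligner and NJ builder are desk-scale fallbacks, not
  replacements for MAFFT/FastTree.
* Within-species clustering by Markov clustering of within-species hits is
  a stand-in for bidirectional-best-hit cluster builders; externally
  produced cluster files are accepted as the alternative input.
* Isoform grouping is id-regex based (`.N`, `-RX`, `_TNN` suffixes); GFF3
  parentage is not consulted.
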