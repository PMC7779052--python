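# pangene-forge

A comparative-pangenomics toolkit for plant (or any multi-assembly)
genomics.  When a species has several sequenced genome assemblies, no single
reference captures its full gene repertoire: genes show presence/absence
variation (PAV) and copy-number differences between genotypes.
`pangene-forge` collapses the redundancy into **pangenes** — one
representative or consensus protein per species-level gene — and then runs
classic comparative genomics on top of them: multi-level gene-family
clustering, family naming from InterPro signatures, and homology prediction
by reciprocal best hits and rooted gene trees.

It is aimed at people building comparative-genomics resources from public
proteomes: the inputs are plain protein FASTA files (one per assembly), a
BUSCO completeness table, and all-vs-all similarity hits in BLAST tabular
(outfmt 6) format from any search engine.

## Method

**Pangene construction.** Within-species sequence clusters are processed by
type:

* *single-copy* (one sequence per genome): align, then per alignment column
  keep the modal amino acid; a modal tie is resolved in favour of the genome
  with the best BUSCO scores (complete ↓, fragmented ↓, missing ↑); columns
  with more gaps than residues are dropped.
* *multi-copy* (some genome contributes ≥ 2 copies): from the
  Jukes–Cantor-corrected distance matrix
  `d = −b ln(1 − p/b)` with `b = 19/20` (protein alphabet), each genome keeps
  the copy with the smallest summed distance to all *other* genomes' members
  (`.rep`); the remaining copies are participants (`.p`); the consensus is
  then built over the representatives.
* *genotype-specific* (paralogs confined to one assembly): keep the member
  with the lowest mean distance to the rest, verbatim.
* *singletons*: kept only with similarity hits in at least two other
  species; otherwise excluded.

Pangenes are named `<species>_pan_p<NNNNNN>` and classified **core** (every
assembly of the species contributes a representative) or **dispensable**.

**Families.** Pangenes (plus single-assembly proteomes) are clustered from
the similarity graph by Markov clustering at inflations 1.2, 2, 3 and 5 —
four stringency levels, higher inflation giving more and smaller families.
Curated names from a previous release transfer when ≥ 51% of the
shared-species members were clustered together before; remaining families
are auto-named from InterPro *family*-type signatures that are specific to
the cluster and cover ≥ 51% of members.  A boolean query engine
(`AND`/`OR`/`NOT`/`ONLY`) searches sequences by signature combinations.

**Homology.** Reciprocal best hits between every assembly pair, plus gene
trees per family: trees are rooted on the edge minimising duplication events
under the species-overlap rule (a node is a duplication iff two child
subtrees share a species); leaf pairs with a speciation LCA and different
species are orthologs, same-species pairs under a single-species subtree are
in-paralogs.

A bundled synthetic-pangenome generator (`synthsim`) plants families,
duplications, PAV and divergence with full ground-truth tables, so the whole
pipeline is testable without downloading anything.

## Worked example

```sh
pangene-forge simulate --out data --seed 42 --n-species 2 \
    --genomes-per-species 3 --n-families 12
# write a config pointing at the generated files
cat > config.yaml <<EOF
busco: data/busco.tsv
hits: data/hits.tsv
fasta:
  spaaa_g1: data/spaaa_g1.faa
  spaaa_g2: data/spaaa_g2.faa
  spaaa_g3: data/spaaa_g3.faa
  spabb_g1: data/spabb_g1.faa
  spabb_g2: data/spabb_g2.faa
  spabb_g3: data/spabb_g3.faa
EOF
pangene-forge run-all --config config.yaml --out run
head -3 run/pangene_stats.tsv
```

prints

```
species_code  n_pangenes  n_sequences  n_singletons_excluded  pct_singletons_excluded  n_core  n_dispensable
spaaa         11          32           1                      3.12                     5       6
spabb         8           24           4                      16.67                    4       4
```

Species `spaaa` kept 11 pangenes out of 32 input sequences; 5 are core
(present in all three assemblies) and 6 dispensable.  One sequence was a
within-species singleton without support in two other species and was
excluded (3.12% of the inputs).  With only two species simulated, `spabb`'s
singletons can never reach two foreign species, hence its higher exclusion
rate — exactly the behaviour the rescue rule implies.  `run/` also contains
`pangene_members.tsv` (who backs each pangene, with `.rep`/`.p` roles and
compartments), `families.tsv` (four stringency levels), `homologs.tsv`
(RBH + tree-based pairs) and a `manifest.json` whose hashes are
byte-identical across reruns.

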