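# Methods

`t6sscan` reimplements, as a tested library and CLI, the comparative-genomics
workflow used to survey type VI secretion systems (T6SS) in bacterial symbiont
genomes: gene-cluster calling, sheath phylotyping, genomic-island genotyping,
fusion-sheath detection, and effector screening. This note records the models,
parameter choices, numerical conventions and known limitations.

## Cluster calling (`cluster_detect`)

A T6SS cluster is called on a contig when a run of core-labeled genes contains
at least `min_core = 4` **distinct** core families out of the 13 structural
genes *tssA*–*tssM*, with adjacent core genes separated by at most
`max_gap = 10` non-core genes. Counting distinct families rather than gene
copies means a tandem array of one family (e.g. an Hcp/*tssD* run in an
auxiliary effector cluster) never satisfies the rule — auxiliary clusters are
deliberately out of scope. Gaps are counted in genes, not base pairs. The
cluster span runs from the first to the last core gene inclusive of intervening
non-core genes; accessory genes within `max_gap` genes beyond the span are
reported separately as "flanking accessory" genes, because cluster expansions
(e.g. the effector-rich region after the *vasH* regulator) sit beyond the
outermost core gene. Strand is ignored: real clusters mix orientations.

Truncation: a cluster is flagged truncated on a side when fewer than `max_gap`
genes separate it from the contig end **and** the cluster is incomplete; the
completeness record then attributes missing families to the assembly break
(`truncated_assembly`) rather than genuine absence. Note one asymmetry worth
knowing: raising `max_gap` can *merge* two called clusters into one, so the
cluster **count** is not monotone in `max_gap`; what is monotone is coverage —
every span called at a smaller gap is contained in a span called at a larger
one. `min_core` is monotone on counts.

## Family assignment (`family_assign`)

Families are a closed, config-extensible vocabulary: 13 core genes, ten
accessory/regulatory families (PAAR, FHA, Pkinase, PP2C, DUF4150, tasL, tasR,
vasH, impE, tagF), and the sheath Pfam domains VipA (PF05591) and VipB
(PF05943). Hits normally arrive as HMMER3 `domtblout` text (parsed with
Biopython's SearchIO); lines above the inclusion E-value (default 1e-5) are
dropped. Per gene, the best-scoring core hit wins (score ties break
alphabetically, so assignment is order-independent); all accessory labels are
kept, and a gene may carry a core label *and* accessory labels (PAAR motifs
ride on *tssI* genes). Domain hits on one protein are position-sorted after
resolving overlaps: of any pair overlapping more than 50% of the shorter hit,
the higher-scoring one is kept.

`naive_assign` is a fixture-scale, alignment-based assigner (local alignment
against one consensus protein per family, identity ≥ 0.5 and E ≤ 1e-5). It is
quadratic in genes × families and is *not* a profile search; it exists so the
package can be exercised without external HMM output.

## Alignment engine (`align`)

Needleman–Wunsch and Smith–Waterman with affine gaps, computed by
`Bio.Align.PairwiseAligner` under fixed conventions: BLOSUM62, gap open 11,
gap extend 1 (a gap of length k costs open + (k−1)·extend), deterministic
traceback. Bit scores use the Karlin–Altschul transform with the standard
gapped BLOSUM62 constants λ = 0.267, K = 0.041; E-values use the BLAST formula
E = m·n·2^(−bits) with n the total database residues. Identity defaults to the
alignment-columns convention (gap columns count in the denominator); a
shorter-sequence convention and a positives-based "similarity" fraction are
available because published screening thresholds are sometimes quoted as
similarity rather than identity. Correctness is checked in the test suite
against an independent hand-written Gotoh dynamic program.

One measured bias informs a convention elsewhere: aligning two distantly
related sequences of equal length, the optimizer buys extra matches with gaps
and inflates identity (≈ +3 points at ~26% identity on a 160-residue domain).
Domain-instance comparisons (below) therefore use stiffer gap penalties.

## Sheath phylotyping (`phylotype`)

Each cluster's sheath record concatenates TssB then TssC. When several *tssC*
copies exist (a standard copy next to the long fusion protein, or a duplicated
copy), the copy closest in length to the 506-aa reference TssC is used and the
choice logged. Distances are d = 1 − identity of the pairwise global alignment
of concatenated sheaths — a deliberate departure from an MSA + maximum-
likelihood tree: pairwise identity distances plus neighbor joining are
deterministic, dependency-light, and sufficient for clade placement at this
scale. NJ comes from scikit-bio and is exact on additive matrices (verified to
1e-15 in the tests; the guarantee asserted is 1e-9). The tree builder is a
plain callable, so an external ML tool can be substituted without touching the
rest of the pipeline.

Subtype (1, 2, 3, 4a, 4b, 5) is assigned by the nearest labeled reference
sheath, ties broken by reference id; a nearest distance above the cutoff
(default 0.7) leaves the query unclassified. Nearest-reference placement is
not identical to clade membership for deep queries — with a sparse reference
set the two can disagree; the cutoff is the guard. Bootstrap support (column
resampling of the pairwise alignments, 100 seeded replicates) is available but
off by default: resampling pairwise alignments approximates, but is not, MSA
column bootstrapping.

## Island genotyping (`island_genotype`)

The island is delimited by two flanking markers located by product token:
*manA* (mannose-6-phosphate isomerase) and tRNA-Gly — tokens, not coordinates,
because draft assemblies reorder contigs. Both flanks on one contig give a
resolved region; flanks on two contigs are accepted only when the region is
split by a single assembly break (each flank's island-facing side, strand-
aware, runs to its contig end), mirroring the practice of concatenating
one-break regions; anything else is excluded. Island length is flank-inclusive
(first base of *manA* through the last base of tRNA-Gly).

Island proteins are grouped into homolog families by greedy single-linkage on
local-alignment identity ≥ 0.7 with mutual coverage ≥ 0.8 (RNA genes group by
product token). Families matched by one protein are merged, so the linkage is
genuinely single; a length-ratio and shared-4-mer prefilter skips hopeless
pairs for speed without affecting results at these thresholds. This replaces a
pangenome workflow's BLAST + MCL clustering with a dependency-free equivalent;
the thresholds are config values.

Genomes are clustered on the binary genome × family matrix with average-
linkage agglomeration on Jaccard distances; k defaults to the silhouette
maximum over k ∈ 2…8 (ties to smaller k) and is overridable — the original
analysis fixed no k but read five genotypes from the dendrogram. Genotype
indices are ordered by cluster size so they are stable under row permutation
up to relabeling. Archetypes are rule-based per genotype: an island containing
a complete (13/13) cluster ⇒ `complete_T6SS2_plus_genes`; any cluster ⇒
`incomplete_T6SS2_plus_genes`; more than `min_genes = 3` non-flank genes
without a cluster ⇒ `no_T6SS2_with_genes`; else `near_empty`. Mixed
genotypes take the majority archetype and are flagged.

## Sheath architecture and effector screen (`protein_architecture`)

Per-protein architecture is a pure function of the ordered, overlap-resolved
domain string: ≥2 VipA plus ≥1 VipB is the TssC_L fusion signature
(TssC_L is a ~1,684-aa protein carrying two VipA domains and one VipB domain,
an apparent TssB–TssC fusion found in roseobacter clusters); VipA-only is
TssB-like; VipB-only is TssC-like; one VipA plus one VipB is *not* the fusion
signature and is flagged "other" for review. Cluster repertoires: any fusion
protein ⇒ `fusion`; ≥2 TssC-like with no fusion ⇒ `duplication`, with the
pairwise TssC identity reported (the report states the identity and draws no
evolutionary conclusion from it); one TssB-like plus one TssC-like ⇒
`standard`.

The fused-domain identity report excises each domain instance by its hit
envelope coordinates and globally aligns it against the corresponding
standalone domain (fused VipA vs TssB's VipA; fused VipB vs TssC's VipB).
These comparisons use gap open 30 / extend 4: compact domain instances align
essentially end-to-end, and the stiffer penalties avoid the identity inflation
described under the alignment engine.

Effector prediction is an all-vs-all local-alignment screen against a
reference effector FASTA. Hits must pass **both** thresholds, inclusive:
identity ≥ 30% and E ≤ 1e-6 (a `use_similarity` switch counts positive
substitutions instead, for thresholds quoted as similarity). One best hit per
query–subject pair, sorted by E-value then bit score. No heuristic seeding is
used; the screen is exact at the cost of speed, which is acceptable at the
query scales of this pipeline (cluster and island proteins).

## Species assignment (`pipeline.assign_species`)

ANI computation is out of scope; a FastANI-style table is consumed. A query
joins the species of its maximal-ANI labeled reference when that ANI is ≥ 95%,
otherwise it is unassigned; pairs at ANI 100 are flagged probable clones.
Tables asymmetric beyond 0.5 ANI points are rejected.

## Synthetic panel (`synth_data`)

The generator emulates the surveyed genome panel and defines the study
conditions for every test:

- **34 vibrio-like genomes** with a chromosome-1 T6SS of 11/13 cores (missing
  *tssD* and *tssI*, whose products are typically encoded elsewhere) plus
  PP2C/Pkinase/FHA accessories, and a chromosome-2 island between *manA* and
  tRNA-Gly realized in five genotype archetypes apportioned by largest
  remainder from the proportions 52.9 / 2.9 / 11.8 / 11.7 / 20.6% (the
  published 23.5% middle class split into two archetypes), giving counts
  (18, 1, 4, 4, 7). Archetype 1 carries a complete 13/13 island cluster with
  DUF4150/tasL/tasR/FHA/Pkinase accessories, a post-cluster *vasH* and an
  effector homolog; archetype 2 a genuinely incomplete (tssA–F) cluster;
  archetypes 3/4 distinct non-T6SS gene blocks; archetype 5 is near-empty.
  Island sizes are drawn per archetype within the surveyed 11.2–106.2 kbp
  range by padding one insertion-site spacer.
- **Draft fragmentation**: with probability 0.15 per genome the chromosome-1
  cluster is split across a contig break into two ≥4-core fragments, the
  ground truth recording the truncation sides.
- **Roseobacter-like genomes** (5 fusion + 4 duplication) with a 12/13-core
  cluster (missing *tssJ*) and PAAR/FHA/impE accessories, carrying either a
  1,684-aa TssC_L (fused domains planted at identities 86.21 / 26.32 / 30.94%
  to the cluster's own TssB VipA and TssC VipB) or a second 506-aa *tssC* at
  35.5% identity (inside the reported 34–37% band). TssC_L is annotated and
  hit-labeled as *tssC*, as in real annotations; its architecture is carried
  by the domain hits.
- **Decoys**: random-composition backbone genes flank every cluster (≥ the gap
  window on interior sides, so truncation flags are unambiguous), plus a few
  hit-table lines above the inclusion E-value that the loader must drop.

All protein sequences are substitution-only mutants of a bundled synthetic
consensus panel (random sequences of realistic lengths per family, generated
from a fixed internal seed — they are not real consensus sequences).
`mutate_sequence` plants an *exact* number of substitutions, so every target
identity is recoverable; sheaths derive from per-subtype bases (mutated at
0.85 within the panel), family genes from family bases (at 0.90). Subtype
bases are mutually unrelated, which exaggerates between-subtype divergence
relative to real sheath families. What passing tests therefore demonstrate is
recovery of planted structure under substitution-only divergence with exact
annotations; they do not demonstrate robustness to indels, annotation errors,
HMM scoring noise, mobile elements inside clusters, or compositional bias —
all present in real data. The generator's files (GFF3 + FASTA + GenBank twin,
domtblout, reference sheaths, ANI table, truth JSON) are byte-deterministic
given the config seed; all randomness flows from that one seed.

Problem sizes used throughout (34 + 9 genomes, ~80–120 genes per genome,
50 NJ matrices of 4–8 taxa, 120 subtype trials, 100 alignment-oracle pairs,
50 effector decoys) were chosen as the smallest panels that exercise every
rule and imbalance of interest while keeping the whole suite quick on a
single CPU.

## Numerical and tie-break conventions

- Coordinates: 0-based half-open internally; 1-based inclusive in all
  serialized output.
- Genes with equal start sort by end then gene id; core-family score ties
  break alphabetically; NJ tie-breaks are delegated to scikit-bio's
  deterministic implementation; subtype distance ties break by reference id;
  silhouette ties in k-selection go to the smaller k.
- Zero-column alignments have *undefined* identity (a distinct error), not 0.
- Empty contigs, <3-taxon trees (degenerate single-edge tree with a warning),
  all-identical presence rows (single genotype with a warning) are handled,
  not errors.

## Known limitations

- Pairwise-identity NJ is not an ML phylogeny; branch lengths are identity
  distances, not substitutions per site, and deep placements should not be
  over-read.
- Nearest-reference subtyping depends on reference coverage of each subtype.
- The effector screen is exact but O(queries × database); genome-proteome ×
  large-database screens should use a seeded search tool upstream and feed the
  results in.
- `extract_island` trusts product annotations to find flanks; a missing or
  renamed *manA* annotation makes the island unresolved.
- Pseudo/partial CDS are retained and flagged, never silently dropped; their
  treatment in the original annotations is unknown.
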