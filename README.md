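# t6sscan

Survey **type VI secretion system (T6SS) gene clusters** in annotated
bacterial genomes. The package reimplements, as a reusable and tested
pipeline, the comparative-genomics workflow used to characterize T6SSs in
squid-symbiont genomes (*Vibrio fischeri* light-organ symbionts and
roseobacter accessory-nidamental-gland symbionts), and ships a synthetic-data
generator that plants every structure of interest with machine-readable
ground truth, so the whole pipeline is testable without downloading genomes.

It is aimed at comparative genomicists who have Prokka-style annotations (or
GenBank files) plus HMMER family hits and want reproducible, scriptable
answers to: *which genomes carry a T6SS, of which subtype, how complete, in
which genomic context, with which sheath architecture, and with which
candidate effectors?*

## What it computes

- **Cluster calling** (`cluster_detect`): a cluster is a run of core-gene
  hits with at least 4 of the 13 distinct core families *tssA*–*tssM*, any
  two adjacent core genes separated by ≤ 10 non-core genes. Completeness
  (13/13), missing families, accessory content and contig-edge truncation are
  reported per cluster.
- **Sheath phylotyping** (`phylotype`): concatenated TssB+TssC (sheath
  subunit) sequences, identity distances d = 1 − identity from global
  alignment, a neighbor-joining tree (exact on additive matrices), and
  subtype assignment (1, 2, 3, 4a, 4b, 5) by nearest labeled reference with
  an unclassified cutoff.
- **Island genotyping** (`island_genotype`): extraction of the genomic
  island between *manA* and tRNA-Gly (tolerating one assembly break), a
  binary genome × homolog-family presence matrix (greedy single-linkage at
  ≥ 70% identity / ≥ 80% mutual coverage), average-linkage Jaccard
  clustering into genotypes (k by silhouette), and rule-based archetypes:
  complete T6SS2 + genes / incomplete + genes / genes without T6SS2 /
  near-empty.
- **Sheath architecture** (`protein_architecture`): per-protein VipA/VipB
  domain strings; the two-VipA + one-VipB signature calls the long fusion
  sheath protein **TssC_L**, with fused-domain identities reported against
  the cluster's own TssB/TssC; duplicated-*tssC* repertoires are classified
  with their pairwise identity.
- **Effector screen** (`protein_architecture.search_effectors`): local
  alignment against a reference effector FASTA, hits kept at identity ≥ 30%
  and E ≤ 10⁻⁶ (both inclusive).
- **Species assignment** (`pipeline.assign_species`): the ≥ 95% ANI rule on
  a supplied FastANI-style table, with ANI-100 clone flagging.
- **Synthetic panels** (`synth_data`): deterministic genome sets (GFF3 +
  FASTA + GenBank + domtblout + truth JSON) with planted clusters, island
  genotypes at the surveyed proportions, draft fragmentation, TssC_L fusion
  and tssC-duplication repertoires, decoys and effector homologs.

See `docs/methods.md` for the model conventions, defaults and limitations.

## Worked example

Generate a small synthetic panel (5 vibrio-like genomes plus the default 5
fusion and 4 duplication roseobacter-like genomes) and run the pipeline end
to end:

```bash
t6sscan synth --out panel --seed 2 --n-genomes 5
t6sscan detect --gff panel/VF01.gff --fna panel/VF01.fna \
               --faa panel/VF01.faa --domtbl panel/hits.domtbl
```

prints one line per called cluster (coordinates are 1-based inclusive):

```
VF01|VF01_chr1|1	VF01_chr1	9283-32650	cores=11(tssA,tssB,tssC,tssE,tssF,tssG,tssH,tssJ,tssK,tssL,tssM)	truncated=none
VF01|VF01_chr2|2	VF01_chr2	12572-39184	cores=13(tssA,tssB,tssC,tssD,tssE,tssF,tssG,tssH,tssI,tssJ,tssK,tssL,tssM)	truncated=none
```

— genome VF01 carries a chromosome-1 cluster with 11 of 13 core genes
(missing *tssD* and *tssI*, the Hcp tube and VgrG spike genes) and a
complete 13/13 cluster inside the chromosome-2 island, exactly as planted.
The full pipeline over the panel directory:

```bash
t6sscan run-all --input-dir panel --out results --seed 2
# 14/14 genomes processed; 19 clusters; reports in results
```

writes `clusters.tsv`, `subtypes.tsv`, `islands.tsv`, `genotypes.tsv`
(genotype index + archetype per genome), `presence_matrix.tsv`,
`architectures.tsv` (standard / fusion / duplication repertoires),
`effectors.tsv` (BLAST outfmt-6-like), `sheath_tree.nwk`, a per-genome
`status.tsv` and a `manifest.json` that echoes every threshold and the seed,
sufficient to reproduce the run bit-identically.

The same operations are available as library calls
(`t6sscan.run_all(RunConfig(...))`, `t6sscan.cluster_detect.scan_contig`,
…) for use in notebooks and workflows.

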