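"""Genomic-island extraction, presence/absence genotyping and archetypes.

The island of interest sits between two flanking marker genes — *manA*
(mannose-6-phosphate isomerase) and tRNA-Gly — on the second chromosome
of the symbiont genomes.  Its gene content varies widely between strains
(11.2-106.2 kbp including flanks), so genomes are genotyped by
hierarchically clustering a binary genome x homolog-family matrix of the
inter-flank gene content, and each genotype cluster is labeled with a
rule-based archetype (complete T6SS2 cluster plus other genes, incomplete
cluster plus genes, genes without T6SS2, or near-empty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from . import align as _align
from .cluster_detect import T6SSCluster
from .genome_io import AnnotatedGenome, Gene

logger = logging.getLogger(__name__)

ARCHETYPES = (
    "complete_T6SS2_plus_genes",
    "incomplete_T6SS2_plus_genes",
    "no_T6SS2_with_genes",
    "near_empty",
)


class IslandError(ValueError):
    pass


@dataclass
class IslandRegion:
    genome_id: str
    flank_a_gene: str | None
    flank_b_gene: str | None
    gene_ids: list[str]  # ordered, flanks included
    length_bp: int
    status: str  # resolved | concatenated_one_break | unresolved
    reason: str = ""


@dataclass
class PresenceMatrix:
    """Binary genome x homolog-family matrix with family exemplars."""

    matrix: pd.DataFrame  # genomes (rows) x families (columns), 0/1
    exemplars: dict[str, str]  # family id -> exemplar sequence (or RNA token)
    members: dict[str, list[tuple[str, str]]]  # family id -> (genome, gene)

    @property
    def prevalence(self) -> pd.Series:
        return self.matrix.mean(axis=0)


@dataclass
class GenotypeAssignment:
    genome_id: str
    genotype_index: int
    archetype: str | None = None
    flagged: bool = False


def _matches_flank(gene: Gene, token: str) -> bool:
    return token.lower() in gene.product.lower()


def extract_island(
    genome: AnnotatedGenome,
    flank_a_product: str = "manA",
    flank_b_product: str = "tRNA-Gly",
) -> IslandRegion:
    """Extract the inter-flank region, tolerating one assembly break.

    Both flanks on one contig gives a resolved region (genes between and
    including the flanks; length from the first base of the leftmost
    flank to the last base of the rightmost, i.e. flank-inclusive).  When
    the flanks sit on two different contigs the region is accepted only
    if it is split by a single assembly break: each flank's island-facing
    side (downstream of flank A, upstream of flank B, strand-aware) must
    run to its contig end, and the two gene runs are concatenated in
    flank order.  Anything else is unresolved and excluded downstream.
    """
    gid = genome.genome_id
    hit_a = hit_b = None
    for contig in genome.contigs:
        for i, gene in enumerate(contig.genes):
            if hit_a is None and _matches_flank(gene, flank_a_product):
                hit_a = (contig, i)
            elif hit_b is None and _matches_flank(gene, flank_b_product):
                hit_b = (contig, i)
    if hit_a is None or hit_b is None:
        missing = flank_a_product if hit_a is None else flank_b_product
        return IslandRegion(gid, None, None, [], 0, "unresolved",
                            reason=f"flank {missing} not found")

    (ca, ia), (cb, ib) = hit_a, hit_b
    ga, gb = ca.genes[ia], cb.genes[ib]
    if ca.contig_id == cb.contig_id:
        lo, hi = sorted((ia, ib))
        members = ca.genes[lo : hi + 1]
        length = members[-1].end - members[0].start
        return IslandRegion(gid, ga.gene_id, gb.gene_id,
                            [g.gene_id for g in members], length, "resolved")

    # Flanks on two contigs: island runs downstream of flank A and
    # upstream of flank B (relative to each flank's strand).
    if ga.strand == "+":
        seg_a = ca.genes[ia:]
        len_a = ca.genes[-1].end - ga.start
    else:
        seg_a = list(reversed(ca.genes[: ia + 1]))
        len_a = ga.end - ca.genes[0].start
    if gb.strand == "+":
        seg_b = cb.genes[: ib + 1]
        len_b = gb.end - cb.genes[0].start
    else:
        seg_b = list(reversed(cb.genes[ib:]))
        len_b = cb.genes[-1].end - gb.start
    return IslandRegion(
        gid, ga.gene_id, gb.gene_id,
        [g.gene_id for g in seg_a] + [g.gene_id for g in seg_b],
        len_a + len_b,
        "concatenated_one_break",
    )


# ---------------------------------------------------------------------------
# Homolog families and the presence matrix


def _kmers(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _homologous(seq_a: str, seq_b: str, identity_threshold: float,
                coverage_threshold: float) -> bool:
    la, lb = len(seq_a), len(seq_b)
    # mutual coverage >= c is impossible below this length ratio
    if min(la, lb) / max(la, lb) < coverage_threshold * 0.6:
        return False
    ka, kb = _kmers(seq_a), _kmers(seq_b)
    if len(ka & kb) / max(1, min(len(ka), len(kb))) < 0.02:
        return False
    aln = _align.local_align(seq_a, seq_b)
    if aln.is_empty:
        return False
    return (
        aln.identity_fraction >= identity_threshold
        and aln.query_coverage >= coverage_threshold
        and aln.subject_coverage >= coverage_threshold
    )


def build_presence_matrix(
    islands: list[IslandRegion],
    genomes: dict[str, AnnotatedGenome],
    identity_threshold: float = 0.7,
    coverage_threshold: float = 0.8,
) -> PresenceMatrix:
    """Cluster island proteins into homolog families; emit binary matrix.

    Families form by greedy single-linkage: a protein joins every family
    in which some member aligns at >= ``identity_threshold`` identity
    with mutual coverage >= ``coverage_threshold`` (families matched by
    one protein are merged, so linkage is genuinely single).  RNA genes
    (no protein product) are grouped by product token.  Every island gene
    lands in exactly one family.
    """
    usable = [isl for isl in islands if isl.status != "unresolved"]
    if len(usable) < 2:
        raise IslandError("need at least 2 resolved islands")

    # families: list of dicts with exemplar seq, member seqs, members
    protein_families: list[dict] = []
    rna_families: dict[str, list[tuple[str, str]]] = {}
    for isl in sorted(usable, key=lambda i: i.genome_id):
        genome = genomes[isl.genome_id]
        index = genome.gene_index()
        for gene_id in isl.gene_ids:
            gene = index[gene_id]
            if gene.feature_kind != "CDS" or not gene.protein_seq:
                token = gene.product or gene.feature_kind
                rna_families.setdefault(token, []).append((isl.genome_id, gene_id))
                continue
            seq = gene.protein_seq
            matched = [
                fam for fam in protein_families
                if any(
                    _homologous(seq, member_seq, identity_threshold, coverage_threshold)
                    for member_seq in fam["seqs"]
                )
            ]
            if not matched:
                protein_families.append(
                    {"exemplar": seq, "seqs": [seq],
                     "members": [(isl.genome_id, gene_id)]}
                )
            else:
                target = matched[0]
                for other in matched[1:]:  # single-linkage merge
                    target["seqs"].extend(other["seqs"])
                    target["members"].extend(other["members"])
                    protein_families.remove(other)
                target["seqs"].append(seq)
                target["members"].append((isl.genome_id, gene_id))

    exemplars: dict[str, str] = {}
    members: dict[str, list[tuple[str, str]]] = {}
    for i, fam in enumerate(protein_families):
        fam_id = f"fam_{i + 1:04d}"
        exemplars[fam_id] = fam["exemplar"]
        members[fam_id] = fam["members"]
    for token in sorted(rna_families):
        fam_id = f"rna:{token}"
        exemplars[fam_id] = token
        members[fam_id] = rna_families[token]

    genome_ids = sorted(isl.genome_id for isl in usable)
    matrix = pd.DataFrame(0, index=genome_ids, columns=sorted(members), dtype=int)
    for fam_id, mem in members.items():
        for genome_id, _ in mem:
            matrix.loc[genome_id, fam_id] = 1
    return PresenceMatrix(matrix, exemplars, members)


def cluster_genotypes(
    pm: PresenceMatrix,
    linkage: str = "average",
    metric: str = "jaccard",
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 8),
) -> list[GenotypeAssignment]:
    """Agglomerative clustering of genome rows into island genotypes.

    ``k="auto"`` picks the cut maximising mean silhouette over
    ``k_range`` (ties to the smaller k).  Genotype indices are assigned
    1..k ordered by cluster size (largest first; ties by first member
    id), so they are stable under row permutation up to relabeling.
    """
    X = pm.matrix.to_numpy(dtype=bool)
    genome_ids = list(pm.matrix.index)
    n = len(genome_ids)
    dist = pdist(X, metric=metric)
    if n < 2 or np.all(dist == 0):
        logger.warning("all island rows identical; single genotype")
        return [GenotypeAssignment(g, 1) for g in genome_ids]
    Z = hierarchy.linkage(dist, method=linkage)
    if k == "auto":
        sq = squareform(dist)
        best = None
        for kk in range(k_range[0], min(k_range[1], n - 1) + 1):
            labels = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            score = silhouette_score(sq, labels, metric="precomputed")
            if best is None or score > best[0] + 1e-12:
                best = (score, kk, labels)
        if best is None:
            labels = np.ones(n, dtype=int)
        else:
            labels = best[2]
    else:
        labels = hierarchy.fcluster(Z, t=int(k), criterion="maxclust")

    groups: dict[int, list[str]] = {}
    for g, lab in zip(genome_ids, labels):
        groups.setdefault(int(lab), []).append(g)
    ordered = sorted(groups.values(), key=lambda mem: (-len(mem), min(mem)))
    assignment = {}
    for idx, mem in enumerate(ordered, start=1):
        for g in mem:
            assignment[g] = idx
    return [GenotypeAssignment(g, assignment[g]) for g in genome_ids]


def _member_archetype(
    island: IslandRegion,
    clusters: list[T6SSCluster],
    min_genes: int,
) -> str:
    island_genes = set(island.gene_ids)
    overlapping = [cl for cl in clusters if island_genes & set(cl.gene_ids)]
    if any(cl.complete for cl in overlapping):
        return "complete_T6SS2_plus_genes"
    if overlapping:
        return "incomplete_T6SS2_plus_genes"
    non_flank = [g for g in island.gene_ids
                 if g not in (island.flank_a_gene, island.flank_b_gene)]
    if len(non_flank) > min_genes:
        return "no_T6SS2_with_genes"
    return "near_empty"


def label_archetype(
    assignments: list[GenotypeAssignment],
    islands: dict[str, IslandRegion],
    clusters_by_genome: dict[str, list[T6SSCluster]],
    min_genes: int = 3,
) -> list[GenotypeAssignment]:
    """Rule-based archetype per genotype cluster.

    A member island containing a complete T6SS cluster maps to
    complete_T6SS2_plus_genes; any (incomplete) cluster to
    incomplete_T6SS2_plus_genes; more than ``min_genes`` non-flank genes
    without a cluster to no_T6SS2_with_genes; otherwise near_empty.  A
    genotype whose members disagree takes the majority archetype and is
    flagged.
    """
    by_genotype: dict[int, list[GenotypeAssignment]] = {}
    for a in assignments:
        by_genotype.setdefault(a.genotype_index, []).append(a)
    for genotype, group in by_genotype.items():
        votes: dict[str, int] = {}
        for a in group:
            arch = _member_archetype(
                islands[a.genome_id], clusters_by_genome.get(a.genome_id, []), min_genes
            )
            votes[arch] = votes.get(arch, 0) + 1
        winner = max(votes.items(), key=lambda kv: (kv[1], -ARCHETYPES.index(kv[0])))[0]
        mixed = len(votes) > 1
        if mixed:
            logger.warning("genotype %d has mixed archetypes %s; majority taken",
                           genotype, votes)
        for a in group:
            a.archetype = winner
            a.flagged = mixed
    return assignments
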