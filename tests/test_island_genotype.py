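"""Island extraction, homolog presence matrix, genotype clustering."""

import numpy as np
import pandas as pd
import pytest

from t6sscan.cluster_detect import T6SSCluster
from t6sscan.genome_io import AnnotatedGenome, Contig, Gene
from t6sscan.island_genotype import (IslandError, PresenceMatrix,
                                     build_presence_matrix, cluster_genotypes,
                                     extract_island, label_archetype)
from t6sscan.synth_data import mutate_sequence, random_protein


def _gene(gid, contig, pos, product="hypothetical", seq="M" * 120,
          kind="CDS", strand="+"):
    length = len(seq) * 3 + 3 if kind == "CDS" else 75
    return Gene(gid, contig, pos, pos + length, strand,
                seq if kind == "CDS" else "", product, kind)


def _island_genome(genome_id="G", n_between=2, split=False):
    rng = np.random.default_rng(4)
    if not split:
        genes = [_gene("up1", "c1", 100)]
        pos = 700
        genes.append(_gene("manA", "c1", pos, "manA mannose-6-phosphate isomerase"))
        pos += 1400
        for i in range(n_between):
            genes.append(_gene(f"mid{i}", "c1", pos, seq=random_protein(rng, 150)))
            pos += 700
        pos += 7000  # insertion-site spacer
        genes.append(_gene("trna", "c1", pos, "tRNA-Gly", kind="tRNA"))
        genes.append(_gene("down1", "c1", pos + 600))
        return AnnotatedGenome(genome_id, [Contig("c1", pos + 2000, genes)])
    # split: manA..break on c1, break..tRNA-Gly on c2
    c1 = [_gene("up1", "c1", 100),
          _gene("manA", "c1", 700, "manA mannose-6-phosphate isomerase"),
          _gene("mid0", "c1", 2200, seq=random_protein(rng, 150))]
    c2 = [_gene("mid1", "c2", 80, seq=random_protein(rng, 150)),
          _gene("trna", "c2", 900, "tRNA-Gly", kind="tRNA"),
          _gene("down1", "c2", 1200)]
    return AnnotatedGenome(genome_id, [Contig("c1", 2800, c1), Contig("c2", 2000, c2)])


def test_resolved_island_flank_inclusive_span():
    genome = _island_genome(n_between=2)
    isl = extract_island(genome)
    assert isl.status == "resolved"
    assert isl.gene_ids == ["manA", "mid0", "mid1", "trna"]
    index = genome.gene_index()
    assert isl.length_bp == index["trna"].end - index["manA"].start


def test_island_split_over_one_break_is_concatenated():
    genome = _island_genome(split=True)
    isl = extract_island(genome)
    assert isl.status == "concatenated_one_break"
    assert isl.gene_ids == ["manA", "mid0", "mid1", "trna"]


def test_missing_flank_is_unresolved():
    genome = _island_genome()
    genome.contigs[0].genes = [g for g in genome.contigs[0].genes
                               if g.gene_id != "manA"]
    isl = extract_island(genome)
    assert isl.status == "unresolved"
    assert "manA" in isl.reason
    assert isl.gene_ids == []


def _panel_islands(n_genomes=6, seed=0):
    """Two genome groups sharing blocks of homolog families."""
    rng = np.random.default_rng(seed)
    bases = {f"fam{i}": random_protein(rng, 200) for i in range(6)}
    genomes, islands = {}, []
    for i in range(n_genomes):
        gid = f"G{i}"
        block = ["fam0", "fam1", "fam2"] if i % 2 == 0 else ["fam3", "fam4", "fam5"]
        genes = [_gene("manA", "c1", 100, "manA mannose-6-phosphate isomerase")]
        pos = 1600
        for fam in block:
            genes.append(_gene(f"{gid}_{fam}", "c1", pos,
                               seq=mutate_sequence(bases[fam], 0.9, rng)))
            pos += 800
        genes.append(_gene("trna", "c1", pos, "tRNA-Gly", kind="tRNA"))
        genome = AnnotatedGenome(gid, [Contig("c1", pos + 500, genes)])
        genomes[gid] = genome
        islands.append(extract_island(genome))
    return genomes, islands


def test_presence_matrix_families_match_planted_blocks():
    genomes, islands = _panel_islands()
    pm = build_presence_matrix(islands, genomes)
    # 6 planted families + shared manA family + shared tRNA token
    assert pm.matrix.shape == (6, 8)
    # every island gene in exactly one family
    total_members = sum(len(m) for m in pm.members.values())
    assert total_members == sum(len(i.gene_ids) for i in islands)
    assert (pm.prevalence > 0).all()


def test_presence_matrix_distant_proteins_split_families():
    rng = np.random.default_rng(1)
    base = random_protein(rng, 200)
    genomes = {}
    islands = []
    for gid, ident in (("A", 1.0), ("B", 0.5)):
        genes = [_gene("manA", "c1", 100, "manA mannose-6-phosphate isomerase"),
                 _gene(f"{gid}_p", "c1", 1600, seq=mutate_sequence(base, ident, rng)),
                 _gene("trna", "c1", 2600, "tRNA-Gly", kind="tRNA")]
        genome = AnnotatedGenome(gid, [Contig("c1", 3400, genes)])
        genomes[gid] = genome
        islands.append(extract_island(genome))
    pm = build_presence_matrix(islands, genomes)
    # proteins at ~50% identity stay in separate families at the 0.7 cutoff
    protein_fams = [f for f in pm.matrix.columns if f.startswith("fam_")]
    assert len(protein_fams) == 3  # manA pair merges; the planted pair splits
    with pytest.raises(IslandError):
        build_presence_matrix(islands[:1], genomes)


def _block_matrix():
    rows = {}
    for i in range(5):
        rows[f"A{i}"] = [1] * 6 + [0] * 6
    for i in range(5):
        rows[f"B{i}"] = [0] * 6 + [1] * 6
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"f{j}" for j in range(12)])
    return PresenceMatrix(df, {}, {})


def test_orthogonal_blocks_recover_k2():
    assignments = cluster_genotypes(_block_matrix())
    labels = {a.genome_id: a.genotype_index for a in assignments}
    assert len(set(labels.values())) == 2
    assert len({labels[f"A{i}"] for i in range(5)}) == 1
    assert len({labels[f"B{i}"] for i in range(5)}) == 1


def test_genotype_assignment_invariant_to_row_permutation():
    pm = _block_matrix()
    a1 = {a.genome_id: a.genotype_index for a in cluster_genotypes(pm)}
    perm = pm.matrix.sample(frac=1.0, random_state=3)
    a2 = {a.genome_id: a.genotype_index
          for a in cluster_genotypes(PresenceMatrix(perm, {}, {}))}
    # identical partition up to relabeling
    partition1 = {}
    for g, lab in a1.items():
        partition1.setdefault(lab, set()).add(g)
    partition2 = {}
    for g, lab in a2.items():
        partition2.setdefault(lab, set()).add(g)
    assert sorted(map(sorted, partition1.values())) == \
        sorted(map(sorted, partition2.values()))


def test_identical_rows_collapse_to_single_genotype():
    df = pd.DataFrame([[1, 0, 1]] * 4, index=list("abcd"), columns=list("xyz"))
    assignments = cluster_genotypes(PresenceMatrix(df, {}, {}))
    assert {a.genotype_index for a in assignments} == {1}


def _mk_island(gid, gene_ids):
    from t6sscan.island_genotype import IslandRegion

    return IslandRegion(gid, gene_ids[0], gene_ids[-1], gene_ids,
                        20_000, "resolved")


def _mk_cluster(gid, gene_ids, n_core):
    from t6sscan.family_assign import CORE_FAMILIES

    return T6SSCluster(f"{gid}|c|1", gid, "c", gene_ids, (0, 1000),
                       frozenset(CORE_FAMILIES[:n_core]))


def test_archetype_rules():
    from t6sscan.island_genotype import GenotypeAssignment

    islands = {
        "G1": _mk_island("G1", ["a", "b", "c", "d", "e", "f", "g"]),
        "G2": _mk_island("G2", ["a2", "b2", "c2", "d2", "e2", "f2"]),
        "G3": _mk_island("G3", [f"x{i}" for i in range(12)]),
        "G4": _mk_island("G4", ["m", "t"]),
    }
    clusters = {
        "G1": [_mk_cluster("G1", ["b", "c", "d"], 13)],   # complete in island
        "G2": [_mk_cluster("G2", ["b2", "c2"], 9)],        # incomplete
    }
    assignments = [GenotypeAssignment("G1", 1), GenotypeAssignment("G2", 2),
                   GenotypeAssignment("G3", 3), GenotypeAssignment("G4", 4)]
    label_archetype(assignments, islands, clusters)
    by_genome = {a.genome_id: a.archetype for a in assignments}
    assert by_genome == {
        "G1": "complete_T6SS2_plus_genes",
        "G2": "incomplete_T6SS2_plus_genes",
        "G3": "no_T6SS2_with_genes",
        "G4": "near_empty",
    }
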