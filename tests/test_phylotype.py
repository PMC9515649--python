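"""Sheath extraction, identity distances, NJ consistency, subtyping."""

import heapq

import numpy as np
import pytest

from t6sscan.cluster_detect import scan_contig
from t6sscan.family_assign import FamilyMap
from t6sscan.genome_io import AnnotatedGenome, Contig, Gene
from t6sscan.phylotype import (DistanceMatrix, PhylotypeError, SheathSequence,
                               SUBTYPES, assign_subtype, distance_matrix,
                               nj_tree, sheath_distance, tree_path_lengths)
from t6sscan.synth_data import mutate_sequence, random_protein, reference_panel
from t6sscan.phylotype import extract_sheath


def random_additive_matrix(n, rng):
    """Path-length matrix of a random edge-weighted binary tree."""
    adj = {"i0": {}}
    for t in ("t0", "t1", "t2"):
        w = rng.uniform(0.1, 1.0)
        adj["i0"][t] = w
        adj.setdefault(t, {})["i0"] = w
    for i in range(3, n):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        w = adj[a][b]
        mid = f"i{i}"
        x = rng.uniform(0.1, 0.9) * w
        del adj[a][b], adj[b][a]
        adj.setdefault(mid, {})[a] = x
        adj[a][mid] = x
        adj[mid][b] = w - x
        adj[b][mid] = w - x
        tip = f"t{i}"
        bl = rng.uniform(0.1, 1.0)
        adj[mid][tip] = bl
        adj.setdefault(tip, {})[mid] = bl
    labels = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i in range(n):
        dist = {labels[i]: 0.0}
        pq = [(0.0, labels[i])]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist.get(u, np.inf):
                continue
            for v, w in adj[u].items():
                if d + w < dist.get(v, np.inf):
                    dist[v] = d + w
                    heapq.heappush(pq, (d + w, v))
        for j in range(n):
            D[i, j] = dist[labels[j]]
    return labels, (D + D.T) / 2


def _cluster_with(proteins):
    """One-contig genome whose genes all sit in a single cluster."""
    genes = []
    core = {}
    pos = 100
    for gid, (family, seq) in proteins.items():
        genes.append(Gene(gid, "c1", pos, pos + max(30, len(seq)) * 3, "+", seq))
        core[gid] = family
        pos += max(30, len(seq)) * 3 + 50
    genome = AnnotatedGenome("G", [Contig("c1", pos + 100, genes)])
    fam_map = FamilyMap(core=core)
    clusters = scan_contig(genome.contigs[0], fam_map, min_core=2, genome_id="G")
    return clusters[0], genome, fam_map


def test_extract_sheath_concatenates_tssB_then_tssC():
    b, c = "B" * 170, "C" * 500
    cluster, genome, fam_map = _cluster_with(
        {"g1": ("tssB", b), "g2": ("tssC", c)})
    sheath = extract_sheath(cluster, genome, fam_map)
    assert sheath.concatenated == b + c
    assert len(sheath.concatenated) == 670


def test_extract_sheath_picks_tssC_copy_nearest_reference_length():
    """With a standard 506-aa TssC and a 1,684-aa TssC_L both labeled
    tssC, the 506-aa copy feeds the tree."""
    cluster, genome, fam_map = _cluster_with({
        "g1": ("tssB", "B" * 170),
        "g2": ("tssC", "C" * 506),
        "g3": ("tssC", "L" * 1684),
    })
    sheath = extract_sheath(cluster, genome, fam_map)
    assert sheath.tssC_seq == "C" * 506


def test_cluster_without_tssB_is_excluded():
    cluster, genome, fam_map = _cluster_with(
        {"g1": ("tssC", "C" * 506), "g2": ("tssK", "K" * 100)})
    assert extract_sheath(cluster, genome, fam_map) is None


def test_distance_matrix_identity_and_symmetry():
    rng = np.random.default_rng(2)
    base_b, base_c = random_protein(rng, 170), random_protein(rng, 506)
    sheaths = [SheathSequence("s0", base_b, base_c)]
    for i in range(1, 6):
        sheaths.append(SheathSequence(
            f"s{i}", mutate_sequence(base_b, 0.8, rng),
            mutate_sequence(base_c, 0.8, rng)))
    D = distance_matrix(sheaths)
    assert np.allclose(D.d, D.d.T)
    assert np.all(np.diag(D.d) == 0)
    # mutants at 80% identity: distance near 0.2 (alignment can only
    # find more matches, so <= 0.2 plus a small alignment slack)
    assert 0.1 <= D.d[0, 1] <= 0.2 + 1e-9


def test_identical_sheaths_have_zero_distance():
    s = SheathSequence("a", "V" * 170, "C" * 506)
    t = SheathSequence("b", "V" * 170, "C" * 506)
    assert sheath_distance(s, t) == 0.0


def test_nj_reproduces_additive_distances_and_all_quartet_topologies():
    """Classical NJ consistency: 50 random additive matrices (4-8 taxa)
    are reproduced exactly; each quartet topology is recovered."""
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = int(rng.integers(4, 9))
        labels, D = random_additive_matrix(n, rng)
        tree = nj_tree(DistanceMatrix(labels, D))
        P = tree_path_lengths(tree, labels)
        assert np.abs(P - D).max() < 1e-9

    # the three 4-taxon topologies from hand-built additive matrices
    def quartet_matrix(pairing):
        # pair distances: within-cherry 2, across 6
        D = np.full((4, 4), 6.0)
        np.fill_diagonal(D, 0.0)
        (a, b), (c, d) = pairing
        D[a, b] = D[b, a] = 2.0
        D[c, d] = D[d, c] = 2.0
        return D

    labels = ["A", "B", "C", "D"]
    for pairing in (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))):
        tree = nj_tree(DistanceMatrix(labels, quartet_matrix(pairing)))
        P = tree_path_lengths(tree, labels)
        assert np.abs(P - quartet_matrix(pairing)).max() < 1e-9
        (a, b), _ = pairing
        # the cherry pair must be closer on the tree than any cross pair
        assert P[a, b] == pytest.approx(2.0)


def test_two_taxon_degenerate_tree():
    tree = nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]])))
    da = tree.find("a").length
    db = tree.find("b").length
    assert da == pytest.approx(0.2) and db == pytest.approx(0.2)


def test_three_taxon_pendant_lengths_closed_form():
    D = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
    P = tree_path_lengths(tree, ["a", "b", "c"])
    assert np.abs(P - D).max() < 1e-9
    # pendant a = (d_ab + d_ac - d_bc) / 2
    assert tree.find("a").length == pytest.approx((0.4 + 0.6 - 0.8) / 2)


def test_newick_round_trip_topology():
    from skbio.tree import TreeNode

    rng = np.random.default_rng(23)
    labels, D = random_additive_matrix(6, rng)
    tree = nj_tree(DistanceMatrix(labels, D))
    reparsed = TreeNode.read([str(tree)])
    assert sorted(t.name for t in reparsed.tips()) == sorted(labels)
    P1 = tree_path_lengths(tree, labels)
    P2 = tree_path_lengths(reparsed, labels)
    assert np.abs(P1 - P2).max() < 1e-6


def _references(rng, n_per_subtype=2):
    panel = reference_panel()
    refs = {}
    for subtype in SUBTYPES:
        for i in range(n_per_subtype):
            b = panel[f"sheath_B_{subtype}"]
            c = panel[f"sheath_C_{subtype}"]
            if i:
                b = mutate_sequence(b, 0.92, rng)
                c = mutate_sequence(c, 0.92, rng)
            refs[f"ref_{subtype}_{i}"] = (SheathSequence(f"ref_{subtype}_{i}", b, c),
                                          subtype)
    return refs


def test_subtype_exact_match_and_cutoff():
    rng = np.random.default_rng(5)
    refs = _references(rng)
    query = SheathSequence("q", refs["ref_3_0"][0].tssB_seq,
                           refs["ref_3_0"][0].tssC_seq)
    a = assign_subtype(query, refs)
    assert a.subtype == "3" and a.distance == 0.0

    far = SheathSequence("far", random_protein(rng, 170), random_protein(rng, 506))
    assert assign_subtype(far, refs).subtype == "unclassified"

    with pytest.raises(PhylotypeError):
        assign_subtype(query, {})


def test_subtype_recovery_at_75_percent_identity():
    """Queries mutated to 75% identity of subtype-1 references are always
    placed in subtype 1 (n = 20, seeded)."""
    rng = np.random.default_rng(6)
    refs = _references(rng)
    panel = reference_panel()
    for _ in range(20):
        q = SheathSequence(
            "q", mutate_sequence(panel["sheath_B_1"], 0.75, rng),
            mutate_sequence(panel["sheath_C_1"], 0.75, rng))
        assert assign_subtype(q, refs).subtype == "1"


def test_subtype_invariant_to_reference_ordering():
    rng = np.random.default_rng(8)
    refs = _references(rng)
    panel = reference_panel()
    q = SheathSequence("q", mutate_sequence(panel["sheath_B_2"], 0.8, rng),
                       mutate_sequence(panel["sheath_C_2"], 0.8, rng))
    a1 = assign_subtype(q, refs)
    shuffled = dict(reversed(list(refs.items())))
    a2 = assign_subtype(q, shuffled)
    assert (a1.subtype, a1.nearest_reference_id) == (a2.subtype, a2.nearest_reference_id)


def test_bootstrap_support_fractions_are_valid():
    """Column-resampling bootstrap (off by default in the pipeline)
    returns per-bipartition support fractions in [0, 1]."""
    from t6sscan.phylotype import bootstrap_support

    rng = np.random.default_rng(13)
    base_b, base_c = random_protein(rng, 80), random_protein(rng, 120)
    other_b, other_c = random_protein(rng, 80), random_protein(rng, 120)
    sheaths = [
        SheathSequence("a1", base_b, base_c),
        SheathSequence("a2", mutate_sequence(base_b, 0.9, rng),
                       mutate_sequence(base_c, 0.9, rng)),
        SheathSequence("b1", other_b, other_c),
        SheathSequence("b2", mutate_sequence(other_b, 0.9, rng),
                       mutate_sequence(other_c, 0.9, rng)),
    ]
    support = bootstrap_support(sheaths, n_replicates=10, seed=3)
    assert all(0.0 <= v <= 1.0 for v in support.values())
    # the two clear pairs form the only informative bipartition; it
    # should recur in every replicate
    assert support.get(frozenset({"b1", "b2"}), 0.0) == 1.0
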