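"""Sheath (TssBC) distance phylogeny and T6SS subtype assignment.

The contractile sheath subunits TssB (small) and TssC (large) are
concatenated per cluster, pairwise distances are taken as one minus
global-alignment identity, and a neighbor-joining tree is built from the
distance matrix.  Subtypes (1, 2, 3, 4a, 4b, 5) are assigned by nearest
labeled reference sheath, with queries beyond a distance cutoff left
unclassified.

Neighbor joining and nearest-reference placement stand in for
maximum-likelihood inference: they are deterministic, exact on additive
distance matrices, and sufficient for clade placement at this scale.  The
tree builder is a pluggable callable so an external ML tool can be
substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

from . import align as _align
from .cluster_detect import T6SSCluster
from .family_assign import FamilyMap
from .genome_io import AnnotatedGenome

logger = logging.getLogger(__name__)

SUBTYPES = ("1", "2", "3", "4a", "4b", "5")
#: Median length of described TssC proteins; used to pick among tssC copies.
TSSC_REFERENCE_LENGTH = 506
DEFAULT_SUBTYPE_CUTOFF = 0.7


class PhylotypeError(ValueError):
    pass


@dataclass
class SheathSequence:
    cluster_id: str
    tssB_seq: str
    tssC_seq: str

    def __post_init__(self):
        if not self.tssB_seq or not self.tssC_seq:
            raise PhylotypeError("both sheath components must be non-empty")

    @property
    def concatenated(self) -> str:
        return self.tssB_seq + self.tssC_seq


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise PhylotypeError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise PhylotypeError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise PhylotypeError("diagonal must be zero")
        self.d = d

    def to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.d, ids=self.labels)


@dataclass
class SubtypeAssignment:
    cluster_id: str
    subtype: str  # one of SUBTYPES or "unclassified"
    nearest_reference_id: str | None
    distance: float


def extract_sheath(
    cluster: T6SSCluster, genome: AnnotatedGenome, family_map: FamilyMap
) -> SheathSequence | None:
    """Concatenated TssB + TssC sequence for one cluster.

    When a cluster carries several tssC copies (e.g. a standard TssC next
    to the long fusion protein TssC_L) the copy closest in length to the
    506-aa reference TssC is used and the choice is logged.  A cluster
    missing either subunit yields no sheath record and is excluded from
    the tree.
    """
    index = genome.gene_index()
    tssB = [index[g] for g in cluster.gene_ids if family_map.core_family(g) == "tssB"]
    tssC = [index[g] for g in cluster.gene_ids if family_map.core_family(g) == "tssC"]
    tssB = [g for g in tssB if g.protein_seq]
    tssC = [g for g in tssC if g.protein_seq]
    if not tssB or not tssC:
        logger.info("cluster %s lacks tssB or tssC; excluded from tree", cluster.cluster_id)
        return None
    b = tssB[0]
    if len(tssB) > 1:
        logger.info("cluster %s has %d tssB copies; first used", cluster.cluster_id, len(tssB))
    c = min(tssC, key=lambda g: (abs(len(g.protein_seq) - TSSC_REFERENCE_LENGTH), g.gene_id))
    if len(tssC) > 1:
        logger.info(
            "cluster %s has %d tssC copies; chose %s (%d aa, closest to %d aa)",
            cluster.cluster_id, len(tssC), c.gene_id, len(c.protein_seq),
            TSSC_REFERENCE_LENGTH,
        )
    return SheathSequence(cluster.cluster_id, b.protein_seq, c.protein_seq)


def sheath_distance(a: SheathSequence, b: SheathSequence) -> float:
    aln = _align.global_align(a.concatenated, b.concatenated,
                              query_id=a.cluster_id, subject_id=b.cluster_id)
    return 1.0 - aln.identity_fraction


def distance_matrix(sheaths: list[SheathSequence]) -> DistanceMatrix:
    """All-pairs identity distance d = 1 - global alignment identity."""
    if len(sheaths) < 2:
        raise PhylotypeError("need at least 2 sheath records")
    n = len(sheaths)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sheath_distance(sheaths[i], sheaths[j])
    return DistanceMatrix([s.cluster_id for s in sheaths], d)


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; exact on additive distance matrices.

    For n < 3 a degenerate single-edge tree is returned with a warning.
    """
    n = len(D.labels)
    if n < 3:
        logger.warning("fewer than 3 taxa; returning degenerate tree")
        if n == 1:
            return TreeNode.read([f"({D.labels[0]}:0.0);"])
        half = D.d[0, 1] / 2
        return TreeNode.read([f"({D.labels[0]}:{half},{D.labels[1]}:{half});"])
    return _skbio_nj(D.to_skbio())


def tree_path_lengths(tree: TreeNode, labels: list[str]) -> np.ndarray:
    """Tip-to-tip path-length matrix in the given label order."""
    dm = tree.tip_tip_distances(endpoints=list(labels))
    order = [list(dm.ids).index(l) for l in labels]
    return dm.data[np.ix_(order, order)]


def assign_subtype(
    query_sheath: SheathSequence,
    references: dict[str, tuple[SheathSequence, str]],
    cutoff: float = DEFAULT_SUBTYPE_CUTOFF,
) -> SubtypeAssignment:
    """Subtype of the nearest labeled reference sheath.

    ``references`` maps reference id -> (sheath, subtype label).  The
    result is invariant to reference ordering (distance ties break on the
    reference id).  A nearest distance above ``cutoff`` leaves the query
    unclassified.
    """
    if not references:
        raise PhylotypeError("empty reference set")
    best = min(
        ((sheath_distance(query_sheath, ref), ref_id, label)
         for ref_id, (ref, label) in references.items()),
        key=lambda t: (t[0], t[1]),
    )
    dist, ref_id, label = best
    if dist > cutoff:
        return SubtypeAssignment(query_sheath.cluster_id, "unclassified", ref_id, dist)
    return SubtypeAssignment(query_sheath.cluster_id, label, ref_id, dist)


def bootstrap_support(
    sheaths: list[SheathSequence],
    n_replicates: int = 100,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Clade support by column resampling of the pairwise alignments.

    Off by default in the pipeline.  Each replicate resamples, with
    replacement, the columns of every pairwise global alignment, rebuilds
    the identity distance matrix and the NJ tree, and counts how often
    each tip bipartition of the replicate trees recurs.  Returns
    support fractions keyed by frozenset of tip names (one side of the
    bipartition, the side not containing the first label).
    """
    rng = np.random.default_rng(seed)
    n = len(sheaths)
    labels = [s.cluster_id for s in sheaths]
    pair_cols: dict[tuple[int, int], tuple[str, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = _align.global_align(sheaths[i].concatenated, sheaths[j].concatenated)
            pair_cols[(i, j)] = (aln.aligned_query, aln.aligned_subject)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        d = np.zeros((n, n))
        for (i, j), (qa, sa) in pair_cols.items():
            cols = rng.integers(0, len(qa), size=len(qa))
            matches = sum(1 for c in cols if qa[c] == sa[c] and qa[c] != "-")
            d[i, j] = d[j, i] = 1.0 - matches / len(cols)
        tree = nj_tree(DistanceMatrix(labels, d))
        for clade in _bipartitions(tree, labels):
            counts[clade] = counts.get(clade, 0) + 1
    return {k: v / n_replicates for k, v in counts.items()}


def _bipartitions(tree: TreeNode, labels: list[str]):
    all_tips = frozenset(labels)
    out = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if labels[0] in side:
            side = all_tips - side
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out
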