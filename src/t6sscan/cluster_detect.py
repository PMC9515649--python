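"""T6SS gene-cluster calling by core-gene count and spacing.

A cluster is called on a contig when a run of core-family genes contains
at least ``min_core`` (default 4) DISTINCT core families out of the 13
*tssA*-*tssM*, with adjacent core genes separated by no more than
``max_gap`` (default 10) non-core genes.  Distinct families, not gene
copies, satisfy the count, so a tandem array of one family (e.g. an Hcp
run) never triggers a call; this is what keeps auxiliary effector
clusters out of the results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .family_assign import CORE_FAMILIES, FamilyMap
from .genome_io import AnnotatedGenome, Contig

logger = logging.getLogger(__name__)

TRUNCATION_STATES = ("none", "left", "right", "both")


@dataclass
class T6SSCluster:
    cluster_id: str
    genome_id: str
    contig_id: str
    gene_ids: list[str]
    span: tuple[int, int]  # bp, 0-based half-open
    core_present: frozenset[str]
    accessory: list[tuple[str, str]] = field(default_factory=list)
    flanking_accessory: list[tuple[str, str]] = field(default_factory=list)
    truncated: str = "none"
    label: str | None = None

    @property
    def core_count(self) -> int:
        return len(self.core_present)

    @property
    def complete(self) -> bool:
        return self.core_count == len(CORE_FAMILIES)


@dataclass
class CompletenessRecord:
    cluster_id: str
    present: tuple[str, ...]
    missing: tuple[str, ...]
    complete: bool
    accessory_by_family: dict[str, list[str]]
    cause: str | None  # truncated_assembly | genuinely_absent | None when complete


def scan_contig(
    contig: Contig,
    family_map: FamilyMap,
    min_core: int = 4,
    max_gap: int = 10,
    genome_id: str = "",
    start_ordinal: int = 1,
) -> list[T6SSCluster]:
    """Call clusters on one contig.

    Core-labeled genes are grouped into maximal runs in which adjacent
    core genes have <= ``max_gap`` intervening non-core genes; a run with
    >= ``min_core`` distinct core families becomes a cluster spanning the
    first through last core gene (intervening non-core genes included).
    Accessory-labeled genes within ``max_gap`` genes beyond the span are
    reported separately as flanking accessory genes.  A cluster is flagged
    truncated on a side where fewer than ``max_gap`` genes separate it
    from the contig end and the cluster is incomplete.
    """
    genes = contig.genes
    core_idx = [i for i, g in enumerate(genes) if family_map.is_core(g.gene_id)]
    clusters: list[T6SSCluster] = []
    ordinal = start_ordinal

    runs: list[list[int]] = []
    for idx in core_idx:
        if runs and idx - runs[-1][-1] - 1 <= max_gap:
            runs[-1].append(idx)
        else:
            runs.append([idx])

    for run in runs:
        families = frozenset(
            family_map.core_family(genes[i].gene_id) for i in run
        )
        if len(families) < min_core:
            continue
        first, last = run[0], run[-1]
        members = genes[first : last + 1]
        accessory = [
            (g.gene_id, fam)
            for g in members
            for fam in family_map.accessory_families(g.gene_id)
        ]
        flank_lo = genes[max(0, first - max_gap) : first]
        flank_hi = genes[last + 1 : last + 1 + max_gap]
        flanking = [
            (g.gene_id, fam)
            for g in (*flank_lo, *flank_hi)
            for fam in family_map.accessory_families(g.gene_id)
        ]
        incomplete = len(families) < len(CORE_FAMILIES)
        near_left = first < max_gap
        near_right = (len(genes) - 1 - last) < max_gap
        if incomplete and near_left and near_right:
            truncated = "both"
        elif incomplete and near_left:
            truncated = "left"
        elif incomplete and near_right:
            truncated = "right"
        else:
            truncated = "none"
        clusters.append(
            T6SSCluster(
                cluster_id=f"{genome_id or 'genome'}|{contig.contig_id}|{ordinal}",
                genome_id=genome_id,
                contig_id=contig.contig_id,
                gene_ids=[g.gene_id for g in members],
                span=(members[0].start, members[-1].end),
                core_present=families,
                accessory=accessory,
                flanking_accessory=flanking,
                truncated=truncated,
            )
        )
        ordinal += 1
    return clusters


def scan_genome(genome: AnnotatedGenome, family_map: FamilyMap,
                min_core: int = 4, max_gap: int = 10) -> list[T6SSCluster]:
    clusters = []
    for contig in genome.contigs:
        clusters.extend(
            scan_contig(contig, family_map, min_core=min_core, max_gap=max_gap,
                        genome_id=genome.genome_id, start_ordinal=len(clusters) + 1)
        )
    return clusters


def classify_completeness(cluster: T6SSCluster) -> CompletenessRecord:
    """Present/absent core inventory and the likely cause of incompleteness.

    Incompleteness at a contig edge is attributed to the assembly break
    (draft genomes routinely cut clusters at contig boundaries); an
    incomplete cluster in the contig interior has its missing families
    flagged genuinely absent.
    """
    present = tuple(f for f in CORE_FAMILIES if f in cluster.core_present)
    missing = tuple(f for f in CORE_FAMILIES if f not in cluster.core_present)
    acc: dict[str, list[str]] = {}
    for gene_id, family in cluster.accessory:
        acc.setdefault(family, []).append(gene_id)
    if cluster.complete:
        cause = None
    elif cluster.truncated != "none":
        cause = "truncated_assembly"
    else:
        cause = "genuinely_absent"
    return CompletenessRecord(
        cluster_id=cluster.cluster_id,
        present=present,
        missing=missing,
        complete=cluster.complete,
        accessory_by_family=acc,
        cause=cause,
    )


def label_known_systems(
    clusters: list[T6SSCluster],
    genome: AnnotatedGenome,
    replicon_map: dict[str, str] | None = None,
    subtype_labels: dict[str, str] | None = None,
    reference_system_map: dict[str, str] | None = None,
) -> list[T6SSCluster]:
    """Attach T6SS1/T6SS2 labels by replicon or by subtype placement.

    ``replicon_map`` maps contig_id to a replicon token ("chromosome1" /
    "chromosome2"); ``subtype_labels`` maps cluster_id to the system label
    implied by its nearest phylogenetic reference (see
    ``reference_system_map`` in the phylotype stage).  Conflicting
    evidence demotes the cluster to unlabeled with a warning; several
    clusters resolving to the same label get ordinal suffixes.
    """
    replicon_to_label = {"chromosome1": "T6SS1", "chromosome2": "T6SS2"}
    labels: list[str | None] = []
    for cl in clusters:
        by_replicon = None
        if replicon_map and cl.contig_id in replicon_map:
            by_replicon = replicon_to_label.get(replicon_map[cl.contig_id])
        by_subtype = subtype_labels.get(cl.cluster_id) if subtype_labels else None
        if by_replicon and by_subtype and by_replicon != by_subtype:
            logger.warning(
                "conflicting system labels for %s (%s vs %s); left unlabeled",
                cl.cluster_id, by_replicon, by_subtype,
            )
            labels.append(None)
        else:
            labels.append(by_replicon or by_subtype)

    counts: dict[str, int] = {}
    for lab in labels:
        if lab:
            counts[lab] = counts.get(lab, 0) + 1
    seen: dict[str, int] = {}
    for cl, lab in zip(clusters, labels):
        if lab is None:
            cl.label = "unlabeled"
        elif counts[lab] > 1:
            seen[lab] = seen.get(lab, 0) + 1
            cl.label = f"{lab}.{seen[lab]}"
        else:
            cl.label = lab
    return clusters
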