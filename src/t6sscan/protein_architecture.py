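"""Sheath-protein domain architecture and effector similarity screening.

Standard sheaths pair a TssB protein (one VipA domain) with a TssC
protein (one VipB domain).  Some roseobacter clusters instead carry
TssC_L, a long (~1,684 aa) protein with two VipA domains and one VipB
domain — an apparent TssB-TssC fusion — or a second *tssC* copy.  This
module calls per-protein architectures from resolved VipA/VipB domain
hits, reports fused-domain identities against the standalone subunits in
the same cluster, classifies each cluster's sheath repertoire, and runs
the threshold-based effector screen (hits kept when identity >= 30% and
E-value <= 1e-6, both inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import align as _align
from .cluster_detect import T6SSCluster
from .family_assign import FamilyHit


logger = logging.getLogger(__name__)

ARCHITECTURE_CALLS = ("TssB_like", "TssC_like", "TssC_L_fusion", "other")
REPERTOIRE_PATTERNS = ("standard", "fusion", "duplication", "other")

DEFAULT_MIN_IDENTITY = 0.30
DEFAULT_MAX_EVALUE = 1e-6

#: Gap penalties for end-to-end comparisons of envelope-excised domain
#: instances.  Compact sheath domains align essentially without gaps;
#: with light penalties the aligner invents gapped correspondences
#: between distantly related instances and inflates identity estimates.
DOMAIN_GAP_OPEN = 30
DOMAIN_GAP_EXTEND = 4


class ArchitectureError(ValueError):
    pass


@dataclass
class ArchitectureCall:
    protein_id: str
    domain_string: tuple[str, ...]  # ordered VipA/VipB tokens
    call: str
    domain_hits: list[FamilyHit] = field(default_factory=list)
    flagged: bool = False  # rule-boundary cases (e.g. one VipA + one VipB)


@dataclass
class DomainComparison:
    domain_family: str
    instance_index: int  # 1-based position among same-family domains
    partner_protein: str
    identity_fraction: float
    evalue: float


@dataclass
class RepertoireCall:
    cluster_id: str
    pattern: str
    tssB_ids: list[str]
    tssC_ids: list[str]
    tssC_L_ids: list[str]
    tssC_pairwise_identity: float | None = None


@dataclass(frozen=True)
class EffectorHit:
    query_id: str
    db_protein_id: str
    identity_fraction: float
    evalue: float
    bit_score: float
    coverage: float
    alignment_length: int


def scan_architecture(protein_id: str, domain_hits: list[FamilyHit]) -> ArchitectureCall:
    """Architecture call from an ordered, overlap-resolved domain string.

    >=2 VipA plus >=1 VipB is the TssC_L fusion signature; VipA-only is
    TssB-like; VipB-only is TssC-like; anything else (including exactly
    one VipA plus one VipB, which is not the 2+1 signature) is "other"
    and flagged for review.
    """
    ordered = sorted(domain_hits, key=lambda h: h.ali_start)
    tokens = tuple(h.family for h in ordered)
    n_a = tokens.count("VipA")
    n_b = tokens.count("VipB")
    if n_a >= 2 and n_b >= 1:
        call, flagged = "TssC_L_fusion", False
    elif n_a >= 1 and n_b == 0:
        call, flagged = "TssB_like", False
    elif n_b >= 1 and n_a == 0:
        call, flagged = "TssC_like", False
    else:
        call, flagged = "other", n_a + n_b > 0
        if flagged:
            logger.info("protein %s has ambiguous domain string %s", protein_id, tokens)
    return ArchitectureCall(protein_id, tokens, call, ordered, flagged)


def _domain_seq(protein_seq: str, hit: FamilyHit) -> str:
    return protein_seq[hit.ali_start : hit.ali_end]


def domain_identity_report(
    fusion_call: ArchitectureCall,
    fusion_seq: str,
    tssB_id: str | None,
    tssB_seq: str | None,
    tssB_hits: list[FamilyHit],
    tssC_id: str | None,
    tssC_seq: str | None,
    tssC_hits: list[FamilyHit],
) -> tuple[list[DomainComparison], list[str]]:
    """Identity of each fused domain against its standalone partner.

    Each VipA instance in the fusion is globally aligned against the VipA
    domain of the cluster's TssB, and the VipB instance against the VipB
    domain of TssC, using domain-hit envelope coordinates to excise the
    domains.  Missing partners produce omission reasons rather than
    errors.  Returns (comparisons, omitted-reasons).
    """
    if fusion_call.call != "TssC_L_fusion":
        raise ArchitectureError("domain identity report requires a TssC_L_fusion call")
    comparisons: list[DomainComparison] = []
    omitted: list[str] = []
    partner_domains = {
        "VipA": (tssB_id, tssB_seq, [h for h in tssB_hits if h.family == "VipA"]),
        "VipB": (tssC_id, tssC_seq, [h for h in tssC_hits if h.family == "VipB"]),
    }
    counters: dict[str, int] = {}
    for hit in fusion_call.domain_hits:
        counters[hit.family] = counters.get(hit.family, 0) + 1
        partner_id, partner_seq, partner_hits = partner_domains[hit.family]
        if partner_id is None or not partner_seq or not partner_hits:
            omitted.append(
                f"{hit.family} instance {counters[hit.family]}: no standalone partner domain"
            )
            continue
        fused = _domain_seq(fusion_seq, hit)
        partner = _domain_seq(partner_seq, partner_hits[0])
        aln = _align.global_align(fused, partner,
                                  query_id=fusion_call.protein_id,
                                  subject_id=partner_id,
                                  gap_open=DOMAIN_GAP_OPEN,
                                  gap_extend=DOMAIN_GAP_EXTEND)
        ev = _align.evalue(aln.bit_score, len(fused), len(partner))
        comparisons.append(
            DomainComparison(
                domain_family=hit.family,
                instance_index=counters[hit.family],
                partner_protein=partner_id,
                identity_fraction=aln.identity_fraction,
                evalue=ev,
            )
        )
    return comparisons, omitted


def classify_repertoire(
    cluster: T6SSCluster,
    calls: dict[str, ArchitectureCall],
    protein_seqs: dict[str, str],
) -> RepertoireCall:
    """Cluster-level sheath repertoire from per-protein architecture calls.

    Any TssC_L fusion protein makes the cluster "fusion"; two or more
    TssC-like proteins with no fusion make it "duplication", with their
    pairwise global identity reported; exactly one TssB-like plus one
    TssC-like is "standard"; anything else is "other".
    """
    members = [calls[g] for g in cluster.gene_ids if g in calls]
    tssB = [c.protein_id for c in members if c.call == "TssB_like"]
    tssC = [c.protein_id for c in members if c.call == "TssC_like"]
    fusion = [c.protein_id for c in members if c.call == "TssC_L_fusion"]
    pairwise = None
    if fusion:
        pattern = "fusion"
    elif len(tssC) >= 2:
        pattern = "duplication"
        a, b = tssC[0], tssC[1]
        aln = _align.global_align(protein_seqs[a], protein_seqs[b],
                                  query_id=a, subject_id=b)
        pairwise = aln.identity_fraction
    elif len(tssB) == 1 and len(tssC) == 1:
        pattern = "standard"
    else:
        pattern = "other"
    return RepertoireCall(cluster.cluster_id, pattern, tssB, tssC, fusion, pairwise)


def passes_effector_thresholds(
    identity_fraction: float,
    evalue: float,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> bool:
    """Both thresholds are inclusive: identity >= 30% and E <= 1e-6 pass."""
    return identity_fraction >= min_identity and evalue <= max_evalue


def search_effectors(
    query_proteins: dict[str, str],
    effector_db: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    use_similarity: bool = False,
) -> list[EffectorHit]:
    """All-vs-all local-alignment screen against an effector database.

    One best hit per query-subject pair; hits must pass BOTH thresholds
    (inclusive) and are returned sorted by E-value then descending bit
    score.  ``use_similarity`` counts positive-scoring substitutions in
    place of identities, for screens quoted as "similarity".
    """
    if not effector_db:
        raise ArchitectureError("empty effector database")
    db_residues = sum(len(s) for s in effector_db.values())
    hits: list[EffectorHit] = []
    for query_id in sorted(query_proteins):
        qseq = query_proteins[query_id]
        if not qseq:
            continue
        for db_id in sorted(effector_db):
            aln = _align.local_align(qseq, effector_db[db_id],
                                     query_id=query_id, subject_id=db_id)
            if aln.is_empty:
                continue
            frac = (_align.percent_similarity(aln) if use_similarity
                    else aln.identity_fraction)
            ev = _align.evalue(aln.bit_score, len(qseq), db_residues)
            if passes_effector_thresholds(frac, ev, min_identity, max_evalue):
                hits.append(
                    EffectorHit(
                        query_id=query_id,
                        db_protein_id=db_id,
                        identity_fraction=frac,
                        evalue=ev,
                        bit_score=aln.bit_score,
                        coverage=aln.query_coverage,
                        alignment_length=aln.columns,
                    )
                )
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.query_id, h.db_protein_id))
    return hits


def write_effector_tsv(hits: list[EffectorHit], path) -> None:
    """BLAST outfmt-6-like hit table."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tpident\tlength\tevalue\tbitscore\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.db_protein_id}\t{100 * h.identity_fraction:.2f}\t"
                f"{h.alignment_length}\t{h.evalue:.3g}\t{h.bit_score:.1f}\n"
            )
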