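"""Assignment of genes to T6SS gene families and sheath Pfam domains.

Families come in three tiers: the 13 core structural genes *tssA*-*tssM*,
a set of accessory/regulatory families (PAAR, FHA, Pkinase, PP2C, DUF4150,
tasL, tasR, vasH, impE, tagF), and the two sheath domains VipA (PF05591,
small subunit) and VipB (PF05943, large subunit) used for fusion-protein
architecture calls.  Hits normally come from an HMMER domtblout table; a
naive alignment-based assigner is provided for fixture-scale work where no
profile search output is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SearchIO, SeqIO

from . import align as _align
from .genome_io import AnnotatedGenome

logger = logging.getLogger(__name__)

CORE_FAMILIES = tuple("tss" + c for c in "ABCDEFGHIJKLM")
ACCESSORY_FAMILIES = (
    "PAAR", "FHA", "Pkinase", "PP2C", "DUF4150",
    "tasL", "tasR", "vasH", "impE", "tagF",
)
DOMAIN_FAMILIES = ("VipA", "VipB")
#: Pfam accessions of the sheath domains (VipA = PF05591, VipB = PF05943).
DOMAIN_ACCESSIONS = {"PF05591": "VipA", "PF05943": "VipB"}

ALL_FAMILIES = CORE_FAMILIES + ACCESSORY_FAMILIES + DOMAIN_FAMILIES


class FamilyError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyHit:
    gene_id: str
    family: str
    score: float
    evalue: float
    ali_start: int  # 0-based half-open on the protein
    ali_end: int

    def __post_init__(self):
        if self.evalue < 0:
            raise FamilyError("evalue must be >= 0")
        if not self.ali_start < self.ali_end:
            raise FamilyError("ali_start must be < ali_end")


@dataclass
class FamilyMap:
    """Resolved per-gene family assignments for one or more genomes."""

    core: dict[str, str] = field(default_factory=dict)
    accessory: dict[str, list[str]] = field(default_factory=dict)
    domains: dict[str, list[FamilyHit]] = field(default_factory=dict)

    def core_family(self, gene_id: str) -> str | None:
        return self.core.get(gene_id)

    def is_core(self, gene_id: str) -> bool:
        return gene_id in self.core

    def accessory_families(self, gene_id: str) -> list[str]:
        return self.accessory.get(gene_id, [])

    def domain_hits(self, gene_id: str) -> list[FamilyHit]:
        return self.domains.get(gene_id, [])


def load_name_map(path) -> dict[str, str]:
    """Profile-name -> family-token map from a two-column TSV."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, token = line.split("\t")[:2]
            out[name] = token
    return out


def load_domtbl(
    path,
    name_map: dict[str, str] | None = None,
    max_evalue: float = 1e-5,
    strict: bool = True,
    extra_families: tuple[str, ...] = (),
) -> list[FamilyHit]:
    """Parse an HMMER3 domtblout table into FamilyHits.

    The query (profile) name, mapped through ``name_map`` when given and
    through the Pfam sheath-domain accessions, must land in the family
    vocabulary; unknown names are an error in strict mode, otherwise
    skipped with a warning.  Domain lines with independent E-value above
    ``max_evalue`` are excluded.
    """
    vocab = set(ALL_FAMILIES) | set(extra_families)
    hits: list[FamilyHit] = []
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        family = qresult.id
        if name_map and family in name_map:
            family = name_map[family]
        acc = (qresult.accession or "").split(".")[0]
        if acc in DOMAIN_ACCESSIONS:
            family = DOMAIN_ACCESSIONS[acc]
        if family not in vocab:
            if strict:
                raise FamilyError(f"unknown family name in domtblout: {qresult.id}")
            logger.warning("skipping unknown family %s", qresult.id)
            continue
        for hit in qresult:
            for hsp in hit:
                if hsp.evalue > max_evalue:
                    continue
                hits.append(
                    FamilyHit(
                        gene_id=hit.id,
                        family=family,
                        score=float(hsp.bitscore),
                        evalue=float(hsp.evalue),
                        ali_start=int(hsp.hit_start),
                        ali_end=int(hsp.hit_end),
                    )
                )
    return hits


def _resolve_domain_overlaps(domain_hits: list[FamilyHit]) -> list[FamilyHit]:
    """Drop the weaker of any pair overlapping >50% of the shorter hit."""
    kept: list[FamilyHit] = []
    for hit in sorted(domain_hits, key=lambda h: (-h.score, h.ali_start, h.family)):
        clash = False
        for other in kept:
            ov = min(hit.ali_end, other.ali_end) - max(hit.ali_start, other.ali_start)
            shorter = min(hit.ali_end - hit.ali_start, other.ali_end - other.ali_start)
            if ov > 0.5 * shorter:
                clash = True
                break
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: h.ali_start)
    return kept


def assign_families(genome: AnnotatedGenome, hits: list[FamilyHit]) -> FamilyMap:
    """Resolve raw hits to one core family, accessory labels and domains.

    Per gene the core family is the highest-scoring core hit (score ties
    broken alphabetically by family token); all accessory hits are kept;
    VipA/VipB domain hits are position-sorted with >50%-overlapping pairs
    resolved in favour of the higher score.  Idempotent and independent of
    hit input order.
    """
    index = genome.gene_index()
    core_best: dict[str, FamilyHit] = {}
    accessory: dict[str, set[str]] = {}
    domains: dict[str, list[FamilyHit]] = {}
    for hit in sorted(hits, key=lambda h: (h.gene_id, h.family, h.ali_start, -h.score)):
        if hit.gene_id not in index:
            raise FamilyError(f"hit references unknown gene_id {hit.gene_id}")
        if hit.family in CORE_FAMILIES:
            prev = core_best.get(hit.gene_id)
            if (
                prev is None
                or hit.score > prev.score
                or (hit.score == prev.score and hit.family < prev.family)
            ):
                core_best[hit.gene_id] = hit
        elif hit.family in DOMAIN_FAMILIES:
            domains.setdefault(hit.gene_id, []).append(hit)
        else:
            accessory.setdefault(hit.gene_id, set()).add(hit.family)
    return FamilyMap(
        core={g: h.family for g, h in core_best.items()},
        accessory={g: sorted(fams) for g, fams in accessory.items()},
        domains={g: _resolve_domain_overlaps(hl) for g, hl in domains.items()},
    )


def read_consensus_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def naive_assign(
    genome: AnnotatedGenome,
    family_consensus: dict[str, str],
    min_identity: float = 0.5,
    max_evalue: float = 1e-5,
) -> list[FamilyHit]:
    """Alignment-based family assignment against consensus sequences.

    A fixture-scale assigner: each CDS protein is locally aligned against
    one consensus protein per family token; a hit is emitted when the
    alignment-column identity is >= ``min_identity`` and the BLAST-style
    E-value (database = the whole consensus set) is <= ``max_evalue``.
    Quadratic in genes x families; intended for small synthetic inputs,
    not genome-scale profile search.
    """
    if not family_consensus:
        raise FamilyError("empty consensus set")
    db_residues = sum(len(s) for s in family_consensus.values())
    hits: list[FamilyHit] = []
    for gene in genome.genes():
        if gene.feature_kind != "CDS" or not gene.protein_seq:
            continue
        for family in sorted(family_consensus):
            aln = _align.local_align(
                gene.protein_seq, family_consensus[family],
                query_id=gene.gene_id, subject_id=family,
            )
            if aln.is_empty:
                continue
            ev = _align.evalue(aln.bit_score, len(gene.protein_seq), db_residues)
            if aln.identity_fraction >= min_identity and ev <= max_evalue:
                hits.append(
                    FamilyHit(
                        gene_id=gene.gene_id,
                        family=family,
                        score=aln.bit_score,
                        evalue=ev,
                        ali_start=aln.query_start,
                        ali_end=aln.query_end,
                    )
                )
    return hits
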