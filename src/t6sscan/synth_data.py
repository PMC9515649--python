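"""Synthetic annotated genome sets with planted T6SS ground truth.

Generates multi-contig draft genomes that emulate a squid-symbiont genome
panel: *Vibrio fischeri*-like genomes carrying a chromosome-1 T6SS
(11/13 cores, missing tssD and tssI) and, island genotype permitting, a
chromosome-2 T6SS inside the genomic island between *manA* and tRNA-Gly;
plus roseobacter-like genomes whose clusters carry either the long
TssC_L fusion sheath gene or a duplicated *tssC*.  Decoy genes, draft
fragmentation (clusters cut at contig edges) and below-threshold decoy
hits are planted alongside, and a machine-readable ground-truth record
sufficient to score every pipeline stage is emitted with the files.

All protein sequences are substitution-only mutants of a bundled
synthetic reference panel (consensus-like random sequences per family);
no external database is needed.  All randomness flows from the single
config seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import genome_io
from .family_assign import CORE_FAMILIES
from .genome_io import AnnotatedGenome, Contig, Gene
from .phylotype import SUBTYPES

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AA.encode(), dtype="S1")
_NT_ARR = np.frombuffer(b"ACGT", dtype="S1")

#: Internal seed for the bundled reference panel; a package constant so the
#: panel is identical across runs and configs.
_PANEL_SEED = 745632901

#: Family lengths (aa) for the synthetic consensus panel; sized after
#: typical T6SS proteins (tssB small sheath subunit ~170 aa, tssC large
#: subunit 506 aa, tssH the large ClpV ATPase, tssM the large membrane
#: component).
FAMILY_LENGTHS = {
    "tssA": 380, "tssB": 170, "tssC": 506, "tssD": 160, "tssE": 140,
    "tssF": 580, "tssG": 330, "tssH": 880, "tssI": 650, "tssJ": 160,
    "tssK": 440, "tssL": 220, "tssM": 1120,
    "PAAR": 95, "FHA": 230, "Pkinase": 270, "PP2C": 240, "DUF4150": 130,
    "tasL": 520, "tasR": 210, "vasH": 480, "impE": 250, "tagF": 220,
    "manA": 390,
}

#: Sheath domain envelopes on the synthetic TssB/TssC (0-based half-open).
VIPA_ENVELOPE = (5, 165)
VIPB_ENVELOPE = (20, 480)

#: Fused-domain target identities for planted TssC_L proteins: one
#: high-identity VipA, one low-identity VipA, one low-identity VipB
#: relative to the standalone TssB/TssC of the same cluster.
DEFAULT_FUSION_IDENTITIES = (0.8621, 0.2632, 0.3094)

T6SS1_CORES = tuple(f for f in CORE_FAMILIES if f not in ("tssD", "tssI"))
ROSEO_CORES = tuple(f for f in CORE_FAMILIES if f != "tssJ")

ISLAND_SIZE_RANGE_KBP = (11.2, 106.2)


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Primitive generators


def random_protein(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_AA_ARR, size=length).tobytes().decode()


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_NT_ARR, size=length).tobytes().decode()


def mutate_sequence(reference: str, target_identity: float, seed) -> str:
    """Substitution-only mutant with exact identity to the reference.

    Exactly ``round((1 - target_identity) * len)`` positions are replaced
    with a different residue, so the un-gapped identity equals
    ``round(target_identity * len) / len``; on short sequences the
    nearest achievable identity is used.  ``seed`` may be an int or a
    numpy Generator.
    """
    if not 0 < target_identity <= 1:
        raise SynthError("target_identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(reference)
    n_mut = int(round((1.0 - target_identity) * n))
    if n_mut == 0:
        return reference
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(reference)
    for pos in positions:
        current = out[pos]
        choices = [a for a in AA if a != current]
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def largest_remainder(n: int, proportions) -> list[int]:
    """Apportion n items to proportions by the largest-remainder method.

    Remainder ties break on the earlier index, deterministically.
    """
    total = sum(proportions)
    quotas = [p / total * n for p in proportions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder_order = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainder_order[: n - sum(counts)]:
        counts[i] += 1
    return counts


@lru_cache(maxsize=1)
def reference_panel() -> dict[str, str]:
    """The bundled synthetic consensus panel (deterministic constant).

    Keys: family tokens (FAMILY_LENGTHS), per-subtype sheath bases
    ``sheath_B_<subtype>`` / ``sheath_C_<subtype>``, island gene-content
    blocks ``isl_o{1..4}_*`` and conserved intra-cluster hypotheticals
    ``isl_x_*``, and effector references ``eff_*``.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    panel: dict[str, str] = {}
    for fam in sorted(FAMILY_LENGTHS):
        panel[fam] = random_protein(rng, FAMILY_LENGTHS[fam])
    for subtype in SUBTYPES:
        panel[f"sheath_B_{subtype}"] = random_protein(rng, FAMILY_LENGTHS["tssB"])
        panel[f"sheath_C_{subtype}"] = random_protein(rng, FAMILY_LENGTHS["tssC"])
    for block, count in (("o1", 6), ("o2", 6), ("o3", 8), ("o4", 8), ("x", 8)):
        for i in range(1, count + 1):
            panel[f"isl_{block}_{i}"] = random_protein(rng, int(rng.integers(220, 380)))
    for i in range(1, 11):
        panel[f"eff_{i:02d}"] = random_protein(rng, int(rng.integers(260, 420)))
    return panel


# ---------------------------------------------------------------------------
# Configuration and truth


@dataclass
class SynthConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the surveyed panel: 34 island-informative vibrio-like
    genomes at the five genotype proportions read from the island
    comparison (52.9 / 2.9 / 11.8 / 11.7 / 20.6%, the middle class split
    into two archetypes), plus roseobacter-like genomes carrying the
    TssC_L fusion or the duplicated tssC sheath repertoires.
    """

    seed: int
    n_genomes: int = 34
    genotype_proportions: tuple = (0.529, 0.029, 0.118, 0.117, 0.206)
    subtype_t6ss1: str = "1"
    subtype_t6ss2: str = "1"
    subtype_roseo: str = "3"
    sheath_identity: float = 0.85
    family_identity: float = 0.90
    fusion_identities: tuple = DEFAULT_FUSION_IDENTITIES
    duplicate_tssC_identity: float = 0.355
    effector_identity: float = 0.45
    fragmentation_prob: float = 0.15
    n_fusion_genomes: int = 5
    n_duplication_genomes: int = 4
    backbone_genes_per_side: int = 11
    max_intervening: int = 2
    boundary_mode: bool = False
    island_size_ranges: dict = field(
        default_factory=lambda: {
            1: (40_000, 80_000), 2: (30_000, 60_000),
            3: (15_000, 30_000), 4: (15_000, 30_000), 5: (11_200, 13_000),
        }
    )

    def __post_init__(self):
        if self.seed is None:
            raise SynthError("seed is mandatory")
        # published percentages are rounded; allow their 99.9% total
        if abs(sum(self.genotype_proportions) - 1.0) > 5e-3:
            raise SynthError("genotype proportions must sum to 1")
        for ident in (self.sheath_identity, self.family_identity,
                      self.effector_identity):
            if not 0 < ident <= 1:
                raise SynthError("identities must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["island_size_ranges"] = {str(k): list(v) for k, v in
                                   self.island_size_ranges.items()}
        return d


@dataclass
class GroundTruth:
    data: dict

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(json.load(fh))

    @property
    def genomes(self) -> dict:
        return self.data["genomes"]


# ---------------------------------------------------------------------------
# Genome building


class ContigBuilder:
    def __init__(self, contig_id: str, start_offset: int = 200):
        self.contig_id = contig_id
        self.cursor = start_offset
        self.genes: list[Gene] = []

    def add_spacer(self, bp: int) -> None:
        self.cursor += max(0, int(bp))

    def add_gene(self, gene_id: str, protein: str, product: str,
                 kind: str = "CDS", strand: str = "+") -> Gene:
        length = len(protein) * 3 + 3 if kind == "CDS" else 75
        gene = Gene(gene_id, self.contig_id, self.cursor, self.cursor + length,
                    strand, protein if kind == "CDS" else "", product, kind)
        self.genes.append(gene)
        self.cursor += length + 80  # default intergenic spacing
        return gene

    def build(self, rng: np.random.Generator) -> Contig:
        length = self.cursor + 120
        contig = Contig(self.contig_id, length,
                        genes=list(self.genes),
                        sequence=random_dna(rng, length))
        contig.sort_genes()
        return contig


class GenomeBuilder:
    """Accumulates genes, planted hits and truth for one genome."""

    def __init__(self, genome_id: str, rng: np.random.Generator):
        self.genome_id = genome_id
        self.rng = rng
        self.contigs: list[ContigBuilder] = []
        self._counter = 0
        self.hits: list[dict] = []  # rows for the domtblout table
        self.gene_families: dict[str, str] = {}
        self.island_tokens: dict[str, str] = {}

    def new_contig(self, suffix: str) -> ContigBuilder:
        cb = ContigBuilder(f"{self.genome_id}_{suffix}")
        self.contigs.append(cb)
        return cb

    def next_id(self) -> str:
        self._counter += 1
        return f"{self.genome_id}_{self._counter:05d}"

    def plant_hit(self, gene_id: str, family: str, protein_len: int,
                  ali: tuple[int, int] | None = None,
                  score: float | None = None, evalue: float = 1e-50) -> None:
        start, end = ali if ali else (0, protein_len)
        self.hits.append(
            {"gene_id": gene_id, "family": family, "tlen": protein_len,
             "score": score if score is not None else 40.0 + protein_len / 10.0,
             "evalue": evalue, "ali_start": start, "ali_end": end}
        )

    def add_family_gene(self, cb: ContigBuilder, family: str, protein: str,
                        product: str | None = None, domains=()) -> str:
        gid = self.next_id()
        cb.add_gene(gid, protein, product or f"{family} protein")
        self.gene_families[gid] = family
        self.plant_hit(gid, family, len(protein))
        for dom_family, start, end in domains:
            self.plant_hit(gid, dom_family, len(protein), ali=(start, end),
                           score=30.0 + (end - start) / 5.0)
        return gid

    def add_decoy_gene(self, cb: ContigBuilder, length: int | None = None) -> str:
        gid = self.next_id()
        protein = random_protein(self.rng, length or int(self.rng.integers(120, 350)))
        cb.add_gene(gid, protein, "hypothetical protein")
        self.gene_families[gid] = "decoy"
        return gid

    def finish(self, source: str, taxon_label: str) -> AnnotatedGenome:
        return AnnotatedGenome(
            self.genome_id,
            [cb.build(self.rng) for cb in self.contigs],
            source=source,
            taxon_label=taxon_label,
        )


def _sheath_domains(family: str, protein_len: int):
    if family == "tssB":
        return [("VipA", *VIPA_ENVELOPE)]
    if family == "tssC" and protein_len >= VIPB_ENVELOPE[1]:
        return [("VipB", *VIPB_ENVELOPE)]
    return []


def plant_cluster(
    builder: GenomeBuilder,
    cb: ContigBuilder,
    subtype: str,
    cores: tuple[str, ...],
    accessories: tuple[str, ...] = (),
    gap_lengths: list[int] | None = None,
    intervening_pool: list[str] | None = None,
    sheath_identity: float = 0.85,
    family_identity: float = 0.90,
    max_gap_rule: int = 10,
) -> list[dict]:
    """Plant one cluster in canonical core order; return expected truth.

    ``gap_lengths[i]`` is the number of non-core genes between core i and
    core i+1 (drawn 0..2 when omitted); a gap above ``max_gap_rule``
    intentionally splits the planted cluster, and the returned truth then
    records the resulting sub-threshold or split fragments, mirroring how
    the spacing rule must read the layout.  Accessory genes are drawn
    from ``accessories`` and spliced into the gaps; intervening non-core
    genes come from ``intervening_pool`` (panel keys for conserved
    hypotheticals) and then random decoys.
    """
    unknown = [f for f in cores if f not in CORE_FAMILIES]
    if unknown:
        raise SynthError(f"completeness spec requests unknown core families {unknown}")
    panel = reference_panel()
    rng = builder.rng
    ordered = tuple(f for f in CORE_FAMILIES if f in cores)
    if gap_lengths is None:
        gap_lengths = [int(rng.integers(0, 3)) for _ in range(len(ordered) - 1)]
    if len(gap_lengths) != len(ordered) - 1:
        raise SynthError("gap_lengths must have len(cores) - 1 entries")

    filler: list[tuple[str, str | None]] = [(acc, acc) for acc in accessories]
    for key in intervening_pool or []:
        filler.append((key, None))
    total_gap = sum(gap_lengths)
    while len(filler) < total_gap:
        filler.append(("decoy", None))
    rng.shuffle(filler)

    entries: list[tuple[str, str]] = []  # (gene_id, family or 'decoy'/panel key)
    fpos = 0
    for i, fam in enumerate(ordered):
        if fam == "tssB":
            protein = mutate_sequence(panel[f"sheath_B_{subtype}"], sheath_identity, rng)
        elif fam == "tssC":
            protein = mutate_sequence(panel[f"sheath_C_{subtype}"], sheath_identity, rng)
        else:
            protein = mutate_sequence(panel[fam], family_identity, rng)
        gid = builder.add_family_gene(cb, fam, protein,
                                      domains=_sheath_domains(fam, len(protein)))
        entries.append((gid, fam))
        if i < len(ordered) - 1:
            for _ in range(gap_lengths[i]):
                if fpos < len(filler):
                    token, acc_family = filler[fpos]
                    fpos += 1
                else:
                    token, acc_family = "decoy", None
                if acc_family:
                    protein = mutate_sequence(panel[acc_family], family_identity, rng)
                    gid = builder.add_family_gene(cb, acc_family, protein)
                    entries.append((gid, acc_family))
                elif token.startswith("isl_"):
                    protein = mutate_sequence(panel[token], family_identity, rng)
                    gid = builder.next_id()
                    cb.add_gene(gid, protein, "conserved hypothetical protein")
                    builder.gene_families[gid] = token
                    entries.append((gid, token))
                else:
                    gid = builder.add_decoy_gene(cb)
                    entries.append((gid, "decoy"))

    # expected clusters under the spacing rule, derived from the layout
    truth: list[dict] = []
    segment: list[tuple[int, str, str]] = []  # (entry idx, gene_id, family)
    core_entries = [(i, g, f) for i, (g, f) in enumerate(entries) if f in CORE_FAMILIES]
    segments: list[list[tuple[int, str, str]]] = []
    for item in core_entries:
        if segment and item[0] - segment[-1][0] - 1 > max_gap_rule:
            segments.append(segment)
            segment = []
        segment.append(item)
    if segment:
        segments.append(segment)
    for seg in segments:
        families = sorted({f for _, _, f in seg})
        if len(families) < 4:
            continue
        lo, hi = seg[0][0], seg[-1][0]
        truth.append(
            {
                "contig_id": cb.contig_id,
                "gene_ids": [g for g, _ in entries[lo : hi + 1]],
                "core_present": families,
                "subtype": subtype,
                "truncated": "none",
            }
        )
    return truth


def _plant_fusion_gene(builder, cb, tssB_seq, tssC_seq, identities, rng):
    """Plant a TssC_L gene: two VipA domains + one VipB, linkers between.

    Domain segments are full-envelope-length mutants of the standalone
    TssB VipA and TssC VipB at the given identities, so the identity
    report can recover them exactly.  Annotated (and hit) as tssC, as
    such genes are in real annotations, with the true architecture
    carried by the VipA/VipB domain hits.
    """
    vipA = tssB_seq[VIPA_ENVELOPE[0]:VIPA_ENVELOPE[1]]
    vipB = tssC_seq[VIPB_ENVELOPE[0]:VIPB_ENVELOPE[1]]
    segA1 = mutate_sequence(vipA, identities[0], rng)
    segA2 = mutate_sequence(vipA, identities[1], rng)
    segB = mutate_sequence(vipB, identities[2], rng)
    linkers = [120, 130, 140]
    tail = 1684 - (len(segA1) + len(segA2) + len(segB) + sum(linkers))
    parts = [random_protein(rng, linkers[0]), segA1,
             random_protein(rng, linkers[1]), segA2,
             random_protein(rng, linkers[2]), segB,
             random_protein(rng, max(0, tail))]
    protein = "".join(parts)
    offs = []
    pos = 0
    for part in parts:
        offs.append(pos)
        pos += len(part)
    domains = [("VipA", offs[1], offs[1] + len(segA1)),
               ("VipA", offs[3], offs[3] + len(segA2)),
               ("VipB", offs[5], offs[5] + len(segB))]
    gid = builder.add_family_gene(cb, "tssC", protein,
                                  product="tssC large sheath subunit",
                                  domains=domains)
    builder.gene_families[gid] = "tssC_L"
    return gid


# ---------------------------------------------------------------------------
# Whole-genome assembly


def _build_vibrio_genome(gid, archetype, fragmented, config, rng, eff_refs):
    panel = reference_panel()
    builder = GenomeBuilder(gid, rng)
    truth_clusters: list[dict] = []

    # chromosome 1: backbone + T6SS1 (11/13 cores, missing tssD and tssI)
    boundary = config.boundary_mode
    if fragmented:
        cb1a = builder.new_contig("chr1a")
        for _ in range(config.backbone_genes_per_side):
            builder.add_decoy_gene(cb1a)
        split_at = int(rng.integers(4, len(T6SS1_CORES) - 3))
        part1 = T6SS1_CORES[:split_at]
        part2 = T6SS1_CORES[split_at:]
        t1 = plant_cluster(builder, cb1a, config.subtype_t6ss1, part1,
                           accessories=("PP2C",),
                           sheath_identity=config.sheath_identity,
                           family_identity=config.family_identity)
        cb1b = builder.new_contig("chr1b")
        t2 = plant_cluster(builder, cb1b, config.subtype_t6ss1, part2,
                           accessories=("Pkinase", "FHA"),
                           sheath_identity=config.sheath_identity,
                           family_identity=config.family_identity)
        for _ in range(config.backbone_genes_per_side):
            builder.add_decoy_gene(cb1b)
        for t in t1:
            t.update(system="T6SS1", truncated="right")
        for t in t2:
            t.update(system="T6SS1", truncated="left")
        truth_clusters += t1 + t2
    else:
        cb1 = builder.new_contig("chr1")
        for _ in range(config.backbone_genes_per_side):
            builder.add_decoy_gene(cb1)
        gaps = None
        if boundary:
            # exercise the spacing boundary: one merged gap of exactly 10
            gaps = [0] * (len(T6SS1_CORES) - 1)
            gaps[4] = 10
        t1 = plant_cluster(builder, cb1, config.subtype_t6ss1, T6SS1_CORES,
                           accessories=("PP2C", "Pkinase", "FHA"),
                           gap_lengths=gaps,
                           sheath_identity=config.sheath_identity,
                           family_identity=config.family_identity)
        for t in t1:
            t["system"] = "T6SS1"
        truth_clusters += t1
        for _ in range(config.backbone_genes_per_side):
            builder.add_decoy_gene(cb1)

    # chromosome 2: the genomic island between manA and tRNA-Gly
    cb2 = builder.new_contig("chr2")
    for _ in range(6):
        builder.add_decoy_gene(cb2)
    manA_seq = mutate_sequence(panel["manA"], config.family_identity, rng)
    manA_id = builder.next_id()
    cb2.add_gene(manA_id, manA_seq, "manA mannose-6-phosphate isomerase")
    builder.gene_families[manA_id] = "manA"
    builder.island_tokens[manA_id] = "flank:manA"

    island_entries: list[str] = [manA_id]
    lo_kbp, hi_kbp = config.island_size_ranges[archetype]
    target_bp = int(rng.integers(lo_kbp, hi_kbp))
    spacer_anchor = cb2.cursor

    effector_genes: list[str] = []
    if archetype in (1, 2):
        block = "o1" if archetype == 1 else "o2"
        n_other = 6
        for i in range(1, n_other + 1):
            key = f"isl_{block}_{i}"
            protein = mutate_sequence(panel[key], config.family_identity, rng)
            g = builder.next_id()
            cb2.add_gene(g, protein, "island conserved protein")
            builder.gene_families[g] = key
            builder.island_tokens[g] = key
            island_entries.append(g)
        if archetype == 1:
            cores = CORE_FAMILIES
            accessories = ("DUF4150", "tasL", "tasR", "FHA", "Pkinase")
            pool = [f"isl_x_{i}" for i in range(1, 9)]
        else:
            cores = CORE_FAMILIES[:6]  # genuinely incomplete: tssA-tssF only
            accessories = ()
            pool = []
        tc = plant_cluster(builder, cb2, config.subtype_t6ss2, cores,
                           accessories=accessories, intervening_pool=pool,
                           sheath_identity=config.sheath_identity,
                           family_identity=config.family_identity)
        for t in tc:
            t["system"] = "T6SS2"
            island_entries.extend(t["gene_ids"])
            for g in t["gene_ids"]:
                token = builder.gene_families.get(g, "decoy")
                if token == "decoy":
                    token = f"private:{g}"  # random filler: its own family
                builder.island_tokens[g] = token
        truth_clusters += tc
        # expansion region beyond the cluster (after the vasH regulator in
        # complete islands): accessory regulator + an effector homolog
        if archetype == 1:
            vasH_seq = mutate_sequence(panel["vasH"], config.family_identity, rng)
            vh = builder.add_family_gene(cb2, "vasH", vasH_seq)
            builder.island_tokens[vh] = "vasH"
            island_entries.append(vh)
            ref = f"eff_{int(rng.integers(1, 11)):02d}"
            protein = mutate_sequence(panel[ref], config.effector_identity, rng)
            g = builder.next_id()
            cb2.add_gene(g, protein, "putative secreted effector")
            builder.gene_families[g] = f"effector_homolog:{ref}"
            builder.island_tokens[g] = f"eff:{gid}"
            effector_genes.append(g)
            island_entries.append(g)
        else:
            for _ in range(4):  # filler so the cluster sits clear of the ends
                g = builder.add_decoy_gene(cb2)
                builder.island_tokens[g] = f"private:{g}"
                island_entries.append(g)
    elif archetype in (3, 4):
        block = "o3" if archetype == 3 else "o4"
        for i in range(1, 9):
            key = f"isl_{block}_{i}"
            protein = mutate_sequence(panel[key], config.family_identity, rng)
            g = builder.next_id()
            cb2.add_gene(g, protein, "island conserved protein")
            builder.gene_families[g] = key
            builder.island_tokens[g] = key
            island_entries.append(g)

    if archetype in (1, 2, 3, 4):
        g = builder.add_decoy_gene(cb2)  # one strain-private island gene
        builder.island_tokens[g] = f"private:{g}"
        island_entries.append(g)

    # pad the island to its drawn target size with one large spacer
    # (an integrase-free insertion-site region)
    natural = cb2.cursor - spacer_anchor
    trna_len = 75 + 80
    deficit = target_bp - (natural + trna_len + FAMILY_LENGTHS["manA"] * 3 + 3)
    if deficit > 0:
        cb2.add_spacer(deficit)

    trna_id = builder.next_id()
    cb2.add_gene(trna_id, "", "tRNA-Gly", kind="tRNA")
    builder.gene_families[trna_id] = "tRNA-Gly"
    builder.island_tokens[trna_id] = "flank:tRNA-Gly"
    island_entries.append(trna_id)
    for _ in range(6):
        builder.add_decoy_gene(cb2)

    index_for_span = {}
    genome = builder.finish(
        source="host-associated" if rng.random() < 0.8 else "environmental",
        taxon_label="Vibrio fischeri-like (synthetic)",
    )
    index_for_span = genome.gene_index()
    island_span = (index_for_span[manA_id].start, index_for_span[trna_id].end)

    truth = {
        "kind": "vibrio",
        "archetype": archetype,
        "fragmented": fragmented,
        "clusters": truth_clusters,
        "island": {
            "status": "resolved",
            "flank_a_gene": manA_id,
            "flank_b_gene": trna_id,
            "gene_ids": island_entries,
            "length_bp": island_span[1] - island_span[0],
        },
        "effector_genes": effector_genes,
        "repertoire": "standard",
    }
    return genome, builder, truth


def _build_roseo_genome(gid, pattern, config, rng):
    """Roseobacter-like genome: one T6SS (12/13 cores, no tssJ) whose
    sheath repertoire is either a TssC_L fusion or a duplicated tssC."""
    panel = reference_panel()
    builder = GenomeBuilder(gid, rng)
    cb = builder.new_contig("chr1")
    for _ in range(config.backbone_genes_per_side):
        builder.add_decoy_gene(cb)
    tc = plant_cluster(builder, cb, config.subtype_roseo, ROSEO_CORES,
                       accessories=("PAAR", "FHA", "impE"),
                       sheath_identity=config.sheath_identity,
                       family_identity=config.family_identity)
    # recover this cluster's own sheath sequences for the extra sheath gene
    index = {g.gene_id: g for c in builder.contigs for g in c.genes}
    tssB_id = next(g for g, f in builder.gene_families.items() if f == "tssB")
    tssC_id = next(g for g, f in builder.gene_families.items() if f == "tssC")
    tssB_seq = index[tssB_id].protein_seq
    tssC_seq = index[tssC_id].protein_seq

    fusion_identities = None
    duplicate_identity = None
    if pattern == "fusion":
        extra = _plant_fusion_gene(builder, cb, tssB_seq, tssC_seq,
                                   config.fusion_identities, rng)
        fusion_identities = list(config.fusion_identities)
    else:
        protein = mutate_sequence(tssC_seq, config.duplicate_tssC_identity, rng)
        extra = builder.add_family_gene(
            cb, "tssC", protein, product="tssC large sheath subunit",
            domains=_sheath_domains("tssC", len(protein)))
        duplicate_identity = config.duplicate_tssC_identity
    for t in tc:
        t["system"] = "roseo_T6SS1"
        # the extra sheath gene carries a tssC hit and sits right after
        # the last core gene, so the spacing rule extends the cluster to it
        t["gene_ids"] = t["gene_ids"] + [extra]
    truth_clusters = tc
    for _ in range(config.backbone_genes_per_side):
        builder.add_decoy_gene(cb)

    genome = builder.finish("host-associated", "Roseobacter-like (synthetic)")
    truth = {
        "kind": f"roseobacter_{pattern}",
        "archetype": None,
        "fragmented": False,
        "clusters": truth_clusters,
        "island": None,
        "effector_genes": [],
        "repertoire": pattern,
        "fusion_identities": fusion_identities,
        "duplicate_identity": duplicate_identity,
        "fusion_gene": extra if pattern == "fusion" else None,
    }
    return genome, builder, truth

# ---------------------------------------------------------------------------
# Output writers


def _write_domtbl(path, rows: list[dict]) -> None:
    """HMMER3 domtblout dialect (one line per planted domain hit)."""
    acc = {"VipA": "PF05591.12", "VipB": "PF05943.14"}
    with open(path, "w") as fh:
        fh.write("# target name accession tlen query name accession qlen "
                 "E-value score bias # of c-Evalue i-Evalue score bias "
                 "hmm_from hmm_to ali_from ali_to env_from env_to acc "
                 "description of target\n")
        fh.write("#" + "-" * 40 + "\n")
        by_family: dict[str, list[dict]] = {}
        for row in rows:
            by_family.setdefault(row["family"], []).append(row)
        for family in sorted(by_family):
            frows = sorted(by_family[family], key=lambda r: r["gene_id"])
            qlen = FAMILY_LENGTHS.get(family, 200)
            for r in frows:
                alen = r["ali_end"] - r["ali_start"]
                fh.write(
                    f"{r['gene_id']:<20} - {r['tlen']:>6} "
                    f"{family:<12} {acc.get(family, '-'):<11} {qlen:>5} "
                    f"{r['evalue']:9.2g} {r['score']:6.1f} 0.0 "
                    f"1 1 {r['evalue'] / 10:9.2g} {r['evalue']:9.2g} "
                    f"{r['score']:6.1f} 0.0 "
                    f"1 {alen} {r['ali_start'] + 1} {r['ali_end']} "
                    f"{max(1, r['ali_start'])} {min(r['tlen'], r['ali_end'] + 5)} "
                    f"0.95 planted\n"
                )


def _write_fasta(path, records: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rec_id, description, seq in records:
            header = f">{rec_id} {description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_reference_sheaths(path, sheath_identity_within: float = 0.92,
                            n_per_subtype: int = 2, seed: int = 11) -> None:
    """Labeled reference sheath FASTA (subtype tokens in the headers).

    One concatenated TssB+TssC record per reference; headers carry
    ``subtype=`` and ``tssB_len=`` tokens so the record can be split back
    into its components.
    """
    panel = reference_panel()
    rng = np.random.default_rng(seed)
    records = []
    for subtype in SUBTYPES:
        base_b = panel[f"sheath_B_{subtype}"]
        base_c = panel[f"sheath_C_{subtype}"]
        for i in range(1, n_per_subtype + 1):
            b = base_b if i == 1 else mutate_sequence(base_b, sheath_identity_within, rng)
            c = base_c if i == 1 else mutate_sequence(base_c, sheath_identity_within, rng)
            records.append(
                (f"ref_{subtype}_{i}", f"subtype={subtype} tssB_len={len(b)}", b + c)
            )
    _write_fasta(path, records)


def _write_ani_table(path, genome_ids: list[str], clone_pair: tuple[str, str],
                     rng: np.random.Generator) -> None:
    """FastANI-style pairwise table: query, reference, ANI percent.

    The type-strain reference REF_VF anchors species assignment; vibrio
    genomes sit above the 95% species line, roseobacter genomes far
    below, and one co-isolated pair is planted at ANI 100 (clones).
    """
    vibrio = [g for g in genome_ids if g.startswith("VF")] + ["REF_VF"]
    ani: dict[tuple[str, str], float] = {}
    everything = genome_ids + ["REF_VF"]
    for i, a in enumerate(everything):
        for b in everything[i + 1:]:
            both_vibrio = a in vibrio and b in vibrio
            both_roseo = a not in vibrio and b not in vibrio
            if {a, b} == set(clone_pair):
                value = 100.0
            elif both_vibrio:
                value = float(np.round(96.0 + 3.5 * rng.random(), 2))
            elif both_roseo:
                value = float(np.round(84.0 + 6.0 * rng.random(), 2))
            else:
                value = float(np.round(70.0 + 8.0 * rng.random(), 2))
            ani[(a, b)] = ani[(b, a)] = value
    with open(path, "w") as fh:
        for a in everything:
            for b in everything:
                if a != b:
                    fh.write(f"{a}\t{b}\t{ani[(a, b)]:.2f}\n")


def generate_genome_set(config: SynthConfig, out_dir) -> GroundTruth:
    """Emit the full synthetic panel and its ground truth.

    Per genome: ``<id>.gff`` + ``<id>.fna`` + ``<id>.faa`` and a GenBank
    twin ``<id>.gbk``.  Shared: ``hits.domtbl`` (planted family/domain
    hits, plus a few decoy hits above the inclusion threshold),
    ``effector_db.faa``, ``reference_sheaths.faa``, ``ani.tsv``,
    ``genomes.tsv`` and ``truth.json``.  Fully deterministic given
    ``config.seed``.
    """
    os.makedirs(out_dir, exist_ok=True)
    master = np.random.default_rng(config.seed)
    panel = reference_panel()

    counts = largest_remainder(config.n_genomes, config.genotype_proportions)
    archetypes: list[int] = []
    for arch, cnt in enumerate(counts, start=1):
        archetypes.extend([arch] * cnt)

    genomes_truth: dict[str, dict] = {}
    gene_families: dict[str, str] = {}
    island_tokens: dict[str, str] = {}
    all_hits: list[dict] = []
    genome_rows: list[tuple[str, str]] = []

    def emit(genome, builder, truth):
        gid = genome.genome_id
        genome_io.write_gff_fasta(
            genome,
            os.path.join(out_dir, f"{gid}.gff"),
            os.path.join(out_dir, f"{gid}.fna"),
            os.path.join(out_dir, f"{gid}.faa"),
        )
        genome_io.write_genbank(genome, os.path.join(out_dir, f"{gid}.gbk"))
        genomes_truth[gid] = truth
        gene_families.update(builder.gene_families)
        island_tokens.update(builder.island_tokens)
        all_hits.extend(builder.hits)
        genome_rows.append((gid, truth["kind"]))

    vibrio_ids = []
    for i, arch in enumerate(archetypes, start=1):
        gid = f"VF{i:02d}"
        vibrio_ids.append(gid)
        rng = np.random.default_rng(master.integers(0, 2**31))
        fragmented = bool(rng.random() < config.fragmentation_prob)
        genome, builder, truth = _build_vibrio_genome(
            gid, arch, fragmented, config, rng, panel)
        emit(genome, builder, truth)

    for i in range(1, config.n_fusion_genomes + 1):
        gid = f"ROSF{i:02d}"
        rng = np.random.default_rng(master.integers(0, 2**31))
        genome, builder, truth = _build_roseo_genome(gid, "fusion", config, rng)
        emit(genome, builder, truth)
    for i in range(1, config.n_duplication_genomes + 1):
        gid = f"ROSD{i:02d}"
        rng = np.random.default_rng(master.integers(0, 2**31))
        genome, builder, truth = _build_roseo_genome(gid, "duplication", config, rng)
        emit(genome, builder, truth)

    # decoy hit lines above the inclusion threshold: must be filtered out
    decoy_rng = np.random.default_rng(master.integers(0, 2**31))
    decoy_gene_ids = sorted(g for g, f in gene_families.items() if f == "decoy")
    for g in decoy_gene_ids[:5]:
        all_hits.append(
            {"gene_id": g, "family": "tssK", "tlen": 200, "score": 8.0,
             "evalue": 1e-3, "ali_start": 0, "ali_end": 100}
        )

    _write_domtbl(os.path.join(out_dir, "hits.domtbl"), all_hits)
    _write_fasta(
        os.path.join(out_dir, "effector_db.faa"),
        [(f"eff_{i:02d}", "validated effector (synthetic)", panel[f"eff_{i:02d}"])
         for i in range(1, 11)],
    )
    write_reference_sheaths(os.path.join(out_dir, "reference_sheaths.faa"))
    clone_pair = (vibrio_ids[0], vibrio_ids[1]) if len(vibrio_ids) >= 2 else None
    if clone_pair:
        _write_ani_table(os.path.join(out_dir, "ani.tsv"),
                         sorted(genomes_truth), clone_pair, decoy_rng)
    with open(os.path.join(out_dir, "genomes.tsv"), "w") as fh:
        fh.write("genome_id\tkind\n")
        for gid, kind in genome_rows:
            fh.write(f"{gid}\t{kind}\n")

    truth = GroundTruth(
        {
            "config": config.to_dict(),
            "genomes": genomes_truth,
            "gene_families": gene_families,
            "island_family_tokens": island_tokens,
            "clone_pair": list(clone_pair) if clone_pair else None,
            "genotype_counts": counts,
        }
    )
    truth.save(os.path.join(out_dir, "truth.json"))
    return truth
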