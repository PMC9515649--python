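"""Genome data model and readers/writers for GFF3 + FASTA and GenBank.

Coordinates are stored 0-based half-open internally and serialized 1-based
inclusive (GFF/GenBank convention), so ``length == end - start`` holds on
the internal model.  tRNA features are retained as genes: tRNA-Gly is one
of the two genomic-island flanking markers.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from gffutils.feature import feature_from_line
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_SOURCES = ("host-associated", "environmental", "unknown")
_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA"}


class GenomeIOError(ValueError):
    pass


@dataclass
class Gene:
    """One gene model: 0-based half-open coordinates on its contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str = ""
    product: str = ""
    feature_kind: str = "CDS"
    partial: bool = False  # pseudo/partial CDS retained but flagged

    def __post_init__(self):
        if not self.start < self.end:
            raise GenomeIOError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    contig_id: str
    length: int
    genes: list[Gene] = field(default_factory=list)
    sequence: str | None = None  # nucleotide sequence when available

    def sort_genes(self) -> None:
        # deterministic order: start, then end, then id
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def validate(self) -> None:
        for g in self.genes:
            if g.end > self.length:
                raise GenomeIOError(
                    f"gene {g.gene_id} extends past contig {self.contig_id} "
                    f"({g.end} > {self.length})"
                )


@dataclass
class AnnotatedGenome:
    genome_id: str
    contigs: list[Contig] = field(default_factory=list)
    source: str = "unknown"
    taxon_label: str = ""

    def __post_init__(self):
        if self.source not in VALID_SOURCES:
            raise GenomeIOError(f"source must be one of {VALID_SOURCES}")
        seen = set()
        for c in self.contigs:
            if c.contig_id in seen:
                raise GenomeIOError(f"duplicate contig_id {c.contig_id}")
            seen.add(c.contig_id)

    def genes(self):
        for c in self.contigs:
            yield from c.genes

    def gene_index(self) -> dict[str, Gene]:
        idx = {}
        for g in self.genes():
            if g.gene_id in idx:
                raise GenomeIOError(f"duplicate gene_id {g.gene_id}")
            idx[g.gene_id] = g
        return idx

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


# ---------------------------------------------------------------------------
# Readers


def read_gff_fasta(
    gff_path,
    genome_fasta_path,
    protein_fasta_path,
    genome_id: str | None = None,
    source: str = "unknown",
    taxon_label: str = "",
) -> AnnotatedGenome:
    """Read a Prokka-style GFF3 plus genomic and protein FASTA.

    GFF 1-based inclusive coordinates are converted to 0-based half-open.
    Every CDS must have a matching protein FASTA record (hard error naming
    the gene otherwise) unless it is flagged partial/pseudo.
    """
    contig_seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(genome_fasta_path), "fasta")}
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta_path), "fasta")}

    contigs: dict[str, Contig] = {
        cid: Contig(cid, len(seq), sequence=seq) for cid, seq in contig_seqs.items()
    }

    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GenomeIOError(f"malformed GFF line {lineno}: {exc}") from exc
            kind = _FEATURE_KINDS.get(feat.featuretype)
            if feat.featuretype in ("region", "gene"):
                continue
            if kind is None:
                kind = "other"
            gene_id = (feat.attributes.get("ID") or [None])[0]
            if gene_id is None:
                raise GenomeIOError(f"GFF line {lineno}: feature without ID attribute")
            product = (feat.attributes.get("product") or [""])[0]
            partial = "pseudo" in feat.attributes or "partial" in feat.attributes
            protein = ""
            if kind == "CDS":
                if gene_id in proteins:
                    protein = proteins[gene_id]
                elif not partial:
                    raise GenomeIOError(
                        f"CDS {gene_id} has no protein FASTA record "
                        f"(GFF line {lineno})"
                    )
                else:
                    logger.warning("partial CDS %s has no protein sequence", gene_id)
            if feat.seqid not in contigs:
                raise GenomeIOError(
                    f"GFF line {lineno}: contig {feat.seqid} absent from genome FASTA"
                )
            gene = Gene(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                protein_seq=protein,
                product=product,
                feature_kind=kind,
                partial=partial,
            )
            contigs[feat.seqid].genes.append(gene)

    for c in contigs.values():
        c.sort_genes()
        c.validate()

    gid = genome_id or os.path.splitext(os.path.basename(str(gff_path)))[0]
    genome = AnnotatedGenome(gid, list(contigs.values()), source=source, taxon_label=taxon_label)
    genome.gene_index()  # uniqueness check
    return genome


def read_genbank(path, genome_id: str | None = None, source: str = "unknown",
                 taxon_label: str = "") -> AnnotatedGenome:
    """Read a GenBank flat file; one Contig per record.

    A CDS without a /translation qualifier is retained with an empty
    protein sequence and a warning.
    """
    contigs = []
    for record in SeqIO.parse(str(path), "genbank"):
        contig = Contig(record.id, len(record.seq), sequence=str(record.seq))
        for feat in record.features:
            if feat.type not in ("CDS", "tRNA"):
                continue
            quals = feat.qualifiers
            gene_id = (quals.get("locus_tag") or quals.get("gene") or [None])[0]
            if gene_id is None:
                raise GenomeIOError(f"{feat.type} feature without locus_tag in {record.id}")
            protein = ""
            if feat.type == "CDS":
                if "translation" in quals:
                    protein = quals["translation"][0]
                else:
                    logger.warning("CDS %s has no translation; kept empty", gene_id)
            contig.genes.append(
                Gene(
                    gene_id=gene_id,
                    contig_id=record.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand != -1 else "-",
                    protein_seq=protein,
                    product=(quals.get("product") or [""])[0],
                    feature_kind=feat.type,
                    partial="pseudo" in quals,
                )
            )
        contig.sort_genes()
        contig.validate()
        contigs.append(contig)
    gid = genome_id or os.path.splitext(os.path.basename(str(path)))[0]
    return AnnotatedGenome(gid, contigs, source=source, taxon_label=taxon_label)


# ---------------------------------------------------------------------------
# Writers


def write_gff_fasta(genome: AnnotatedGenome, gff_path, genome_fasta_path,
                    protein_fasta_path) -> None:
    """Serialize back to the GFF3 + FASTA dialect read_gff_fasta consumes."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in genome.contigs:
            fh.write(f"##sequence-region {contig.contig_id} 1 {contig.length}\n")
        for contig in genome.contigs:
            for g in contig.genes:
                attrs = f"ID={g.gene_id}"
                if g.product:
                    attrs += f";product={g.product}"
                if g.partial:
                    attrs += ";partial=true"
                fh.write(
                    "\t".join(
                        [
                            contig.contig_id,
                            "t6sscan",
                            g.feature_kind if g.feature_kind != "other" else "misc_feature",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            "0" if g.feature_kind == "CDS" else ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    with open(genome_fasta_path, "w") as fh:
        for contig in genome.contigs:
            seq = contig.sequence or ("N" * contig.length)
            fh.write(f">{contig.contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(protein_fasta_path, "w") as fh:
        for g in genome.genes():
            if g.feature_kind == "CDS" and g.protein_seq:
                fh.write(f">{g.gene_id} {g.product}\n")
                for i in range(0, len(g.protein_seq), 70):
                    fh.write(g.protein_seq[i : i + 70] + "\n")


def write_genbank(genome: AnnotatedGenome, path) -> None:
    records = []
    for contig in genome.contigs:
        seq = contig.sequence or ("N" * contig.length)
        record = SeqRecord(
            Seq(seq),
            id=contig.contig_id,
            name=contig.contig_id[:16],
            description=genome.genome_id,
            annotations={"molecule_type": "DNA"},
        )
        for g in contig.genes:
            quals = {"locus_tag": [g.gene_id]}
            if g.product:
                quals["product"] = [g.product]
            if g.feature_kind == "CDS" and g.protein_seq:
                quals["translation"] = [g.protein_seq]
            record.features.append(
                SeqFeature(
                    FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
                    type=g.feature_kind if g.feature_kind != "other" else "misc_feature",
                    qualifiers=quals,
                )
            )
        records.append(record)
    SeqIO.write(records, str(path), "genbank")


def write_reports(results, out_dir) -> list[str]:
    """Write per-cluster and genotype TSVs plus a JSON run manifest.

    All content is rendered in memory first, so an unwritable directory
    fails before any partial file is left behind.  ``results`` is a
    pipeline result bundle (see :mod:`t6sscan.pipeline`).
    """
    files: dict[str, str] = {}

    cluster_rows = [
        "\t".join(
            [
                "cluster_id", "genome_id", "contig_id", "start", "end",
                "core_count", "core_present", "accessory", "subtype",
                "truncated", "complete", "label",
            ]
        )
    ]
    for cl in getattr(results, "clusters", []):
        subtype = results.subtypes.get(cl.cluster_id) if getattr(results, "subtypes", None) else None
        cluster_rows.append(
            "\t".join(
                [
                    cl.cluster_id,
                    cl.genome_id,
                    cl.contig_id,
                    str(cl.span[0] + 1),  # serialized 1-based inclusive
                    str(cl.span[1]),
                    str(cl.core_count),
                    ",".join(sorted(cl.core_present)),
                    ",".join(f"{g}:{f}" for g, f in cl.accessory),
                    subtype.subtype if subtype else "",
                    cl.truncated,
                    str(cl.complete).lower(),
                    cl.label or "",
                ]
            )
        )
    files["clusters.tsv"] = "\n".join(cluster_rows) + "\n"

    genotype_rows = ["\t".join(["genome_id", "genotype", "archetype", "island_status"])]
    island_status = {
        isl.genome_id: isl.status for isl in getattr(results, "islands", [])
    }
    for ga in getattr(results, "genotypes", []):
        genotype_rows.append(
            "\t".join(
                [
                    ga.genome_id,
                    str(ga.genotype_index),
                    ga.archetype or "",
                    island_status.get(ga.genome_id, ""),
                ]
            )
        )
    files["genotypes.tsv"] = "\n".join(genotype_rows) + "\n"

    manifest = {
        "tool": "t6sscan",
        "config": getattr(results, "config_dict", {}),
        "seed": getattr(results, "seed", None),
        "n_genomes": len(getattr(results, "genome_ids", [])),
        "files": sorted(files),
    }
    files["manifest.json"] = json.dumps(manifest, indent=2, sort_keys=True) + "\n"

    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise GenomeIOError(f"output directory not writable: {out_dir}")
    written = []
    for name, content in sorted(files.items()):
        p = os.path.join(out_dir, name)
        with open(p, "w") as fh:
            fh.write(content)
        written.append(p)
    return written
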