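"""Shared fixtures: synthetic panels and tiny hand-built genomes."""

from __future__ import annotations

import pytest

from t6sscan import RunConfig, SynthConfig, generate_genome_set, run_all
from t6sscan.family_assign import CORE_FAMILIES, FamilyMap
from t6sscan.genome_io import AnnotatedGenome, Contig, Gene

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_set(tmp_path_factory):
    """The default synthetic panel (34 vibrio-like + 9 roseobacter-like
    genomes, seed 1), generated once per session."""
    out = tmp_path_factory.mktemp("synth_default")
    truth = generate_genome_set(SynthConfig(seed=DEFAULT_SEED), out)
    return out, truth


@pytest.fixture(scope="session")
def default_run(default_set, tmp_path_factory):
    """Full pipeline result over the default panel."""
    in_dir, truth = default_set
    out_dir = tmp_path_factory.mktemp("run_default")
    config = RunConfig(input_dir=str(in_dir), out_dir=str(out_dir),
                       seed=DEFAULT_SEED)
    result = run_all(config)
    return result, truth, config


def contig_from_families(tokens, contig_id="c1", gene_len=300):
    """A contig plus family map from a token list (non-core tokens are
    treated as unlabeled filler)."""
    genes = []
    core = {}
    for i, token in enumerate(tokens):
        gid = f"g{i:03d}"
        start = 100 + i * (gene_len + 50)
        genes.append(Gene(gid, contig_id, start, start + gene_len, "+",
                          protein_seq="M" * 99, product=token))
        if token in CORE_FAMILIES:
            core[gid] = token
    contig = Contig(contig_id, genes[-1].end + 200 if genes else 1000, genes)
    return contig, FamilyMap(core=core)


def single_contig_genome(tokens, genome_id="G", **kwargs):
    contig, fam_map = contig_from_families(tokens, **kwargs)
    return AnnotatedGenome(genome_id, [contig]), fam_map
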