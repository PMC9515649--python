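"""Cluster-calling rules: core-count and spacing, against a window oracle."""

import itertools

import numpy as np
import pytest

from t6sscan.cluster_detect import (classify_completeness, label_known_systems,
                                    scan_contig)
from t6sscan.family_assign import CORE_FAMILIES

from conftest import contig_from_families, single_contig_genome


def oracle_spans(tokens, min_core=4, max_gap=10):
    """Independent cluster finder: enumerate all core-index windows,
    keep spacing-valid, non-extendable ones with enough distinct
    families.  Returns (first, last) gene-index spans."""
    core_pos = [i for i, t in enumerate(tokens) if t in CORE_FAMILIES]
    spans = []
    for a in range(len(core_pos)):
        for b in range(a, len(core_pos)):
            window = core_pos[a : b + 1]
            if any(q - p - 1 > max_gap for p, q in zip(window, window[1:])):
                continue
            if a > 0 and core_pos[a] - core_pos[a - 1] - 1 <= max_gap:
                continue  # extendable left
            if b < len(core_pos) - 1 and core_pos[b + 1] - core_pos[b] - 1 <= max_gap:
                continue  # extendable right
            if len({tokens[i] for i in window}) >= min_core:
                spans.append((window[0], window[-1]))
    return sorted(spans)


def detected_spans(tokens, min_core=4, max_gap=10):
    contig, fam_map = contig_from_families(tokens)
    gene_pos = {g.gene_id: i for i, g in enumerate(contig.genes)}
    out = []
    for cl in scan_contig(contig, fam_map, min_core=min_core, max_gap=max_gap):
        out.append((gene_pos[cl.gene_ids[0]], gene_pos[cl.gene_ids[-1]]))
    return sorted(out)


def test_four_distinct_core_families_called_three_not():
    """Retention at exactly four of the 13 core genes."""
    tokens = ["tssB", "x", "tssC", "x", "tssK", "tssL"]
    contig, fam_map = contig_from_families(tokens)
    clusters = scan_contig(contig, fam_map)
    assert len(clusters) == 1
    assert clusters[0].core_present == frozenset({"tssB", "tssC", "tssK", "tssL"})
    assert clusters[0].core_count == 4

    clusters = scan_contig(*contig_from_families(["tssB", "x", "tssC", "x", "tssK"]))
    assert clusters == []


def test_gap_of_ten_merges_eleven_splits():
    merged = ["tssB"] + ["x"] * 10 + ["tssC", "tssK", "tssL"]
    assert len(detected_spans(merged)) == 1
    split = ["tssB"] + ["x"] * 11 + ["tssC", "tssK", "tssL"]
    assert detected_spans(split) == []


def test_tandem_copies_never_satisfy_min_core():
    """Distinct families, not gene copies, satisfy the count — a tandem
    array (e.g. an Hcp run) must not trigger a call."""
    assert detected_spans(["tssB", "tssB", "tssC", "tssK"]) == []
    assert detected_spans(["tssD"] * 12, min_core=2) == []


@pytest.mark.parametrize("min_core,max_gap", [(2, 0), (2, 1), (3, 2)])
def test_exhaustive_oracle_agreement_short_strings(min_core, max_gap):
    """Exhaustive agreement with the window oracle over all strings of
    length <= 7 from a 4-token alphabet (3 core families + filler)."""
    alphabet = ["tssA", "tssB", "tssC", "x"]
    for n in range(1, 8):
        for tokens in itertools.product(alphabet, repeat=n):
            tokens = list(tokens)
            assert detected_spans(tokens, min_core, max_gap) == oracle_spans(
                tokens, min_core, max_gap
            ), tokens


def test_oracle_agreement_sampled_long_strings():
    """Seeded sample of longer strings, including default thresholds."""
    rng = np.random.default_rng(123)
    alphabet = ["tssA", "tssB", "tssC", "tssD", "tssK", "x"]
    for _ in range(2000):
        n = int(rng.integers(8, 16))
        tokens = [alphabet[i] for i in rng.integers(0, len(alphabet), size=n)]
        for min_core, max_gap in ((2, 1), (4, 10), (3, 3)):
            assert detected_spans(tokens, min_core, max_gap) == oracle_spans(
                tokens, min_core, max_gap
            ), (tokens, min_core, max_gap)


def test_monotonicity_in_thresholds():
    rng = np.random.default_rng(5)
    alphabet = ["tssA", "tssB", "tssC", "tssE", "x"]
    for _ in range(200):
        tokens = [alphabet[i] for i in rng.integers(0, 5, size=int(rng.integers(4, 14)))]
        counts_by_min = [len(detected_spans(tokens, mc, 2)) for mc in (2, 3, 4)]
        assert counts_by_min == sorted(counts_by_min, reverse=True)
        # widening the gap allowance can merge clusters (fewer calls) but
        # every called span stays contained in a span called at the wider gap
        for g_small, g_big in ((0, 1), (1, 3)):
            small = detected_spans(tokens, 2, g_small)
            big = detected_spans(tokens, 2, g_big)
            for a, b in small:
                assert any(a2 <= a and b <= b2 for a2, b2 in big)


def test_reversal_symmetry():
    rng = np.random.default_rng(9)
    alphabet = ["tssA", "tssB", "tssC", "tssK", "x"]
    for _ in range(200):
        tokens = [alphabet[i] for i in rng.integers(0, 5, size=int(rng.integers(3, 12)))]
        fwd = detected_spans(tokens, 2, 1)
        n = len(tokens)
        rev = sorted((n - 1 - b, n - 1 - a) for a, b in
                     detected_spans(tokens[::-1], 2, 1))
        assert fwd == rev


def test_clusters_disjoint_and_ordered():
    tokens = (["tssA", "tssB", "tssC", "tssD"] + ["x"] * 11
              + ["tssE", "tssF", "tssG", "tssH"])
    spans = detected_spans(tokens)
    assert spans == [(0, 3), (15, 18)]


def test_completeness_record_missing_families():
    """An 11/13 cluster missing tssD and tssI (the Hcp tube and VgrG
    spike genes, typically encoded in auxiliary clusters)."""
    pad = ["x"] * 12
    tokens = pad + [f for f in CORE_FAMILIES if f not in ("tssD", "tssI")] + pad
    contig, fam_map = contig_from_families(tokens)
    cl = scan_contig(contig, fam_map)[0]
    record = classify_completeness(cl)
    assert record.missing == ("tssD", "tssI")
    assert not record.complete
    assert record.cause == "genuinely_absent"

    contig, fam_map = contig_from_families(list(CORE_FAMILIES))
    record = classify_completeness(scan_contig(contig, fam_map)[0])
    assert record.complete and record.missing == ()
    assert record.cause is None


def test_truncation_at_contig_edge():
    """An incomplete cluster ending at a contig edge is attributed to
    the assembly break."""
    tokens = ["x"] * 12 + list(CORE_FAMILIES[:9])  # ends at the contig end
    contig, fam_map = contig_from_families(tokens)
    cl = scan_contig(contig, fam_map)[0]
    assert cl.truncated == "right"
    assert classify_completeness(cl).cause == "truncated_assembly"
    # interior incomplete cluster: genuinely absent
    tokens = ["x"] * 12 + list(CORE_FAMILIES[:9]) + ["x"] * 12
    cl = scan_contig(*contig_from_families(tokens))[0]
    assert cl.truncated == "none"


def test_label_by_replicon_and_ordinals():
    genome, fam_map = single_contig_genome(list(CORE_FAMILIES))
    clusters = scan_contig(genome.contigs[0], fam_map, genome_id="G")
    labeled = label_known_systems(clusters, genome,
                                  replicon_map={"c1": "chromosome2"})
    assert labeled[0].label == "T6SS2"

    tokens = list(CORE_FAMILIES) + ["x"] * 11 + list(CORE_FAMILIES)
    genome, fam_map = single_contig_genome(tokens)
    clusters = scan_contig(genome.contigs[0], fam_map, genome_id="G")
    labeled = label_known_systems(clusters, genome,
                                  replicon_map={"c1": "chromosome1"})
    assert [c.label for c in labeled] == ["T6SS1.1", "T6SS1.2"]


def test_label_conflict_demotes_to_unlabeled():
    genome, fam_map = single_contig_genome(list(CORE_FAMILIES))
    clusters = scan_contig(genome.contigs[0], fam_map, genome_id="G")
    labeled = label_known_systems(
        clusters, genome, replicon_map={"c1": "chromosome1"},
        subtype_labels={clusters[0].cluster_id: "T6SS2"})
    assert labeled[0].label == "unlabeled"
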