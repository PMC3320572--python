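"""Evidence graph accumulation, JCV scoring, thresholds, fusion classification."""

import math

import pytest
from scipy.special import gammainc

from sasrfuse.evidence import (
    EvidenceEdge,
    EvidenceGraph,
    accumulate_evidence,
    build_candidates,
    call_junctions,
    classify_fusion,
    compute_jcv,
    count_unique_starts,
)
from sasrfuse.mapping import AlignmentRecord, PairedAlignment
from sasrfuse.sasr import SplicedHit

from conftest import make_model


def _aln(read_id, pos, chrom="chr1", strand="+", length=50):
    return AlignmentRecord(read_id=read_id, mate=1, ref_name=chrom, pos=pos,
                           strand=strand, length=length, matches=length,
                           mismatches=0, score=length, reference_class="genome")


def _pair(read_id, fwd_pos, rev_pos, pqv, fwd_chrom="chr1", rev_chrom="chr1"):
    return PairedAlignment(fwd=_aln(read_id, fwd_pos, fwd_chrom),
                           rev=_aln(read_id, rev_pos, rev_chrom, "-", 25),
                           insert_size=0, pqv=pqv, primary=True)


@pytest.fixture
def two_gene_model():
    return make_model([
        ("gA", "chr1", "+", [(100, 300), (500, 700)]),
        ("gB", "chr2", "+", [(100, 300), (500, 700)]),
    ], seed=30)


def _span(donor, acceptor, read_id, prefix=20):
    return SplicedHit(donor_exon_id=donor, acceptor_exon_id=acceptor,
                      prefix_len=prefix, suffix_len=30 - prefix + 20,
                      clipped_left=0, clipped_right=0, mismatches_total=0,
                      read_id=read_id)


def test_fig1a_scenario_counts_four_spans_three_bridges(two_gene_model):
    """Four spanning reads and three bridging pairs on one exon pair."""
    spans = [_span("gA-1", "gB-1", f"s{i}", prefix=15 + i) for i in range(4)]
    pairs = [_pair(f"b{i}", 150 + 10 * i, 150, 40, rev_chrom="chr2")
             for i in range(3)]
    graph = accumulate_evidence(spans, pairs, two_gene_model)
    cands = build_candidates(graph, {}, total_pairs=100)
    cand = next(c for c in cands if (c.donor_exon_id, c.acceptor_exon_id)
                == ("gA-1", "gB-1"))
    assert cand.span_count == 4 and cand.bridge_count == 3
    assert cand.span_unique_starts == 4 and cand.bridge_unique_starts == 3
    assert not cand.same_gene


def test_bridge_pqv_boundary_strictly_greater_than_ten(two_gene_model):
    at_threshold = [_pair("b1", 150, 150, 10, rev_chrom="chr2")]
    above = [_pair("b2", 160, 150, 11, rev_chrom="chr2")]
    graph = accumulate_evidence([], at_threshold + above, two_gene_model)
    edges = graph.bridge_edges[("gA-1", "gB-1")]
    assert [e.read_id for e in edges] == ["b2"]


def test_ambiguous_overlapping_gene_evidence_is_dropped():
    model = make_model([
        ("gA", "chr1", "+", [(100, 300), (500, 700)]),
        ("gOverlap", "chr1", "+", [(150, 350), (500, 700)]),
        ("gB", "chr2", "+", [(100, 300)]),
    ], seed=31)
    # fwd mate falls where gA and gOverlap exons overlap -> ambiguous
    pairs = [_pair("b1", 200, 150, 40, rev_chrom="chr2")]
    graph = accumulate_evidence([], pairs, model)
    assert graph.bridge_edges == {}
    assert graph.n_ambiguous == 1


def test_count_unique_starts():
    def edge(kind, start):
        return EvidenceEdge("x", "y", kind, "r", start, 40)

    edges = [edge("SPAN", 100)] * 5
    assert count_unique_starts(edges) == (1, 0)
    edges = [edge("SPAN", s) for s in (100, 101, 101, 102)]
    assert count_unique_starts(edges) == (3, 0)
    assert count_unique_starts([]) == (0, 0)


# -- JCV ----------------------------------------------------------------

def _bridges(n, pqv):
    return [EvidenceEdge("x", "y", "BRIDGE", f"r{i}", i, pqv) for i in range(n)]


def test_jcv_zero_without_bridges_or_pairs():
    assert compute_jcv([], {}, 1000, 1e-3) == 0
    assert compute_jcv(_bridges(2, 40), {}, 0, 1e-3) == 0


def test_jcv_closed_form_example():
    # two pqv-40 edges (k_eff ~ 2) against lambda = 1e-3*1000*1000/1e6 = 0.001:
    # Poisson upper tail ~ lambda^2/2 = 5e-7, phred 63
    jcv = compute_jcv(_bridges(2, 40), {"x": 1000, "y": 1000}, 1_000_000, 1e-3)
    k_eff = 2 * (1 - 10 ** -4.0)
    assert jcv == round(-10 * math.log10(gammainc(k_eff, 1e-3))) == 63


def test_jcv_caps_at_hundred():
    jcv = compute_jcv(_bridges(10, 40), {"x": 1, "y": 1}, 1_000_000, 1e-3)
    assert jcv == 100


def test_jcv_monotone_in_evidence_and_antimonotone_in_background():
    counts = {"x": 2000, "y": 2000}
    jcvs = [compute_jcv(_bridges(k, 30), counts, 1_000_000, 1e-3)
            for k in range(1, 6)]
    assert jcvs == sorted(jcvs)
    lams = [compute_jcv(_bridges(2, 30), {"x": r, "y": r}, 1_000_000, 1e-3)
            for r in (100, 1000, 5000, 20000, 60000)]
    assert lams == sorted(lams, reverse=True)


# -- calling ------------------------------------------------------------

def _graph_with(model, donor, acceptor, n_span, n_bridge, pqv=40):
    graph = EvidenceGraph(model)
    for i in range(n_span):
        graph.add_span(donor, acceptor, f"s{i}", 100 + i)
    for i in range(n_bridge):
        graph.add_bridge(donor, acceptor, f"b{i}", 200 + 5 * i, pqv)
    return graph


def test_same_gene_threshold_one_and_one(two_gene_model):
    graph = _graph_with(two_gene_model, "gA-1", "gA-2", 1, 1)
    cands = build_candidates(graph, {}, 100)
    junctions, fusions = call_junctions(cands, two_gene_model)
    assert len(junctions) == 1 and fusions == []


@pytest.mark.parametrize("n_span,n_bridge,called", [
    (1, 1, False), (2, 1, False), (1, 2, False), (2, 2, True),
])
def test_fusion_threshold_two_and_two(two_gene_model, n_span, n_bridge, called):
    graph = _graph_with(two_gene_model, "gA-1", "gB-1", n_span, n_bridge)
    cands = build_candidates(graph, {}, 100)
    _, fusions = call_junctions(cands, two_gene_model)
    assert bool(fusions) == called
    if called:
        f = fusions[0]
        assert f.candidate.span_unique_starts >= 2
        assert f.candidate.bridge_unique_starts >= 2


def test_call_sets_nest_across_thresholds(two_gene_model):
    graphs = [_graph_with(two_gene_model, "gA-1", "gB-1", ns, nb)
              for ns, nb in [(1, 0), (2, 0), (2, 2), (3, 3)]]
    all_cands = []
    for g in graphs:
        all_cands.extend(build_candidates(g, {}, 100))
    # merge candidates keyed by evidence level into one pool per threshold run
    def fusion_set(fusion_min):
        _, fusions = call_junctions(all_cands, two_gene_model,
                                    fusion_min=fusion_min)
        return {id(f.candidate) for f in fusions}

    one_sr = fusion_set((1, 0))
    two_sr = fusion_set((2, 0))
    two_sr_two_pe = fusion_set((2, 2))
    assert two_sr_two_pe <= two_sr <= one_sr
    assert len(one_sr) > len(two_sr) > len(two_sr_two_pe)


def test_classification_rules():
    model = make_model([
        ("g1", "chr20", "+", [(100, 200), (400, 500)]),
        ("g2", "chr17", "+", [(100, 200), (400, 500)]),
        ("g3", "chr20", "-", [(1000, 1100), (1300, 1400)]),
        ("g4", "chr20", "+", [(5000, 5100), (5300, 5400)]),
    ], seed=32)

    def call_for(donor, acceptor):
        graph = _graph_with(model, donor, acceptor, 2, 2)
        cands = build_candidates(graph, {}, 100)
        return classify_fusion(cands[0], model)

    inter = call_for("g1-1", "g2-1")
    assert inter.classification == "inter-chromosomal"
    assert inter.signed_distance is None

    inverted = call_for("g1-1", "g3-1")
    assert inverted.classification == "inverted"

    same = call_for("g1-1", "g4-2")
    assert same.classification == "same-strand"
    # donor 3' boundary at 200, acceptor 5' boundary at 5300, downstream
    assert same.signed_distance == 5100


def test_signed_distance_negative_when_acceptor_upstream():
    # acceptor partner lies upstream of the donor in transcription order,
    # like the ESR1->C6orf97 reverse-order fusion geometry
    model = make_model([
        ("gDown", "chr6", "+", [(50_000, 50_200), (51_000, 51_200)]),
        ("gUp", "chr6", "+", [(10_000, 10_200), (11_000, 11_200)]),
    ], seed=33)
    graph = _graph_with(model, "gDown-1", "gUp-2", 2, 2)
    cand = build_candidates(graph, {}, 100)[0]
    call = classify_fusion(cand, model)
    assert call.classification == "same-strand"
    assert call.signed_distance == 11_000 - 50_200  # negative


def test_minus_strand_signed_distance_uses_transcription_direction():
    model = make_model([
        ("gM1", "chr1", "-", [(20_000, 20_200), (21_000, 21_200)]),
        ("gM2", "chr1", "-", [(5_000, 5_200), (6_000, 6_200)]),
    ], seed=34)
    graph = _graph_with(model, "gM1-1", "gM2-1", 2, 2)
    call = classify_fusion(build_candidates(graph, {}, 100)[0], model)
    # donor 3' boundary 21000 (rank-1 exon is the high-coordinate one), acceptor
    # 5' start 6200; genomic delta 6200-21000 = -14800, flipped on minus strand
    assert call.signed_distance == 14_800


def test_jcv_min_filter_applies_after_thresholds(two_gene_model):
    strong = _graph_with(two_gene_model, "gA-1", "gB-1", 3, 3, pqv=40)
    weak = _graph_with(two_gene_model, "gA-2", "gB-2", 3, 3, pqv=12)
    cands = (build_candidates(strong, {"gA-1": 10, "gB-1": 10}, 1_000_000)
             + build_candidates(weak, {"gA-2": 50_000, "gB-2": 50_000}, 1_000_000))
    _, no_filter = call_junctions(cands, two_gene_model)
    _, filtered = call_junctions(cands, two_gene_model, jcv_min=50)
    assert len(no_filter) == 2 and len(filtered) == 1
    assert filtered[0].candidate.donor_exon_id == "gA-1"
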