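"""SPAN/BRIDGE junction evidence graph, Junction Confidence Values, and
junction/fusion calling.

Exons are nodes of a sparse directed graph.  A SPAN edge is a single read
whose alignment crosses the candidate breakpoint (junction-reference mapped
or SASR-discovered); a BRIDGE edge is a read pair whose mates map to two
different exons with PQV above a confidence threshold (strictly > 10 by
default).  Candidates are called from unique-start-point evidence counts:
one of each type for same-gene junctions, two of each for fusions.

The Junction Confidence Value (JCV, 0..100) compares the quantity and
quality of BRIDGE evidence against an expression-driven random-mispairing
null: the pqv-weighted evidence mass is tested against the upper tail of a
Poisson whose rate is proportional to the product of the two exons' read
counts and a global mispairing rate.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from scipy.special import gammainc

from sasrfuse.genemodel import GeneModel
from sasrfuse.mapping import PairedAlignment
from sasrfuse.sasr import SplicedHit

SPAN = "SPAN"
BRIDGE = "BRIDGE"


@dataclass(frozen=True)
class EvidenceEdge:
    donor_exon_id: str
    acceptor_exon_id: str
    kind: str  # SPAN or BRIDGE
    read_id: str
    start_point: int  # leftmost aligned coordinate of the evidencing read
    pqv: int


@dataclass
class JunctionCandidate:
    donor_exon_id: str
    acceptor_exon_id: str
    span_count: int = 0
    bridge_count: int = 0
    span_unique_starts: int = 0
    bridge_unique_starts: int = 0
    jcv: int = 0
    same_gene: bool = False
    bridge_edges: List[EvidenceEdge] = field(default_factory=list)
    alternative: bool = False


@dataclass
class FusionCall:
    candidate: JunctionCandidate
    five_prime_gene: str
    three_prime_gene: str
    classification: str  # inter-chromosomal | inverted | same-strand
    signed_distance: Optional[int] = None
    in_frame: Optional[bool] = None


class EvidenceGraph:
    """Sparse directed exon graph holding SPAN and BRIDGE edges per exon pair."""

    def __init__(self, model: GeneModel):
        self.model = model
        self.span_edges: Dict[Tuple[str, str], List[EvidenceEdge]] = defaultdict(list)
        self.bridge_edges: Dict[Tuple[str, str], List[EvidenceEdge]] = defaultdict(list)
        self.n_ambiguous = 0

    def add_span(self, donor: str, acceptor: str, read_id: str,
                 start_point: int, pqv: int = 40) -> None:
        self.span_edges[(donor, acceptor)].append(EvidenceEdge(
            donor, acceptor, SPAN, read_id, start_point, pqv))

    def add_bridge(self, donor: str, acceptor: str, read_id: str,
                   start_point: int, pqv: int) -> None:
        self.bridge_edges[(donor, acceptor)].append(EvidenceEdge(
            donor, acceptor, BRIDGE, read_id, start_point, pqv))


def span_hit_start_point(hit: SplicedHit) -> int:
    """Uniqueness key for a SPAN evidence: how far the read start sits from
    the donor boundary (duplicate fragments share it)."""
    return hit.prefix_len + hit.clipped_left


def accumulate_evidence(span_hits: Sequence[SplicedHit],
                        paired: Sequence[PairedAlignment],
                        model: GeneModel,
                        bridge_pqv_min: int = 10,
                        exon_assigner=None) -> EvidenceGraph:
    """Build the evidence graph from spliced hits and confident read pairs.

    ``exon_assigner(alignment) -> exon_id | None | "ambiguous"`` maps a
    mate's alignment onto an exon; pairs with an ambiguous assignment
    (overlapping gene annotations) contribute to no candidate.  BRIDGE
    edges require pqv strictly greater than ``bridge_pqv_min``.
    """
    graph = EvidenceGraph(model)
    for h in span_hits:
        pqv = max(0, 40 - 10 * h.mismatches_total)
        graph.add_span(h.donor_exon_id, h.acceptor_exon_id, h.read_id,
                       span_hit_start_point(h), pqv)
    if exon_assigner is None:
        exon_assigner = make_genomic_exon_assigner(model)
    for p in paired:
        if not p.primary or p.pqv <= bridge_pqv_min:
            continue
        ex_f = exon_assigner(p.fwd)
        ex_r = exon_assigner(p.rev)
        if ex_f == "ambiguous" or ex_r == "ambiguous":
            graph.n_ambiguous += 1
            continue
        if ex_f is None or ex_r is None or ex_f == ex_r:
            continue
        graph.add_bridge(ex_f, ex_r, p.fwd.read_id, p.fwd.pos, p.pqv)
    return graph


def make_genomic_exon_assigner(model: GeneModel):
    """Assign a genome-coordinate alignment to an exon.

    Returns the exon id when the alignment overlaps exons of exactly one
    gene (preferring an exon that fully contains it), "ambiguous" when it
    overlaps exons of several genes, None when intergenic.
    """

    def assigner(aln) -> Optional[str]:
        if aln.reference_class != "genome":
            return None
        start, end = aln.pos, aln.pos + aln.length
        exons = model.exons_overlapping(aln.ref_name, start, end)
        if not exons:
            return None
        genes = {e.gene_id for e in exons}
        if len(genes) > 1:
            return "ambiguous"
        containing = [e for e in exons if e.start <= start and end <= e.end]
        pool = containing or exons
        best = max(pool, key=lambda e: (min(end, e.end) - max(start, e.start),
                                        -e.length, e.exon_id))
        return best.exon_id

    return assigner


def count_unique_starts(edges: Iterable[EvidenceEdge]) -> Tuple[int, int]:
    """(span_unique, bridge_unique): distinct start points per evidence kind."""
    span_starts = {e.start_point for e in edges if e.kind == SPAN}
    bridge_starts = {e.start_point for e in edges if e.kind == BRIDGE}
    return len(span_starts), len(bridge_starts)


def compute_jcv(bridge_edges: Sequence[EvidenceEdge],
                exon_read_counts: Mapping[str, int],
                total_pairs: int,
                mispair_rate: float,
                donor_exon_id: Optional[str] = None,
                acceptor_exon_id: Optional[str] = None) -> int:
    """Junction Confidence Value from BRIDGE quantity and quality.

    Effective evidence k_eff = sum over edges of (1 - 10^(-pqv/10)); the
    null rate is lambda = max(1e-6, rho * r_X * r_Y / total_pairs) where
    r_X, r_Y are the two exons' confident read counts and rho is the
    global random-mispairing rate.  p_null = P(Poisson(lambda) >= k_eff)
    (regularized lower incomplete gamma in k_eff); JCV is the phred of
    p_null clamped to [0, 100].
    """
    if total_pairs <= 0 or not bridge_edges:
        return 0
    k_eff = sum(1.0 - 10.0 ** (-e.pqv / 10.0) for e in bridge_edges)
    if k_eff <= 0.0:
        return 0
    donor = donor_exon_id or bridge_edges[0].donor_exon_id
    acceptor = acceptor_exon_id or bridge_edges[0].acceptor_exon_id
    r_x = exon_read_counts.get(donor, 0)
    r_y = exon_read_counts.get(acceptor, 0)
    lam = max(1e-6, mispair_rate * r_x * r_y / total_pairs)
    p_null = float(gammainc(k_eff, lam))  # upper tail of Poisson(lam) at k_eff
    if p_null <= 0.0:
        return 100
    return max(0, min(100, round(-10.0 * math.log10(p_null))))


def _compatible_bridges(graph: EvidenceGraph, donor_id: str,
                        acceptor_id: str) -> List[EvidenceEdge]:
    """Bridge edges supporting the junction (donor, acceptor): fwd mate in
    the donor gene at or upstream of the donor exon, rev mate in the
    acceptor gene at or downstream of the acceptor exon (Fig-1A geometry)."""
    model = graph.model
    d = model.exon(donor_id)
    a = model.exon(acceptor_id)
    out: List[EvidenceEdge] = []
    for (bd, ba), edges in graph.bridge_edges.items():
        ebd = model.exon(bd)
        eba = model.exon(ba)
        if ebd.gene_id != d.gene_id or eba.gene_id != a.gene_id:
            continue
        if ebd.rank <= d.rank and eba.rank >= a.rank:
            out.extend(edges)
    return out


def build_candidates(graph: EvidenceGraph,
                     exon_read_counts: Optional[Mapping[str, int]] = None,
                     total_pairs: int = 0,
                     mispair_rate: float = 1e-3) -> List[JunctionCandidate]:
    """One JunctionCandidate per exon pair carrying SPAN evidence, with
    aggregated compatible BRIDGE support and a JCV."""
    model = graph.model
    exon_read_counts = exon_read_counts or {}
    out: List[JunctionCandidate] = []
    for (donor, acceptor) in sorted(graph.span_edges):
        spans = graph.span_edges[(donor, acceptor)]
        bridges = _compatible_bridges(graph, donor, acceptor)
        span_u, _ = count_unique_starts(spans)
        _, bridge_u = count_unique_starts(bridges)
        cand = JunctionCandidate(
            donor_exon_id=donor, acceptor_exon_id=acceptor,
            span_count=len(spans), bridge_count=len(bridges),
            span_unique_starts=span_u, bridge_unique_starts=bridge_u,
            same_gene=(model.exon(donor).gene_id == model.exon(acceptor).gene_id),
            bridge_edges=bridges,
        )
        cand.jcv = compute_jcv(bridges, exon_read_counts, total_pairs,
                               mispair_rate, donor, acceptor)
        out.append(cand)
    return out


def _flag_alternative_splices(calls: List[JunctionCandidate], model: GeneModel) -> None:
    """Mark alternative donor/acceptor usage when >= 2 alternatives share a
    boundary (partially overlapping exon handling)."""
    by_donor: Dict[Tuple, List[JunctionCandidate]] = defaultdict(list)
    by_acceptor: Dict[Tuple, List[JunctionCandidate]] = defaultdict(list)
    for c in calls:
        d = model.exon(c.donor_exon_id)
        a = model.exon(c.acceptor_exon_id)
        by_donor[(d.chrom, d.strand, d.donor_coord)].append(c)
        by_acceptor[(a.chrom, a.strand, a.acceptor_coord)].append(c)
    for group in list(by_donor.values()) + list(by_acceptor.values()):
        partners = {(g.donor_exon_id, g.acceptor_exon_id) for g in group}
        if len(partners) >= 2:
            for g in group:
                g.alternative = True


def call_junctions(candidates: Sequence[JunctionCandidate],
                   model: GeneModel,
                   same_gene_min: Tuple[int, int] = (1, 1),
                   fusion_min: Tuple[int, int] = (2, 2),
                   jcv_min: Optional[int] = None,
                   ) -> Tuple[List[JunctionCandidate], List[FusionCall]]:
    """Threshold candidates into same-gene junction calls and fusion calls.

    Thresholds are (min unique-start SPAN, min unique-start BRIDGE): the
    defaults are 1-SR-1-PE for same-gene junctions and 2-SR-2-PE for
    fusions.  ``jcv_min`` optionally filters both call sets afterwards.
    """
    junctions: List[JunctionCandidate] = []
    fusions: List[FusionCall] = []
    for c in candidates:
        if c.same_gene:
            if (c.span_unique_starts >= same_gene_min[0]
                    and c.bridge_unique_starts >= same_gene_min[1]):
                junctions.append(c)
        else:
            if (c.span_unique_starts >= fusion_min[0]
                    and c.bridge_unique_starts >= fusion_min[1]):
                fusions.append(classify_fusion(c, model))
    if jcv_min is not None:
        junctions = [c for c in junctions if c.jcv >= jcv_min]
        fusions = [f for f in fusions if f.candidate.jcv >= jcv_min]
    _flag_alternative_splices(junctions, model)
    return junctions, fusions


def classify_fusion(candidate: JunctionCandidate, model: GeneModel) -> FusionCall:
    """Classify a different-gene candidate.

    inter-chromosomal: partner genes on different chromosomes; inverted:
    same chromosome, opposite strands; same-strand otherwise, with a signed
    genomic distance from the donor exon's 3' boundary to the acceptor
    exon's 5' boundary, measured along the donor gene's transcription
    direction (negative when the acceptor partner lies upstream).
    """
    d = model.exon(candidate.donor_exon_id)
    a = model.exon(candidate.acceptor_exon_id)
    call = FusionCall(candidate=candidate, five_prime_gene=d.gene_id,
                      three_prime_gene=a.gene_id, classification="same-strand")
    if d.chrom != a.chrom:
        call.classification = "inter-chromosomal"
    elif d.strand != a.strand:
        call.classification = "inverted"
    else:
        dist = a.acceptor_coord - d.donor_coord
        call.signed_distance = dist if d.strand == "+" else -dist
    return call
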