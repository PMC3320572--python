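"""End-to-end fusion-discovery pipeline: reference construction, mapping,
filter subtraction, mate rescue, pairing, SASR on admitted reads, evidence
accumulation, and junction/fusion calling.

Alignments to the exon and junction references are projected back to genome
coordinates and merged with direct genomic alignments into a single set per
read before pairing, so equivalent placements found through different
references do not compete in the pairing posterior.  Junction-crossing
alignments cannot be projected and stay in junction coordinates; they
become SPAN evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from sasrfuse.evidence import (
    EvidenceGraph,
    FusionCall,
    JunctionCandidate,
    accumulate_evidence,
    build_candidates,
    call_junctions,
    make_genomic_exon_assigner,
)
from sasrfuse.genemodel import (
    GeneModel,
    JunctionReferenceEntry,
    build_junction_reference,
)
from sasrfuse.mapping import (
    AlignmentRecord,
    InsertModel,
    PairedAlignment,
    ReferenceSet,
    map_read_simple,
    pair_and_score,
    rescue_mate,
)
from sasrfuse.sasr import ReadRecord, SplicedHit, admit_read, resolve_unique_junction, sasr_map_read
from sasrfuse.suffix_index import SasrIndex, build_index

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Operating point of the pipeline.

    Defaults: decamer anchors, at most two extension mismatches, at most
    ten clipped bases, BRIDGE confidence PQV > 10, 1-SR-1-PE same-gene
    junction threshold, 2-SR-2-PE fusion threshold.
    """

    anchor_len: int = 10
    min_suffix_len: int = 10
    max_suffix_len: Optional[int] = None  # default: longest read - anchor_len
    max_mismatches: int = 2
    max_clip: int = 10
    bridge_pqv_min: int = 10
    admission_pqv_max: int = 10
    same_gene_min: Tuple[int, int] = (1, 1)
    fusion_min: Tuple[int, int] = (2, 2)
    jcv_min: Optional[int] = None
    insert_mean: float = 150.0
    insert_sd: float = 25.0
    flank_len: Optional[int] = None  # default: longest read - anchor_len
    filter_min_score: int = 25
    mispair_rate: float = 1e-3
    min_junction_overhang: int = 10
    seed: int = 0


@dataclass
class PipelineResult:
    model: GeneModel
    paired: List[PairedAlignment]
    span_hits: List[SplicedHit]
    candidates: List[JunctionCandidate]
    junction_calls: List[JunctionCandidate]
    fusion_calls: List[FusionCall]
    counts: Dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------
# Coordinate projection
# ---------------------------------------------------------------------

def _project_exon(aln: AlignmentRecord, model: GeneModel) -> AlignmentRecord:
    e = model.exon(aln.ref_name)
    if e.strand == "+":
        pos = e.start + aln.pos
        strand = aln.strand
    else:
        pos = e.end - aln.pos - aln.length
        strand = "-" if aln.strand == "+" else "+"
    return replace(aln, ref_name=e.chrom, pos=pos, strand=strand,
                   reference_class="genome")


def project_to_genome(aln: AlignmentRecord, model: GeneModel,
                      junction_entries: Mapping[str, JunctionReferenceEntry]
                      ) -> Optional[AlignmentRecord]:
    """Genome-coordinate version of an exon/junction alignment, or None for
    junction-crossing alignments (no single genomic interval)."""
    if aln.reference_class == "genome":
        return aln
    if aln.reference_class == "exon":
        return _project_exon(aln, model)
    if aln.reference_class == "junction":
        entry = junction_entries[aln.ref_name]
        dflank = entry.donor_flank_len
        if aln.pos + aln.length <= dflank:  # entirely in the donor flank
            e = model.exon(entry.donor_exon_id)
            off = e.length - dflank + aln.pos
            return _project_exon(replace(aln, ref_name=e.exon_id, pos=off,
                                         reference_class="exon"), model)
        if aln.pos >= dflank:  # entirely in the acceptor flank
            e = model.exon(entry.acceptor_exon_id)
            off = aln.pos - dflank
            return _project_exon(replace(aln, ref_name=e.exon_id, pos=off,
                                         reference_class="exon"), model)
        return None
    return None


def _merge_alignments(alignments: Sequence[AlignmentRecord], model: GeneModel,
                      junction_entries: Mapping[str, JunctionReferenceEntry]
                      ) -> List[AlignmentRecord]:
    """Project to genome coordinates where possible and deduplicate
    equivalent placements, keeping the best score per placement."""
    best: Dict[Tuple, AlignmentRecord] = {}
    for aln in alignments:
        proj = project_to_genome(aln, model, junction_entries)
        rec = proj if proj is not None else aln
        key = (rec.reference_class, rec.ref_name, rec.pos, rec.strand)
        if key not in best or rec.score > best[key].score:
            best[key] = rec
    return sorted(best.values(), key=lambda a: (-a.score, a.ref_name, a.pos, a.strand))


# ---------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------

class FusionPipeline:
    """Reusable pipeline over one gene model."""

    def __init__(self, model: GeneModel, config: RunConfig = RunConfig(),
                 filters: Optional[Mapping[str, str]] = None,
                 read_len_hint: int = 50):
        self.model = model
        self.config = config
        flank = config.flank_len or (read_len_hint - config.anchor_len)
        max_suffix = config.max_suffix_len or (read_len_hint - config.anchor_len)
        self.junction_entries: Dict[str, JunctionReferenceEntry] = {
            e.name: e for e in build_junction_reference(model, flank)}
        self.genome_refs = ReferenceSet(model.chroms, "genome")
        self.junction_refs = ReferenceSet(
            {name: e.sequence for name, e in self.junction_entries.items()}, "junction")
        self.exon_refs = ReferenceSet(
            {e.exon_id: model.exon_sequence(e) for e in model.exons}, "exon")
        self.filter_refs = ReferenceSet(filters, "filter") if filters else None
        self.index: SasrIndex = build_index(
            model, min_len=config.min_suffix_len, max_len=max_suffix,
            anchor_len=config.anchor_len)
        self.insert_model = InsertModel(config.insert_mean, config.insert_sd)

    # -- stages ----------------------------------------------------------
    def _is_filtered(self, read: ReadRecord) -> bool:
        if self.filter_refs is None:
            return False
        hits = map_read_simple(self.filter_refs, read)
        return any(h.score >= self.config.filter_min_score for h in hits)

    def _align_read(self, read: ReadRecord, use_exon_ref: bool) -> List[AlignmentRecord]:
        alns = list(map_read_simple(self.genome_refs, read))
        alns += map_read_simple(self.junction_refs, read)
        if use_exon_ref:
            alns += map_read_simple(self.exon_refs, read)
        return _merge_alignments(alns, self.model, self.junction_entries)

    def _junction_span(self, aln: AlignmentRecord, read_id: str) -> Optional[SplicedHit]:
        entry = self.junction_entries[aln.ref_name]
        dflank = entry.donor_flank_len
        over = self.config.min_junction_overhang
        prefix = dflank - aln.pos
        suffix = aln.length - prefix
        if prefix < over or suffix < over:
            return None
        return SplicedHit(
            donor_exon_id=entry.donor_exon_id,
            acceptor_exon_id=entry.acceptor_exon_id,
            prefix_len=prefix, suffix_len=suffix,
            clipped_left=0, clipped_right=0,
            mismatches_total=aln.mismatches, read_id=read_id)

    def run(self, read_pairs: Sequence[Tuple[ReadRecord, ReadRecord]]) -> PipelineResult:
        cfg = self.config
        counts = {"pairs_in": len(read_pairs), "filtered": 0, "rescued": 0,
                  "paired_confident": 0, "admitted": 0, "spans": 0,
                  "junction_mapped_spans": 0}
        paired_primary: List[PairedAlignment] = []
        span_hits: List[SplicedHit] = []
        exon_read_counts: Dict[str, int] = {}
        assigner = make_genomic_exon_assigner(self.model)
        seen_span = set()

        def add_span(hit: Optional[SplicedHit]) -> None:
            if hit is None:
                return
            key = (hit.read_id, hit.donor_exon_id, hit.acceptor_exon_id,
                   hit.prefix_len)
            if key not in seen_span:
                seen_span.add(key)
                span_hits.append(hit)

        for fwd, rev in read_pairs:
            if self._is_filtered(fwd) or self._is_filtered(rev):
                counts["filtered"] += 1
                continue
            fwd_alns = self._align_read(fwd, use_exon_ref=False)
            rev_alns = self._align_read(rev, use_exon_ref=True)
            # annotation-aided rescue of an unmapped mate
            if fwd_alns and not rev_alns:
                genomic = [a for a in fwd_alns if a.reference_class == "genome"]
                if genomic:
                    rescued = rescue_mate(self.model, genomic[0], rev)
                    if rescued is not None:
                        rev_alns = [rescued]
                        counts["rescued"] += 1
            elif rev_alns and not fwd_alns:
                genomic = [a for a in rev_alns if a.reference_class == "genome"]
                if genomic:
                    rescued = rescue_mate(self.model, genomic[0], fwd)
                    if rescued is not None:
                        fwd_alns = [rescued]
                        counts["rescued"] += 1
            pairings = pair_and_score(fwd_alns, rev_alns, self.insert_model)
            primary = pairings[0] if pairings else None
            if primary is not None:
                paired_primary.append(primary)
                if primary.pqv > cfg.bridge_pqv_min:
                    counts["paired_confident"] += 1
                    for aln in (primary.fwd, primary.rev):
                        ex = assigner(aln)
                        if ex not in (None, "ambiguous"):
                            exon_read_counts[ex] = exon_read_counts.get(ex, 0) + 1
            # junction-mapped SPAN evidence from each mate's best placement
            for read, alns in ((fwd, fwd_alns), (rev, rev_alns)):
                if alns and alns[0].reference_class == "junction":
                    hit = self._junction_span(alns[0], read.read_id)
                    if hit is not None:
                        counts["junction_mapped_spans"] += 1
                        add_span(hit)
            # SASR on admitted reads
            prior = primary.pqv if primary is not None else None
            for read, alns in ((fwd, fwd_alns), (rev, rev_alns)):
                prior_pqv = prior if alns else None
                if not admit_read(read, prior_pqv, pqv_max=cfg.admission_pqv_max,
                                  anchor_len=cfg.anchor_len):
                    continue
                counts["admitted"] += 1
                hits = sasr_map_read(self.index, read,
                                     max_mismatches=cfg.max_mismatches,
                                     max_clip=cfg.max_clip)
                add_span(resolve_unique_junction(hits, self.model))

        counts["spans"] = len(span_hits)
        graph = accumulate_evidence(span_hits, paired_primary, self.model,
                                    bridge_pqv_min=cfg.bridge_pqv_min,
                                    exon_assigner=assigner)
        candidates = build_candidates(graph, exon_read_counts,
                                      total_pairs=len(paired_primary),
                                      mispair_rate=cfg.mispair_rate)
        junctions, fusions = call_junctions(
            candidates, self.model, same_gene_min=cfg.same_gene_min,
            fusion_min=cfg.fusion_min, jcv_min=cfg.jcv_min)
        counts["candidates"] = len(candidates)
        counts["junction_calls"] = len(junctions)
        counts["fusion_calls"] = len(fusions)
        logger.info("pipeline counts: %s", counts)
        return PipelineResult(model=self.model, paired=paired_primary,
                              span_hits=span_hits, candidates=candidates,
                              junction_calls=junctions, fusion_calls=fusions,
                              counts=counts)


def run_fusion_pipeline(model: GeneModel,
                        read_pairs: Sequence[Tuple[ReadRecord, ReadRecord]],
                        config: RunConfig = RunConfig(),
                        filters: Optional[Mapping[str, str]] = None) -> PipelineResult:
    read_len = max((len(p[0].sequence) for p in read_pairs), default=50)
    pipe = FusionPipeline(model, config, filters, read_len_hint=read_len)
    return pipe.run(read_pairs)


# ---------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------

FUSION_TSV_COLUMNS = [
    "five_exon", "five_chrom", "three_exon", "three_chrom", "classification",
    "signed_distance", "span_count", "bridge_count", "span_unique",
    "bridge_unique", "jcv", "in_frame",
]


def write_fusion_tsv(fusions: Sequence[FusionCall], model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FUSION_TSV_COLUMNS) + "\n")
        for f in fusions:
            c = f.candidate
            d = model.exon(c.donor_exon_id)
            a = model.exon(c.acceptor_exon_id)
            fh.write("\t".join(map(str, [
                c.donor_exon_id, d.chrom, c.acceptor_exon_id, a.chrom,
                f.classification,
                "" if f.signed_distance is None else f.signed_distance,
                c.span_count, c.bridge_count, c.span_unique_starts,
                c.bridge_unique_starts, c.jcv,
                "" if f.in_frame is None else f.in_frame,
            ])) + "\n")


def write_junction_bed(junctions: Sequence[JunctionCandidate], model: GeneModel,
                       path, block: int = 20) -> None:
    """BED12, one record per called junction with a block on each flanking exon;
    score = total evidence count, name = JCV."""
    with open(path, "w") as fh:
        for c in junctions:
            d = model.exon(c.donor_exon_id)
            a = model.exon(c.acceptor_exon_id)
            if d.chrom != a.chrom:
                continue
            left, right = sorted([(d.start, d.end), (a.start, a.end)])
            b1 = min(block, left[1] - left[0])
            b2 = min(block, right[1] - right[0])
            start, end = left[1] - b1, right[0] + b2
            fh.write("\t".join(map(str, [
                d.chrom, start, end,
                f"{c.donor_exon_id}|{c.acceptor_exon_id}|JCV={c.jcv}",
                c.span_count + c.bridge_count, d.strand, start, end, "0,0,0",
                2, f"{b1},{b2}", f"0,{right[0] + b2 - start - b2}",
            ])) + "\n")


def write_spans_tsv(span_hits: Sequence[SplicedHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tdonor_exon\tacceptor_exon\tprefix_len\tsuffix_len\t"
                 "clips\tmismatches\n")
        for h in span_hits:
            fh.write(f"{h.read_id}\t{h.donor_exon_id}\t{h.acceptor_exon_id}\t"
                     f"{h.prefix_len}\t{h.suffix_len}\t"
                     f"{h.clipped_left + h.clipped_right}\t{h.mismatches_total}\n")


def write_sam(paired: Sequence[PairedAlignment], model: GeneModel, path) -> None:
    """Genome-coordinate SAM of primary pairings; PQV in the XQ integer tag."""
    import pysam

    chroms = sorted(model.chroms)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": model.chrom_length(c)} for c in chroms]}
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in paired:
            if not p.primary:
                continue
            for aln, mate_aln, first in ((p.fwd, p.rev, True), (p.rev, p.fwd, False)):
                if aln.reference_class != "genome" or aln.ref_name not in tid:
                    continue
                rec = pysam.AlignedSegment()
                rec.query_name = aln.read_id
                rec.reference_id = tid[aln.ref_name]
                rec.reference_start = aln.pos
                rec.cigarstring = f"{aln.length}M"
                rec.mapping_quality = p.pqv
                flag = 0x1 | (0x40 if first else 0x80)
                if aln.strand == "-":
                    flag |= 0x10
                if mate_aln.reference_class == "genome" and mate_aln.ref_name in tid:
                    rec.next_reference_id = tid[mate_aln.ref_name]
                    rec.next_reference_start = mate_aln.pos
                    if mate_aln.strand == "-":
                        flag |= 0x20
                    if p.concordant:
                        flag |= 0x2
                rec.flag = flag
                rec.set_tag("XQ", p.pqv, "i")
                out.write(rec)
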