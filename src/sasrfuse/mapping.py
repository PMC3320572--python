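"""Simplified four-reference mapping pipeline: seed-and-extend alignment to
genome/junction/exon/filter references, filter subtraction, annotation-aided
mate rescue, and probabilistic pairing with a pairing quality value (PQV).

This is a deliberately small seed-and-extend mapper adequate for the
synthetic fixtures this package ships with; real datasets can supply
SAM/BAM alignments directly and skip :func:`map_read_simple`.

The PQV is a phred-like 0..40 score for the confidence that a read pair's
chosen joint placement is correct.  Candidate pairings are weighted by
alignment score and an insert-size likelihood; the best candidate's
posterior p is reported as round(-10*log10(1-p)), capped at 40.  Pairs
whose mates land on different references (including different chromosomes)
remain candidates with a small constant background insert density, so a
uniquely placed discordant pair — the signature of a fusion-bridging
fragment — still earns a high PQV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from sasrfuse.genemodel import Gene, GeneModel, reverse_complement

SEED_MISMATCH_BUDGET = {"genome": 2, "junction": 2, "exon": 3, "filter": 2}

# cap on total mismatches per reported alignment: a read whose best placement
# exceeds this is unmapped for that class (and so admissible to SASR) rather
# than reported as a frayed alignment
TOTAL_MISMATCH_CAP = {"genome": 4, "junction": 4, "exon": 5, "filter": 8}

MISMATCH_PENALTY = 3  # score = matches - 2*mismatches = length - 3*mismatches


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    mate: int
    ref_name: str
    pos: int  # 0-based leftmost on the reference
    strand: str
    length: int
    matches: int
    mismatches: int
    score: int
    reference_class: str  # genome | junction | exon | filter


@dataclass
class PairedAlignment:
    fwd: AlignmentRecord
    rev: AlignmentRecord
    insert_size: int
    pqv: int
    primary: bool
    concordant: bool = True
    posterior: float = 0.0


@dataclass(frozen=True)
class InsertModel:
    """Normal model of the library insert (fragment) size."""

    mean: float = 150.0
    sd: float = 25.0

    def density(self, insert: float) -> float:
        z = (insert - self.mean) / self.sd
        return math.exp(-0.5 * z * z) / (self.sd * math.sqrt(2 * math.pi))


class ReferenceSet:
    """Named sequences of one reference class with an exact k-mer seed index."""

    def __init__(self, sequences: Mapping[str, str], reference_class: str, k: int = 8):
        self.reference_class = reference_class
        self.k = k
        self.seqs = {name: seq.upper() for name, seq in sequences.items()}
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i:i + k], []).append((name, i))

    def seed_hits(self, kmer: str) -> List[Tuple[str, int]]:
        return self._index.get(kmer, [])


def _count_mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def map_read_simple(refs: ReferenceSet, read, seed_mismatches: Optional[int] = None,
                    seed_len: int = 25, max_hits: int = 50) -> List[AlignmentRecord]:
    """Seed-and-extend alignment of one read to one reference class.

    The seed is the first ``seed_len`` bases; the per-class mismatch budget
    (genome/junction 2, exon 3) applies to the seed region, and the whole
    read is then scored match=+1 / mismatch=-2.  Both strands are tried.
    """
    budget = SEED_MISMATCH_BUDGET[refs.reference_class] if seed_mismatches is None \
        else seed_mismatches
    mm_cap = TOTAL_MISMATCH_CAP[refs.reference_class]
    seq = read.sequence.upper()
    n = len(seq)
    slen = min(seed_len, n)
    k = refs.k
    out: List[AlignmentRecord] = []
    seen = set()
    for strand, query in (("+", seq), ("-", reverse_complement(seq))):
        # seed chunks of the query anchor candidate diagonals (pigeonhole)
        for off in range(0, slen - k + 1, k):
            for name, hit_pos in refs.seed_hits(query[off:off + k]):
                p = hit_pos - off
                if p < 0 or p + n > len(refs.seqs[name]):
                    continue
                key = (name, p, strand)
                if key in seen:
                    continue
                seen.add(key)
                ref_seq = refs.seqs[name][p:p + n]
                if _count_mismatches(query[:slen], ref_seq[:slen]) > budget:
                    continue
                mm = _count_mismatches(query, ref_seq)
                if mm > mm_cap:
                    continue
                score = n - MISMATCH_PENALTY * mm
                if score <= 0:
                    continue
                out.append(AlignmentRecord(
                    read_id=read.read_id, mate=read.mate, ref_name=name, pos=p,
                    strand=strand, length=n, matches=n - mm, mismatches=mm,
                    score=score, reference_class=refs.reference_class))
    out.sort(key=lambda a: (-a.score, a.ref_name, a.pos, a.strand))
    return out[:max_hits]


def subtract_filtered(alignments: Sequence[AlignmentRecord],
                      filter_hits: Sequence[AlignmentRecord],
                      min_score: int = 25) -> List[AlignmentRecord]:
    """Drop every alignment of any read with a confident filter-reference hit."""
    filtered_ids = {h.read_id for h in filter_hits if h.score >= min_score}
    return [a for a in alignments if a.read_id not in filtered_ids]


def _gene_at(model: GeneModel, chrom: str, start: int, end: int) -> Optional[Gene]:
    exons = model.exons_overlapping(chrom, start, end)
    genes = sorted({e.gene_id for e in exons})
    if len(genes) == 1:
        return model.genes[genes[0]]
    if genes:
        return None  # overlapping genes: ambiguous
    for gid in sorted(model.genes):
        g = model.genes[gid]
        if g.chrom == chrom and g.span_start <= start and end <= g.span_end:
            return g
    return None


def rescue_mate(model: GeneModel, anchored: AlignmentRecord, unmapped_read,
                max_mismatches: int = 6) -> Optional[AlignmentRecord]:
    """Align an unmapped mate within the downstream exons of the gene its
    anchored mate fell in, allowing up to six mismatches."""
    if anchored.reference_class != "genome":
        return None
    gene = _gene_at(model, anchored.ref_name, anchored.pos,
                    anchored.pos + anchored.length)
    if gene is None:
        return None
    # transcription-order rank at/after the anchored position
    r0 = len(gene.exons)
    for e in gene.exons:
        downstream_of_anchor = (
            e.end > anchored.pos if gene.strand == "+"
            else e.start < anchored.pos + anchored.length
        )
        if downstream_of_anchor:
            r0 = min(r0, e.rank)
    seq = unmapped_read.sequence.upper()
    n = len(seq)
    best: Optional[AlignmentRecord] = None
    for e in gene.exons:
        if e.rank < r0 or e.length < n:
            continue
        exon_fwd = model.fetch(e.chrom, e.start, e.end, "+")
        for strand, query in (("+", seq), ("-", reverse_complement(seq))):
            for off in range(e.length - n + 1):
                mm = _count_mismatches(query, exon_fwd[off:off + n])
                if mm > max_mismatches:
                    continue
                rec = AlignmentRecord(
                    read_id=unmapped_read.read_id, mate=unmapped_read.mate,
                    ref_name=e.chrom, pos=e.start + off, strand=strand,
                    length=n, matches=n - mm, mismatches=mm,
                    score=n - MISMATCH_PENALTY * mm, reference_class="genome")
                if best is None or rec.score > best.score:
                    best = rec
    return best


def _concordant_insert(f: AlignmentRecord, r: AlignmentRecord,
                       insert_model: InsertModel) -> Optional[int]:
    """Insert size if the pair is concordant (same reference, FR orientation,
    plausible span), else None."""
    if f.ref_name != r.ref_name or f.reference_class != r.reference_class:
        return None
    if f.strand == r.strand:
        return None
    if f.strand == "+":
        insert = (r.pos + r.length) - f.pos
    else:
        insert = (f.pos + f.length) - r.pos
    if insert <= 0 or insert > insert_model.mean + 10 * insert_model.sd:
        return None
    return insert


def pair_and_score(fwd_alignments: Sequence[AlignmentRecord],
                   rev_alignments: Sequence[AlignmentRecord],
                   insert_model: InsertModel = InsertModel(),
                   background_density: float = 1e-9,
                   max_per_side: int = 20) -> List[PairedAlignment]:
    """Enumerate candidate pairings and assign a PQV to the best one.

    Candidate weight w_i = 10^(score_i/10) * density(insert_i), where the
    density is the insert-size likelihood for concordant candidates and a
    small constant background otherwise.  Posteriors p_i = w_i / sum(w);
    the best candidate is primary with pqv = round(-10*log10(1-p)) capped
    at 40.
    """
    if not fwd_alignments or not rev_alignments:
        return []
    fwd = sorted(fwd_alignments, key=lambda a: -a.score)[:max_per_side]
    rev = sorted(rev_alignments, key=lambda a: -a.score)[:max_per_side]
    cands: List[Tuple[float, AlignmentRecord, AlignmentRecord, Optional[int]]] = []
    for f in fwd:
        for r in rev:
            insert = _concordant_insert(f, r, insert_model)
            dens = insert_model.density(insert) if insert is not None else background_density
            w = 10.0 ** ((f.score + r.score) / 10.0) * dens
            cands.append((w, f, r, insert))
    total = sum(w for w, *_ in cands)
    if total <= 0.0:
        return []
    cands.sort(key=lambda c: (-c[0], c[1].ref_name, c[1].pos, c[2].ref_name, c[2].pos))
    out: List[PairedAlignment] = []
    for i, (w, f, r, insert) in enumerate(cands):
        p = w / total
        if i == 0:
            pqv = 40 if p >= 1.0 - 1e-12 else min(40, round(-10.0 * math.log10(1.0 - p)))
        else:
            pqv = 0
        out.append(PairedAlignment(
            fwd=f, rev=r, insert_size=insert if insert is not None else 0,
            pqv=pqv, primary=(i == 0), concordant=insert is not None,
            posterior=p))
    return out


def assign_gene(model: GeneModel, aln: AlignmentRecord,
                junction_entries: Optional[Mapping[str, object]] = None) -> Optional[str]:
    """Gene id an alignment belongs to, or None if intergenic/ambiguous."""
    if aln.reference_class == "genome":
        g = _gene_at(model, aln.ref_name, aln.pos, aln.pos + aln.length)
        return g.gene_id if g is not None else None
    if aln.reference_class == "exon":
        try:
            return model.exon(aln.ref_name).gene_id
        except KeyError:
            return None
    if aln.reference_class == "junction" and junction_entries is not None:
        entry = junction_entries.get(aln.ref_name)
        if entry is not None:
            return model.exon(entry.donor_exon_id).gene_id
    return None


def compute_rpkm(model: GeneModel, paired_alignments: Sequence[PairedAlignment],
                 pqv_threshold: int = 10,
                 junction_entries: Optional[Mapping[str, object]] = None) -> Dict[str, float]:
    """Reads per kilobase of exon model per million confidently mapped reads.

    Counts primary pairings with pqv > threshold, assigned to a gene by the
    forward mate's placement.
    """
    confident = [p for p in paired_alignments if p.primary and p.pqv > pqv_threshold]
    total = len(confident)
    counts: Dict[str, int] = {gid: 0 for gid in model.genes}
    for p in confident:
        gid = assign_gene(model, p.fwd, junction_entries)
        if gid is not None:
            counts[gid] += 1
    rpkm: Dict[str, float] = {}
    for gid, gene in model.genes.items():
        if total == 0:
            rpkm[gid] = 0.0
        else:
            rpkm[gid] = counts[gid] * 1e9 / (total * gene.exonic_length)
    return rpkm
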