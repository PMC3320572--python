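"""Gene models, genome access, and reference construction.

Internal coordinates are 0-based half-open throughout.  GTF input is
converted from 1-based inclusive at the boundary; BED12 is already 0-based.
Exon ``rank`` is 1-based in transcription order, so on the minus strand
rank 1 is the highest-coordinate exon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Exon:
    """One exon of a gene; coordinates 0-based half-open on the genome."""

    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"zero- or negative-length exon {self.exon_id}: [{self.start},{self.end})")
        if self.rank < 1:
            raise ValueError(f"exon rank must be >= 1, got {self.rank}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for exon {self.exon_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor_coord(self) -> int:
        """Genomic coordinate of the exon's 3' (donor) boundary."""
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor_coord(self) -> int:
        """Genomic coordinate of the exon's 5' (acceptor) boundary."""
        return self.start if self.strand == "+" else self.end


@dataclass
class Gene:
    """A gene as a flattened, rank-ordered exon set on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: List[Exon] = field(default_factory=list)

    @property
    def span_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def span_end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def span_length(self) -> int:
        """Gene length: distance from the start of the first exon to the
        end of the last exon, introns included."""
        return self.span_end - self.span_start

    @property
    def exonic_length(self) -> int:
        """Total length of the (union of the) exons."""
        ivals = sorted((e.start, e.end) for e in self.exons)
        total, cur_s, cur_e = 0, None, None
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def exon_by_rank(self, rank: int) -> Exon:
        return self.exons[rank - 1]


class GeneModel:
    """A set of genes plus an accessor into the genome sequence."""

    def __init__(self, genes: Sequence[Gene], genome: Mapping[str, str]):
        self.genes: Dict[str, Gene] = {}
        self._genome = {name: str(seq).upper() for name, seq in genome.items()}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._exons: List[Exon] = [e for g in genes for e in g.exons]
        self._exon_by_id: Dict[str, Exon] = {}
        for e in self._exons:
            if e.exon_id in self._exon_by_id:
                raise ValueError(f"duplicate exon_id {e.exon_id}")
            self._exon_by_id[e.exon_id] = e
        self._validate()
        self._trees: Dict[str, IntervalTree] = {}
        for e in self._exons:
            self._trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, e)

    def _validate(self) -> None:
        for e in self._exons:
            if e.chrom not in self._genome:
                raise KeyError(f"exon {e.exon_id} references unknown sequence {e.chrom!r}")
            if e.end > len(self._genome[e.chrom]):
                raise ValueError(
                    f"exon {e.exon_id} [{e.start},{e.end}) exceeds length of {e.chrom} "
                    f"({len(self._genome[e.chrom])})"
                )

    # -- genome access -------------------------------------------------
    @property
    def chroms(self) -> Dict[str, str]:
        return self._genome

    def chrom_length(self, chrom: str) -> int:
        return len(self._genome[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self._genome[chrom][start:end]
        return seq if strand == "+" else reverse_complement(seq)

    # -- exon access ---------------------------------------------------
    @property
    def exons(self) -> List[Exon]:
        return self._exons

    def exon(self, exon_id: str) -> Exon:
        return self._exon_by_id[exon_id]

    def gene_of(self, exon_id: str) -> Gene:
        return self.genes[self._exon_by_id[exon_id].gene_id]

    def exons_overlapping(self, chrom: str, start: int, end: int) -> List[Exon]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda e: (e.start, e.end, e.exon_id))

    def exon_sequence(self, exon: Exon) -> str:
        """Exon sequence in transcription orientation."""
        return self.fetch(exon.chrom, exon.start, exon.end, exon.strand)

    def transcript_sequence(self, gene: Gene) -> str:
        """Spliced sequence: exon sequences concatenated in rank order."""
        return "".join(self.exon_sequence(e) for e in gene.exons)


def exon_sequence(model: GeneModel, exon: Exon) -> str:
    return model.exon_sequence(exon)


# ---------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------

def _load_genome(genome_path) -> Dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(genome_path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _rank_exons(gene_id: str, chrom: str, strand: str,
                intervals: Iterable[Tuple[int, int]]) -> Gene:
    """Flatten distinct (start, end) intervals and assign transcription ranks."""
    distinct = sorted(set(intervals))
    if strand == "-":
        distinct = distinct[::-1]
    exons = [
        Exon(exon_id=f"{gene_id}-{i + 1}", gene_id=gene_id, chrom=chrom,
             start=s, end=e, strand=strand, rank=i + 1)
        for i, (s, e) in enumerate(distinct)
    ]
    return Gene(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)


def _load_gtf(path) -> List[Gene]:
    from gffutils.iterators import DataIterator

    per_gene: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    for feat in DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        gid = feat.attributes["gene_id"][0]
        start0, end0 = feat.start - 1, feat.end  # GTF is 1-based inclusive
        if end0 <= start0:
            raise ValueError(f"zero-length exon for gene {gid} at {feat.seqid}:{feat.start}")
        per_gene.setdefault(gid, []).append((start0, end0))
        prev = meta.setdefault(gid, (feat.seqid, feat.strand))
        if prev != (feat.seqid, feat.strand):
            raise ValueError(f"gene {gid} spans multiple chromosomes or strands")
    return [
        _rank_exons(gid, meta[gid][0], meta[gid][1], ivals)
        for gid, ivals in per_gene.items()
    ]


def _load_bed12(path) -> List[Gene]:
    genes: List[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount does not match block lists")
            ivals = [(chrom_start + bs, chrom_start + bs + sz)
                     for bs, sz in zip(starts, sizes)]
            genes.append(_rank_exons(name, chrom, strand, ivals))
    return genes


def load_gene_model(annotation_path, genome_path) -> GeneModel:
    """Load a gene model from GTF or BED12 plus a genome FASTA.

    The annotation format is chosen by extension (.bed -> BED12, otherwise
    GTF).  Fails hard on exons referencing unknown sequences or falling
    outside their chromosome.
    """
    genome = _load_genome(genome_path)
    suffix = Path(str(annotation_path)).suffix.lower()
    genes = _load_bed12(annotation_path) if suffix == ".bed" else _load_gtf(annotation_path)
    return GeneModel(genes, genome)


def write_bed12(model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(model.genes):
            g = model.genes[gid]
            ivals = sorted((e.start, e.end) for e in g.exons)
            cs = g.span_start
            sizes = ",".join(str(e - s) for s, e in ivals)
            starts = ",".join(str(s - cs) for s, _ in ivals)
            fh.write("\t".join(map(str, [
                g.chrom, cs, g.span_end, gid, 0, g.strand,
                cs, g.span_end, "0,0,0", len(ivals), sizes, starts,
            ])) + "\n")


def write_gtf(model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(model.genes):
            g = model.genes[gid]
            for e in g.exons:
                attrs = (f'gene_id "{gid}"; transcript_id "{gid}.t1"; '
                         f'exon_number "{e.rank}";')
                fh.write("\t".join(map(str, [
                    g.chrom, "sasrfuse", "exon", e.start + 1, e.end, ".",
                    g.strand, ".", attrs,
                ])) + "\n")


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionReferenceEntry:
    """Concatenated donor 3' flank + acceptor 5' flank of one exon pair."""

    donor_exon_id: str
    acceptor_exon_id: str
    sequence: str
    donor_flank_len: int
    acceptor_flank_len: int
    kind: str  # "known" (adjacent ranks) or "putative" (rank-skipping)

    @property
    def name(self) -> str:
        return f"{self.donor_exon_id}|{self.acceptor_exon_id}"


def build_junction_reference(model: GeneModel, flank_len: int,
                             max_rank_skip: Optional[int] = None) -> List[JunctionReferenceEntry]:
    """Enumerate within-gene ordered exon pairs (rank i < j) as junction
    reference entries.

    Adjacent pairs (j == i+1) are "known" junctions; rank-skipping pairs
    are "putative".  Flanks are truncated when an exon is shorter than
    ``flank_len``.  ``max_rank_skip`` optionally caps j - i.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    entries: List[JunctionReferenceEntry] = []
    for gid in sorted(model.genes):
        g = model.genes[gid]
        n = len(g.exons)
        for i in range(n):
            for j in range(i + 1, n):
                if max_rank_skip is not None and (j - i) > max_rank_skip:
                    continue
                donor, acceptor = g.exons[i], g.exons[j]
                dseq = model.exon_sequence(donor)[-flank_len:]
                aseq = model.exon_sequence(acceptor)[:flank_len]
                entries.append(JunctionReferenceEntry(
                    donor_exon_id=donor.exon_id,
                    acceptor_exon_id=acceptor.exon_id,
                    sequence=dseq + aseq,
                    donor_flank_len=len(dseq),
                    acceptor_flank_len=len(aseq),
                    kind="known" if j == i + 1 else "putative",
                ))
    return entries


def default_filter_set(length: int = 50) -> Dict[str, str]:
    """Built-in filter reference: the four homopolymers."""
    return {f"poly{b}": b * length for b in "ACGT"}


def load_filter_reference(filter_path) -> Dict[str, str]:
    """Read filter sequences (adaptors, repeats, rRNA, homopolymers) from FASTA.

    An empty file yields an empty filter set with a warning; the pipeline
    then proceeds without filtering.
    """
    from Bio import SeqIO  # lazy: only needed when a filter FASTA is supplied

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(filter_path), "fasta")}
    if not seqs:
        warnings.warn(f"filter reference {filter_path} is empty; no filtering will be applied")
    return seqs
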