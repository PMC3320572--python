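"""Synthetic genomes, gene models, fusion transcripts, and paired-end reads
with ground truth.

The generator emulates a strand-specific paired-end RNA-Seq experiment with
asymmetric read lengths (50 bp forward / 25 bp reverse by default), inserts
gel-selected around 100-200 bp (normal, mean 150, sd 25), log-normal
transcript abundances, and i.i.d. substitution errors.  Fusion transcripts
join the first exons of a 5' gene to the trailing exons of a 3' gene in
three classes: inter-chromosomal, inverted (same chromosome, opposite
strands), and same-strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from sasrfuse.genemodel import (
    Exon,
    Gene,
    GeneModel,
    reverse_complement,
    write_fasta,
    write_gtf,
)
from sasrfuse.sasr import ReadRecord

BASES = np.array(list("ACGT"))

INTER, INVERTED, SAME_STRAND = "inter-chromosomal", "inverted", "same-strand"


@dataclass
class SimConfig:
    n_chroms: int = 3
    chrom_length: int = 120_000
    n_genes: int = 24
    exons_per_gene: Tuple[int, int] = (3, 6)
    exon_length: Tuple[int, int] = (80, 200)
    intron_length: Tuple[int, int] = (200, 800)
    intergenic_gap: Tuple[int, int] = (500, 1500)
    n_fusions: int = 6
    fusion_mix: Dict[str, float] = field(default_factory=lambda: {
        INTER: 1 / 3, INVERTED: 1 / 3, SAME_STRAND: 1 / 3})
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    fusion_expression_boost: float = 3.0
    read_len_fwd: int = 50
    read_len_rev: int = 25
    insert_mean: float = 150.0
    insert_sd: float = 25.0
    substitution_error_rate: float = 0.005
    n_fragments: int = 4000
    guaranteed_span_per_fusion: int = 3
    guaranteed_bridge_per_fusion: int = 3
    seed: int = 0


@dataclass(frozen=True)
class TrueFusion:
    tx_id: str
    five_gene: str
    three_gene: str
    donor_exon_id: str  # last retained exon of the 5' gene
    acceptor_exon_id: str  # first retained exon of the 3' gene
    classification: str
    signed_distance: Optional[int]


@dataclass
class Transcript:
    tx_id: str
    sequence: str
    junction_offsets: List[Tuple[int, str, str]]  # (offset, donor, acceptor)
    fusion_offset: Optional[int] = None  # transcript coord of fusion boundary
    fusion: Optional[TrueFusion] = None


@dataclass(frozen=True)
class ReadProvenance:
    tx_id: str
    start: int
    insert: int
    spans_fusion: Optional[str] = None  # "donor|acceptor" when a mate crosses
    bridges_fusion: Optional[str] = None


@dataclass
class GroundTruth:
    true_junctions: set = field(default_factory=set)  # adjacent exon pairs
    true_fusions: List[TrueFusion] = field(default_factory=list)
    read_truth: Dict[str, ReadProvenance] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    model: GeneModel
    transcripts: Dict[str, Transcript]
    abundances: Dict[str, float]
    read_pairs: List[Tuple[ReadRecord, ReadRecord]]
    truth: GroundTruth


# ---------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------

def _random_genome(rng, n_chroms: int, length: int) -> Dict[str, str]:
    return {f"chr{i + 1}": "".join(rng.choice(BASES, size=length))
            for i in range(n_chroms)}


def simulate_reference(config: SimConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[GeneModel, GroundTruth]:
    """Random genome plus non-overlapping multi-exon genes; deterministic
    under the config seed."""
    rng = rng or np.random.default_rng(config.seed)
    genome = _random_genome(rng, config.n_chroms, config.chrom_length)
    genes: List[Gene] = []
    chrom_cursor = {c: 0 for c in genome}
    chrom_names = sorted(genome)
    g = 0
    attempts = 0
    while g < config.n_genes:
        attempts += 1
        if attempts > 10 * config.n_genes:
            raise ValueError("cannot fit the requested genes; enlarge chrom_length")
        chrom = chrom_names[g % len(chrom_names)]
        # alternate strands within a chromosome so every fusion class has pairs
        strand = "+" if (g // len(chrom_names)) % 2 == 0 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                               max(0, n_ex - 1))
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        span = int(ex_lens.sum() + in_lens.sum())
        pos = chrom_cursor[chrom] + gap
        if pos + span > config.chrom_length:
            chrom_cursor[chrom] = config.chrom_length  # chromosome full
            if all(v >= config.chrom_length for v in chrom_cursor.values()):
                raise ValueError("genome too small for the requested gene count")
            continue
        gid = f"g{g + 1:03d}"
        ivals = []
        p = pos
        for i, L in enumerate(ex_lens):
            ivals.append((p, p + int(L)))
            p += int(L) + (int(in_lens[i]) if i < len(in_lens) else 0)
        distinct = ivals if strand == "+" else ivals[::-1]
        exons = [Exon(exon_id=f"{gid}-{r + 1}", gene_id=gid, chrom=chrom,
                      start=s, end=e, strand=strand, rank=r + 1)
                 for r, (s, e) in enumerate(distinct)]
        genes.append(Gene(gene_id=gid, chrom=chrom, strand=strand, exons=exons))
        chrom_cursor[chrom] = pos + span
        g += 1
    model = GeneModel(genes, genome)
    truth = GroundTruth()
    for gene in genes:
        for i in range(len(gene.exons) - 1):
            truth.true_junctions.add((gene.exons[i].exon_id, gene.exons[i + 1].exon_id))
    return model, truth


# ---------------------------------------------------------------------
# Transcripts and fusions
# ---------------------------------------------------------------------

def _gene_transcripts(model: GeneModel) -> Dict[str, Transcript]:
    out: Dict[str, Transcript] = {}
    for gid in sorted(model.genes):
        gene = model.genes[gid]
        seq_parts, offsets = [], []
        pos = 0
        for i, e in enumerate(gene.exons):
            s = model.exon_sequence(e)
            if i > 0:
                offsets.append((pos, gene.exons[i - 1].exon_id, e.exon_id))
            seq_parts.append(s)
            pos += len(s)
        out[f"{gid}.t1"] = Transcript(tx_id=f"{gid}.t1", sequence="".join(seq_parts),
                                      junction_offsets=offsets)
    return out


def _signed_distance(donor: Exon, acceptor: Exon) -> Optional[int]:
    if donor.chrom != acceptor.chrom or donor.strand != acceptor.strand:
        return None
    dist = acceptor.acceptor_coord - donor.donor_coord
    return dist if donor.strand == "+" else -dist


def _class_counts(mix: Dict[str, float], n: int) -> Dict[str, int]:
    raw = {k: mix.get(k, 0.0) * n for k in (INTER, INVERTED, SAME_STRAND)}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True):
        if remainder <= 0:
            break
        counts[k] += 1
        remainder -= 1
    return counts


def _pair_class(a: Gene, b: Gene) -> str:
    if a.chrom != b.chrom:
        return INTER
    if a.strand != b.strand:
        return INVERTED
    return SAME_STRAND


def simulate_fusions(model: GeneModel, config: SimConfig,
                     rng: Optional[np.random.Generator] = None,
                     truth: Optional[GroundTruth] = None) -> Dict[str, Transcript]:
    """Fusion transcripts joining exons 1..r of a 5' gene to exons s..end of
    a 3' gene, drawn per the configured class mix; genes are not reused."""
    rng = rng or np.random.default_rng(config.seed + 1)
    counts = _class_counts(config.fusion_mix, config.n_fusions)
    gids = sorted(model.genes)
    order = list(rng.permutation(len(gids)))
    available = [gids[i] for i in order]
    out: Dict[str, Transcript] = {}
    f = 0
    for cls in (INTER, INVERTED, SAME_STRAND):
        for _ in range(counts[cls]):
            pair = None
            for i in range(len(available)):
                for j in range(len(available)):
                    if i == j:
                        continue
                    a, b = model.genes[available[i]], model.genes[available[j]]
                    if _pair_class(a, b) == cls and len(a.exons) >= 2 and len(b.exons) >= 2:
                        pair = (i, j)
                        break
                if pair:
                    break
            if pair is None:
                raise ValueError(f"no available gene pair for fusion class {cls}")
            i, j = pair
            five = model.genes[available[i]]
            three = model.genes[available[j]]
            for idx in sorted((i, j), reverse=True):
                available.pop(idx)
            r = int(rng.integers(1, len(five.exons)))  # last retained 5' exon
            s = int(rng.integers(2, len(three.exons) + 1))  # first retained 3' exon
            five_seq = "".join(model.exon_sequence(e) for e in five.exons[:r])
            three_seq = "".join(model.exon_sequence(e) for e in three.exons[s - 1:])
            donor = five.exon_by_rank(r)
            acceptor = three.exon_by_rank(s)
            tf = TrueFusion(
                tx_id=f"fusion{f + 1:02d}", five_gene=five.gene_id,
                three_gene=three.gene_id, donor_exon_id=donor.exon_id,
                acceptor_exon_id=acceptor.exon_id, classification=cls,
                signed_distance=_signed_distance(donor, acceptor))
            offsets = []
            pos = 0
            for i_e, e in enumerate(five.exons[:r]):
                if i_e > 0:
                    offsets.append((pos, five.exons[i_e - 1].exon_id, e.exon_id))
                pos += e.length
            fusion_offset = pos
            offsets.append((pos, donor.exon_id, acceptor.exon_id))
            for i_e, e in enumerate(three.exons[s - 1:]):
                if i_e > 0:
                    offsets.append((pos, three.exons[s - 1 + i_e - 1].exon_id, e.exon_id))
                pos += e.length
            out[tf.tx_id] = Transcript(
                tx_id=tf.tx_id, sequence=five_seq + three_seq,
                junction_offsets=offsets, fusion_offset=fusion_offset, fusion=tf)
            if truth is not None:
                truth.true_fusions.append(tf)
            f += 1
    return out


# ---------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        orig = arr[i].decode()
        choices = [b for b in "ACGT" if b != orig]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def _fragment_to_pair(tx: Transcript, start: int, insert: int, read_id: str,
                      config: SimConfig, rng) -> Tuple[ReadRecord, ReadRecord, ReadProvenance]:
    frag = tx.sequence[start:start + insert]
    fwd_seq = _mutate(frag[:config.read_len_fwd], config.substitution_error_rate, rng)
    rev_seq = _mutate(reverse_complement(frag[-config.read_len_rev:]),
                      config.substitution_error_rate, rng)
    spans = bridges = None
    if tx.fusion_offset is not None:
        b = tx.fusion_offset
        key = f"{tx.fusion.donor_exon_id}|{tx.fusion.acceptor_exon_id}"
        fwd_s, fwd_e = start, start + config.read_len_fwd
        rev_s, rev_e = start + insert - config.read_len_rev, start + insert
        if (fwd_s <= b - 10 and fwd_e >= b + 10) or (rev_s <= b - 10 and rev_e >= b + 10):
            spans = key
        elif fwd_e <= b and rev_s >= b:
            bridges = key
    prov = ReadProvenance(tx_id=tx.tx_id, start=start, insert=insert,
                          spans_fusion=spans, bridges_fusion=bridges)
    return (ReadRecord(read_id, 1, fwd_seq), ReadRecord(read_id, 2, rev_seq), prov)


def simulate_reads(transcripts: Dict[str, Transcript],
                   abundances: Dict[str, float], config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   truth: Optional[GroundTruth] = None
                   ) -> List[Tuple[ReadRecord, ReadRecord]]:
    """Paired reads with fragment positions drawn per abundance and a
    truncated-normal insert model, plus deterministic top-up fragments that
    guarantee the configured spanning/bridging coverage of each fusion."""
    rng = rng or np.random.default_rng(config.seed + 2)
    lf, lr = config.read_len_fwd, config.read_len_rev
    min_insert = max(lf, lr)
    tx_ids = sorted(transcripts)
    usable = [t for t in tx_ids if len(transcripts[t].sequence) >= min_insert + 1]
    weights = np.array([abundances[t] * len(transcripts[t].sequence) for t in usable],
                       dtype=float)
    probs = weights / weights.sum()
    pairs: List[Tuple[ReadRecord, ReadRecord]] = []

    def emit(tx: Transcript, start: int, insert: int, read_id: str) -> None:
        fwd, rev, prov = _fragment_to_pair(tx, start, insert, read_id, config, rng)
        pairs.append((fwd, rev))
        if truth is not None:
            truth.read_truth[read_id] = prov

    choices = rng.choice(len(usable), size=config.n_fragments, p=probs)
    for n, ti in enumerate(choices):
        tx = transcripts[usable[ti]]
        T = len(tx.sequence)
        insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        insert = max(min_insert, min(insert, T))
        start = int(rng.integers(0, T - insert + 1))
        emit(tx, start, insert, f"frag{n:06d}")

    # guaranteed coverage of each fusion breakpoint (distinct start points)
    for tx_id in tx_ids:
        tx = transcripts[tx_id]
        if tx.fusion_offset is None:
            continue
        b, T = tx.fusion_offset, len(tx.sequence)
        for i in range(config.guaranteed_span_per_fusion):
            start = b - lf + 10 + 2 * i
            insert = min(int(config.insert_mean), T - start)
            if start < 0 or insert < lf:
                continue
            emit(tx, start, insert, f"gsp_{tx_id}_{i}")
        for i in range(config.guaranteed_bridge_per_fusion):
            start = b - lf - 5 - 3 * i
            rev_start = b + 5 + 3 * i
            insert = rev_start + lr - start
            if start < 0 or start + insert > T:
                continue
            emit(tx, start, insert, f"gbr_{tx_id}_{i}")
    return pairs


def simulate_dataset(config: SimConfig) -> SimResult:
    """Full fixture: genome + gene model, fusion transcripts, abundances,
    paired reads, and ground truth, all from one seed."""
    rng = np.random.default_rng(config.seed)
    model, truth = simulate_reference(config, rng)
    transcripts = _gene_transcripts(model)
    transcripts.update(simulate_fusions(model, config, rng, truth))
    abundances = {}
    for t in sorted(transcripts):
        a = float(rng.lognormal(config.expression_mu, config.expression_sigma))
        if transcripts[t].fusion is not None:
            a *= config.fusion_expression_boost
        abundances[t] = a
    read_pairs = simulate_reads(transcripts, abundances, config, rng, truth)
    return SimResult(config=config, model=model, transcripts=transcripts,
                     abundances=abundances, read_pairs=read_pairs, truth=truth)


# ---------------------------------------------------------------------
# On-disk fixture
# ---------------------------------------------------------------------

def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qualities or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}/{r.mate}\n{r.sequence}\n+\n{qual}\n")


def write_dataset(result: SimResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.model.chroms, outdir / "genome.fa")
    write_gtf(result.model, outdir / "model.gtf")
    write_fastq([p[0] for p in result.read_pairs], outdir / "reads_1.fq")
    write_fastq([p[1] for p in result.read_pairs], outdir / "reads_2.fq")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("tx_id\tfive_gene\tthree_gene\tdonor_exon\tacceptor_exon\t"
                 "classification\tsigned_distance\n")
        for tf in result.truth.true_fusions:
            fh.write(f"{tf.tx_id}\t{tf.five_gene}\t{tf.three_gene}\t"
                     f"{tf.donor_exon_id}\t{tf.acceptor_exon_id}\t"
                     f"{tf.classification}\t"
                     f"{'' if tf.signed_distance is None else tf.signed_distance}\n")
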