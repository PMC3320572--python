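"""Spliced-read mapping: worked example, budgets, clipping, oracle equivalence."""

import numpy as np
import pytest

from sasrfuse.sasr import (
    ReadRecord,
    admit_read,
    resolve_unique_junction,
    sasr_map_read,
    sequence_entropy,
)
from sasrfuse.suffix_index import SasrIndex

from conftest import make_model, random_seq
from oracles import brute_force_sasr


def hits_as_tuples(hits):
    return {(h.donor_exon_id, h.acceptor_exon_id, h.prefix_len,
             h.clipped_left, h.clipped_right, h.mismatches_total) for h in hits}


@pytest.fixture
def toy_index():
    rng = np.random.default_rng(10)
    donor_exon = random_seq(rng, 20) + "ATTACCAGTTGACCA"
    acceptor_exon = "TGCCATGGCAAC" + random_seq(rng, 20)
    idx = SasrIndex(["donor", "acceptor"], [donor_exon, acceptor_exon],
                    min_len=10, max_len=38)
    return idx


def test_worked_toy_junction_read(toy_index):
    read = ReadRecord("r1", 1, "ACCAGTTGACCA" + "TGCCATGGCAAC")
    hits = sasr_map_read(toy_index, read)
    assert len(hits) == 1
    h = hits[0]
    assert (h.donor_exon_id, h.acceptor_exon_id) == ("donor", "acceptor")
    assert (h.prefix_len, h.suffix_len) == (12, 12)
    assert h.clipped_left == h.clipped_right == 0
    assert h.mismatches_total == 0


def test_three_extension_mismatches_kill_the_hit(toy_index):
    # corrupt three donor-extension bases of a 16/12 split read; donor anchor
    # (first ten bases) stays exact, so only the extension budget can reject
    donor_seq = toy_index.exon_seqs[0]
    acceptor_seq = toy_index.exon_seqs[1]
    prefix = donor_seq[-16:]
    read_seq = prefix + acceptor_seq[:12]

    def flip(b):
        return "A" if b != "A" else "C"

    corrupted = prefix[:10] + "".join(flip(b) for b in prefix[10:13]) + prefix[13:]
    ok = sasr_map_read(toy_index, ReadRecord("ok", 1, read_seq))
    assert any(h.prefix_len == 16 for h in ok)
    bad = sasr_map_read(toy_index, ReadRecord("bad", 1, corrupted + acceptor_seq[:12]))
    assert not any(h.prefix_len == 16 and h.mismatches_total <= 2 for h in bad)


def test_two_extension_mismatches_survive(toy_index):
    donor_seq = toy_index.exon_seqs[0]
    acceptor_seq = toy_index.exon_seqs[1]
    prefix = donor_seq[-16:]

    def flip(b):
        return "A" if b != "A" else "C"

    corrupted = prefix[:10] + "".join(flip(b) for b in prefix[10:12]) + prefix[12:]
    hits = sasr_map_read(toy_index, ReadRecord("r", 1, corrupted + acceptor_seq[:12]))
    match = [h for h in hits if h.prefix_len == 16]
    assert match and match[0].mismatches_total == 2


def test_interior_read_of_one_exon_yields_no_hit():
    rng = np.random.default_rng(11)
    exon = random_seq(rng, 80)
    idx = SasrIndex(["e"], [exon])
    read = ReadRecord("r", 1, exon[20:44])  # interior, touches neither end
    assert sasr_map_read(idx, read) == []


def test_clipping_recovers_reads_with_corrupt_ends(toy_index):
    donor_seq = toy_index.exon_seqs[0]
    acceptor_seq = toy_index.exon_seqs[1]
    clean = donor_seq[-14:] + acceptor_seq[:14]
    noisy = "GGGG" + clean  # 4 junk bases on the left end
    hits = sasr_map_read(toy_index, ReadRecord("r", 1, noisy))
    assert hits, "clipping should recover the junction"
    assert all(h.clipped_left + h.clipped_right == 4 for h in hits)
    assert any(h.clipped_left == 4 and h.prefix_len == 14 for h in hits)


def test_every_hit_satisfies_sum_rule_and_anchor_minima():
    rng = np.random.default_rng(12)
    seqs = [random_seq(rng, int(L)) for L in rng.integers(15, 60, 25)]
    idx = SasrIndex([f"e{i}" for i in range(len(seqs))], seqs)
    for t in range(60):
        i, j = rng.integers(0, len(seqs), 2)
        p = int(rng.integers(10, 15))
        s = int(rng.integers(10, 15))
        if len(seqs[i]) < p or len(seqs[j]) < s:
            continue
        read = ReadRecord(f"r{t}", 1, seqs[i][-p:] + seqs[j][:s])
        for h in sasr_map_read(idx, read):
            n_eff = len(read.sequence) - h.clipped_left - h.clipped_right
            assert h.prefix_len + h.suffix_len == n_eff
            assert h.prefix_len >= 10 and h.suffix_len >= 10


def test_oracle_equivalence_on_random_reads():
    rng = np.random.default_rng(13)
    ids = [f"e{i}" for i in range(30)]
    seqs = [random_seq(rng, int(L)) for L in rng.integers(12, 70, 30)]
    idx = SasrIndex(ids, seqs, min_len=10, max_len=38)
    reads = []
    for t in range(40):  # junction reads, some with errors/junk ends
        i, j = rng.integers(0, 30, 2)
        p = int(rng.integers(10, min(len(seqs[i]), 30) + 1))
        s = int(rng.integers(10, min(len(seqs[j]), 30) + 1))
        seq = seqs[i][-p:] + seqs[j][:s]
        if t % 3 == 1:
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + "T" + seq[pos + 1:]
        if t % 5 == 2:
            seq = random_seq(rng, 3) + seq
        reads.append(seq[:50])
    reads += [random_seq(rng, 30) for _ in range(10)]
    for n, seq in enumerate(reads):
        got = hits_as_tuples(sasr_map_read(idx, ReadRecord(f"r{n}", 1, seq)))
        expected = brute_force_sasr(ids, seqs, seq)
        assert got == expected, f"read {n} disagrees with brute force"


def test_error_free_junction_reads_recovered_with_zero_clips():
    rng = np.random.default_rng(14)
    seqs = [random_seq(rng, 50) for _ in range(10)]
    idx = SasrIndex([f"e{i}" for i in range(10)], seqs)
    for t in range(20):
        i, j = rng.integers(0, 10, 2)
        p, s = int(rng.integers(10, 39)), int(rng.integers(10, 39))
        hits = sasr_map_read(idx, ReadRecord(f"r{t}", 1, seqs[i][-p:] + seqs[j][:s]))
        assert any(h.clipped_left == 0 and h.clipped_right == 0 for h in hits)


def test_determinism_of_hit_ordering(toy_index):
    read = ReadRecord("r", 1, toy_index.exon_seqs[0][-12:] + toy_index.exon_seqs[1][:12])
    assert sasr_map_read(toy_index, read) == sasr_map_read(toy_index, read)


# -- admission ---------------------------------------------------------

def test_admission_rules():
    good = ReadRecord("r", 1, "ACGTACGTACGTACGTACGTACGT")
    assert admit_read(good, prior_pqv=None)          # unmapped -> admitted
    assert not admit_read(good, prior_pqv=35)        # confident -> rejected
    assert admit_read(good, prior_pqv=10)            # at threshold -> admitted
    homopolymer = ReadRecord("r", 1, "A" * 50)
    assert sequence_entropy(homopolymer.sequence) == 0.0
    assert not admit_read(homopolymer, prior_pqv=None)
    assert not admit_read(ReadRecord("r", 1, "ACGTACGT"), None)  # too short


# -- unique-junction resolution ---------------------------------------

def test_resolve_unique_junction_collapses_identical_boundaries():
    from sasrfuse.sasr import SplicedHit

    # two genes with exons sharing identical 3' end / 5' start coordinates
    model = make_model([
        ("gA", "chr1", "+", [(0, 100), (200, 300)]),
        ("gB", "chr1", "+", [(40, 100), (200, 320)]),
    ])

    def hit(donor, acceptor):
        return SplicedHit(donor, acceptor, 12, 12, 0, 0, 0, "r")

    same = [hit("gA-1", "gA-2"), hit("gB-1", "gB-2")]  # boundaries coincide
    resolved = resolve_unique_junction(same, model)
    assert resolved is not None

    # without coordinate collapse the same hits are ambiguous
    assert resolve_unique_junction(same, model=None) is None

    different = [hit("gA-1", "gA-2"), hit("gA-2", "gB-1")]
    assert resolve_unique_junction(different, model) is None
    assert resolve_unique_junction([], model) is None
    assert resolve_unique_junction([hit("gA-1", "gA-2")], model) is not None
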