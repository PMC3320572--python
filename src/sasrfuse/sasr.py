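"""Suffix-array spliced-read (SASR) mapping of single reads across exon pairs.

A read provides evidence of a junction between exons X and Y iff X maps to
the read's prefix, Y maps to its suffix, and the two map lengths sum to the
(effective) read length.  Decamer anchors from both read ends are looked up
exactly in the index; anchor hits are extended with at most two mismatches
per side; up to ten total bases may be clipped from the read ends, stopping
at the first clip total that yields a hit.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from sasrfuse.suffix_index import SasrIndex, extend_match, search_anchor


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    mate: int
    sequence: str
    qualities: Optional[str] = None


@dataclass(frozen=True)
class SplicedHit:
    """One read's junction evidence: prefix on the donor exon's 3' end,
    suffix on the acceptor exon's 5' start."""

    donor_exon_id: str
    acceptor_exon_id: str
    prefix_len: int
    suffix_len: int
    clipped_left: int
    clipped_right: int
    mismatches_total: int
    read_id: str

    def sort_key(self) -> Tuple:
        return (self.donor_exon_id, self.acceptor_exon_id, self.prefix_len,
                self.clipped_left, self.clipped_right)


def sequence_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the base composition."""
    if not seq:
        return 0.0
    counts = Counter(seq.upper())
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def admit_read(read: ReadRecord, prior_pqv: Optional[int] = None,
               pqv_max: int = 10, min_entropy: float = 1.0,
               anchor_len: int = 10) -> bool:
    """Admission gate for SASR candidates.

    A read is admitted iff it has no confident prior placement (unmapped,
    or best pairing quality <= ``pqv_max``), is long enough to carry two
    anchors, and passes a base-composition entropy check that rejects
    homopolymer and other low-complexity reads.
    """
    if len(read.sequence) < 2 * anchor_len:
        return False
    if prior_pqv is not None and prior_pqv > pqv_max:
        return False
    return sequence_entropy(read.sequence) >= min_entropy


def _side_hits(index: SasrIndex, eff: str, side: str,
               max_mismatches: int) -> Dict[int, List[Tuple[int, int]]]:
    """Covered (exon_index, mismatches) per map length for one read end."""
    anchor = eff[:index.anchor_len] if side == "donor" else eff[-index.anchor_len:]
    out: Dict[int, List[Tuple[int, int]]] = defaultdict(list)
    for entry in search_anchor(index, anchor, side):
        covered, map_len, mm = extend_match(index, entry, eff, side, max_mismatches)
        if covered:
            out[map_len].append((entry.exon_index, mm))
    return out


def sasr_map_read(index: SasrIndex, read: ReadRecord, max_mismatches: int = 2,
                  max_clip: int = 10) -> List[SplicedHit]:
    """Map one read across a putative exon-exon breakpoint.

    Clip totals c = 0..max_clip are tried in order, each split over the two
    read ends (ascending left clip); all splits of a total are searched and
    the scan stops at the first total producing at least one hit.  Every
    emitted hit satisfies prefix_len + suffix_len = effective read length
    with both sides >= anchor_len.
    """
    seq = read.sequence.upper()
    n = len(seq)
    a = index.anchor_len
    for c in range(max_clip + 1):
        level: set = set()
        for left in range(c + 1):
            right = c - left
            if n - c < 2 * a:
                continue
            eff = seq[left:n - right]
            donor = _side_hits(index, eff, "donor", max_mismatches)
            if not donor:
                continue
            acceptor = _side_hits(index, eff, "acceptor", max_mismatches)
            if not acceptor:
                continue
            m = len(eff)
            for plen, dhits in donor.items():
                slen = m - plen
                if slen < a or slen not in acceptor:
                    continue
                for d_idx, d_mm in dhits:
                    for a_idx, a_mm in acceptor[slen]:
                        level.add(SplicedHit(
                            donor_exon_id=index.exon_ids[d_idx],
                            acceptor_exon_id=index.exon_ids[a_idx],
                            prefix_len=plen, suffix_len=slen,
                            clipped_left=left, clipped_right=right,
                            mismatches_total=d_mm + a_mm,
                            read_id=read.read_id,
                        ))
        if level:
            return sorted(level, key=SplicedHit.sort_key)
    return []


def resolve_unique_junction(hits: List[SplicedHit],
                            model=None) -> Optional[SplicedHit]:
    """Keep a read only if all its hits name one junction.

    When a GeneModel is given, exons sharing identical boundary coordinates
    (overlapping annotation) are collapsed before testing uniqueness:
    donors by their 3'-end genomic coordinate, acceptors by their 5'-start.
    Ambiguous reads yield None.
    """
    if not hits:
        return None

    def donor_key(h: SplicedHit):
        if model is None:
            return h.donor_exon_id
        e = model.exon(h.donor_exon_id)
        return (e.chrom, e.strand, e.donor_coord)

    def acceptor_key(h: SplicedHit):
        if model is None:
            return h.acceptor_exon_id
        e = model.exon(h.acceptor_exon_id)
        return (e.chrom, e.strand, e.acceptor_coord)

    junctions = {(donor_key(h), acceptor_key(h)) for h in hits}
    if len(junctions) != 1:
        return None
    return min(hits, key=SplicedHit.sort_key)
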