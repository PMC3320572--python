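"""Suffix-array index over exon ends for the spliced-read aligner.

Two lexicographically sorted tables are kept: a donor table of exon 3'-end
suffixes (lengths ``min_len`` .. ``max_len``, transcription orientation)
and an acceptor table of exon 5'-start prefixes keyed by their REVERSED
string, so that the read's right-end anchor can be binary-searched after
reversal.  Each entry is stored compactly as (exon index, length); key
strings are materialized on demand during comparisons.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class SuffixEntry:
    """Compact representation of one stored exon-end string."""

    exon_index: int
    length: int


class SasrIndex:
    """Sorted exon-end suffix/prefix tables answering decamer anchor queries."""

    def __init__(self, exon_ids: Sequence[str], exon_seqs: Sequence[str],
                 min_len: int = 10, max_len: int = 38, anchor_len: int = 10):
        if min_len < anchor_len:
            raise ValueError("min_len must be >= anchor_len")
        if max_len < min_len:
            raise ValueError("max_len must be >= min_len")
        self.exon_ids = list(exon_ids)
        self.exon_seqs = [s.upper() for s in exon_seqs]
        self.min_len = min_len
        self.max_len = max_len
        self.anchor_len = anchor_len
        self.donor_table: List[SuffixEntry] = []
        self.acceptor_table: List[SuffixEntry] = []
        self._build()

    # -- key materialization --------------------------------------------
    def donor_key(self, entry: SuffixEntry) -> str:
        """Last ``length`` bases of the exon (transcription orientation)."""
        return self.exon_seqs[entry.exon_index][-entry.length:]

    def acceptor_key(self, entry: SuffixEntry) -> str:
        """First ``length`` bases of the exon, reversed."""
        return self.exon_seqs[entry.exon_index][:entry.length][::-1]

    def key(self, entry: SuffixEntry, side: str) -> str:
        return self.donor_key(entry) if side == "donor" else self.acceptor_key(entry)

    def table(self, side: str) -> List[SuffixEntry]:
        if side == "donor":
            return self.donor_table
        if side == "acceptor":
            return self.acceptor_table
        raise ValueError(f"side must be 'donor' or 'acceptor', got {side!r}")

    # -- construction ----------------------------------------------------
    def _entries_for(self, i: int) -> List[SuffixEntry]:
        n = len(self.exon_seqs[i])
        hi = min(n, self.max_len)
        return [SuffixEntry(i, L) for L in range(self.min_len, hi + 1)]

    def _build(self) -> None:
        donor, acceptor = [], []
        for i in range(len(self.exon_seqs)):
            for e in self._entries_for(i):
                if _VALID.issuperset(self.donor_key(e)):
                    donor.append(e)
                if _VALID.issuperset(self.acceptor_key(e)):
                    acceptor.append(e)
        donor.sort(key=lambda e: (self.donor_key(e), e.exon_index, e.length))
        acceptor.sort(key=lambda e: (self.acceptor_key(e), e.exon_index, e.length))
        self.donor_table = donor
        self.acceptor_table = acceptor


def build_index(model, min_len: int = 10, max_len: int = 38,
                anchor_len: int = 10) -> SasrIndex:
    """Build the SASR index from a GeneModel's exons (transcription orientation)."""
    exon_ids = [e.exon_id for e in model.exons]
    exon_seqs = [model.exon_sequence(e) for e in model.exons]
    return SasrIndex(exon_ids, exon_seqs, min_len=min_len, max_len=max_len,
                     anchor_len=anchor_len)


def _bisect(index: SasrIndex, side: str, anchor: str, right: bool) -> int:
    table = index.table(side)
    k = len(anchor)
    lo, hi = 0, len(table)
    while lo < hi:
        mid = (lo + hi) // 2
        prefix = index.key(table[mid], side)[:k]
        if prefix < anchor or (right and prefix == anchor):
            lo = mid + 1
        else:
            hi = mid
    return lo


def search_anchor(index: SasrIndex, anchor: str, side: str) -> List[SuffixEntry]:
    """All entries whose key string begins with ``anchor`` (exact match only).

    For the acceptor side the caller passes the read's terminal decamer in
    read orientation; it is reversed here to match the reversed-key table.
    Anchors containing non-ACGT symbols match nothing.
    """
    if len(anchor) != index.anchor_len:
        raise ValueError(f"anchor must have length {index.anchor_len}, got {len(anchor)}")
    anchor = anchor.upper()
    if not _VALID.issuperset(anchor):
        logger.debug("anchor %r contains non-ACGT symbols; no match", anchor)
        return []
    if side == "acceptor":
        anchor = anchor[::-1]
    lo = _bisect(index, side, anchor, right=False)
    hi = _bisect(index, side, anchor, right=True)
    return index.table(side)[lo:hi]


def extend_match(index: SasrIndex, entry: SuffixEntry, read: str, side: str,
                 max_mismatches: int = 2) -> Tuple[bool, int, int]:
    """Extend an anchor hit over the full stored exon-end string.

    The decamer anchor region stays exact; substitutions are counted in the
    extension region only.  Returns (covered, map_len, mismatches) where
    covered means the read's terminal segment of ``entry.length`` bases
    matches the exon end with at most ``max_mismatches`` substitutions.
    """
    L = entry.length
    if L > len(read):
        return False, 0, 0
    a = index.anchor_len
    key = index.key(entry, side)
    if side == "donor":
        segment = read[:L]
        anchor_ok = segment[:a] == key[:a]
        ext_pairs = zip(segment[a:], key[a:])
    else:
        segment = read[-L:]
        key_fwd = key[::-1]  # exon prefix in transcription orientation
        anchor_ok = segment[-a:] == key_fwd[-a:]
        ext_pairs = zip(segment[:L - a], key_fwd[:L - a])
    if not anchor_ok:
        return False, 0, 0
    mismatches = sum(1 for x, y in ext_pairs if x != y)
    covered = mismatches <= max_mismatches
    return covered, (L if covered else 0), mismatches


def block_histogram(index: SasrIndex, side: str) -> Dict[int, int]:
    """Frequencies of maximal runs of entries sharing the same leading anchor.

    Partitions the table into blocks of entries with identical first
    ``anchor_len`` key characters and counts block sizes.
    """
    table = index.table(side)
    a = index.anchor_len
    sizes: Counter = Counter()
    run_anchor: Optional[str] = None
    run_len = 0
    for e in table:
        anc = index.key(e, side)[:a]
        if anc == run_anchor:
            run_len += 1
        else:
            if run_len:
                sizes[run_len] += 1
            run_anchor, run_len = anc, 1
    if run_len:
        sizes[run_len] += 1
    return dict(sizes)
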