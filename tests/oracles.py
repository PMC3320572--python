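"""Independent oracles used by the test suite.

These deliberately avoid the package's own data structures and algorithms:
the spliced-read oracle enumerates every exon pair, split position, and clip
allocation by direct string comparison; the Irwin-Hall CDF is the closed
form for the sum of iid uniforms.
"""

import math


def brute_force_sasr(exon_ids, exon_seqs, read_seq, anchor_len=10,
                     max_mismatches=2, max_clip=10, min_len=10, max_len=38):
    """Exhaustive spliced-read search with the same budgets as the aligner:
    every exon pair x split x clip allocation, stopping at the first
    productive clip total.  Returns tuples
    (donor, acceptor, prefix_len, clip_left, clip_right, mismatches)."""

    def side_match(segment, key, donor):
        # anchor exact at the read end; mismatches counted in the extension
        if donor:
            if segment[:anchor_len] != key[:anchor_len]:
                return None
            mm = sum(1 for x, y in zip(segment[anchor_len:], key[anchor_len:]) if x != y)
        else:
            if segment[-anchor_len:] != key[-anchor_len:]:
                return None
            mm = sum(1 for x, y in zip(segment[:-anchor_len], key[:-anchor_len]) if x != y)
        return mm if mm <= max_mismatches else None

    n = len(read_seq)
    for c in range(max_clip + 1):
        hits = set()
        for left in range(c + 1):
            right = c - left
            eff = read_seq[left:n - right]
            m = len(eff)
            if m < 2 * anchor_len:
                continue
            for s in range(anchor_len, m - anchor_len + 1):
                if not (min_len <= s <= max_len and min_len <= m - s <= max_len):
                    continue
                pre, suf = eff[:s], eff[s:]
                donors, acceptors = [], []
                for eid, seq in zip(exon_ids, exon_seqs):
                    if len(seq) >= s:
                        mm = side_match(pre, seq[-s:], donor=True)
                        if mm is not None:
                            donors.append((eid, mm))
                    if len(seq) >= m - s:
                        mm = side_match(suf, seq[:m - s], donor=False)
                        if mm is not None:
                            acceptors.append((eid, mm))
                for d_id, d_mm in donors:
                    for a_id, a_mm in acceptors:
                        hits.add((d_id, a_id, s, left, right, d_mm + a_mm))
        if hits:
            return hits
    return set()


def irwin_hall_cdf(x: float, n: int) -> float:
    """P(U1 + ... + Un < x) for iid uniform(0,1)."""
    if x <= 0:
        return 0.0
    if x >= n:
        return 1.0
    total = 0.0
    for k in range(int(math.floor(x)) + 1):
        total += ((-1) ** k) * math.comb(n, k) * (x - k) ** n
    return total / math.factorial(n)
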