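"""Independent brute-force oracles used to check the implementation.

These deliberately re-derive each quantity by direct enumeration (or by
translation to a regular expression), never by calling the code paths they
check.
"""

import re

import numpy as np

EDGE_BUCKET = 2


def brute_force_candidates(depth, left_ends, right_ends, ewf, ewt, end_support_min, threshold):
    """Enumerate every (i, j) window directly and keep qualifying candidates."""
    n = len(depth)
    csum = np.concatenate(([0], np.cumsum(depth)))
    out = []
    for i in range(n):
        if left_ends[i] < end_support_min:
            continue
        for j in range(i + ewf - 1, min(i + ewt - 1, n - 1) + 1):
            if right_ends[j] < end_support_min:
                continue
            score = (csum[j + 1] - csum[i]) / (j - i + 1)
            if score >= threshold:
                out.append((float(score), i, j))
    return out


def brute_force_select(candidates):
    """Greedy descending-score selection with double-edge +/-2 bp dedup,
    re-implemented by literal pairwise comparison."""
    order = sorted(candidates, key=lambda c: (-c[0], -(c[2] - c[1]), c[1], c[2]))
    selected = []
    for score, i, j in order:
        if any(abs(i - i2) <= EDGE_BUCKET and abs(j - j2) <= EDGE_BUCKET for _, i2, j2 in selected):
            continue
        selected.append((score, i, j))
    return selected


def brute_force_overlap_count(interval, fragments):
    start, end = interval
    return sum(1 for f in fragments if f.start < end and f.end > start)


_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]", "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGTN]",
}

_RC = {"A": "T", "T": "A", "C": "G", "G": "C",
       "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
       "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def regex_scan(sequence, pattern, both_strands=True):
    """Overlap-aware regex translation of an IUPAC pattern; hits as (pos, strand).

    Minus-strand hits come from scanning the pattern on the reverse-complemented
    sequence and mapping coordinates back — a different route than scanning a
    reverse-complemented pattern on the plus strand.
    """
    sequence = sequence.upper()
    regex = re.compile("(?=(" + "".join(_IUPAC_CLASS[c] for c in pattern.upper()) + "))")
    hits = [(m.start(), "+") for m in regex.finditer(sequence)]
    if both_strands:
        rc_seq = "".join(_RC[c] for c in reversed(sequence))
        plen = len(pattern)
        hits.extend(
            (len(sequence) - m.start() - plen, "-") for m in regex.finditer(rc_seq)
        )
    return sorted(hits)
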