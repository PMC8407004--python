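"""Degenerate-consensus scanning and position-frequency summaries.

Integration host factor (IHF) and similar nucleoid-associated proteins bind
short degenerate sites conventionally written in the IUPAC nucleotide alphabet
(W = A/T, R = A/G, S = G/C, N = any base).  This module provides the IUPAC
pattern type shared with the synthetic-genome planter, a both-strand scanner,
the "fraction of called regions containing the consensus" summary used when
characterising footprint sets, and a position-weight-matrix builder for
logo-style summaries.  De-novo motif discovery is deliberately out of scope:
:func:`export_region_fasta` emits region sequences for external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

# --------------------------------------------------------------------------
# IUPAC alphabet
# --------------------------------------------------------------------------

#: allowed concrete bases per degenerate code
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_CODE_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_BASE_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a concrete sequence over {A,C,G,T,N}."""
    return seq.upper().translate(_BASE_COMPLEMENT)[::-1]


#: consensus elements reported for IHF footprint sets, by timepoint/context
CONSENSUS_PRESETS: dict[str, str] = {
    "known": "WATCARnnnnTTR",          # canonical IHF-binding sequence
    "pre_init_core": "CAnnnnTTT",      # pre-initiation (0 min) core element
    "post_init_10min": "WWTCARSnnnTTA",
    "post_init_20min": "WWCARSnnnTT",
    "random_phase": "WAWCAACnnnTT",
    "ttca": "TAAnnnnTTGATW",           # ttcA / prophage attachment site consensus
}


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate nucleotide pattern (case-insensitive; 'n' == 'N')."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty IUPAC pattern")
        up = self.pattern.upper()
        bad = sorted({c for c in up if c not in IUPAC_CODES})
        if bad:
            raise ValueError(f"illegal IUPAC code(s) {bad!r} in pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", up)

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    def allowed(self, i: int) -> str:
        """Concrete bases permitted at column ``i``."""
        return IUPAC_CODES[self.pattern[i]]

    def matches(self, seq: str) -> bool:
        """Position-wise membership of ``seq`` in the pattern.

        A reference 'N' matches only a pattern 'N' (unknown base, unconstrained
        column); every other code requires a concrete base.
        """
        seq = seq.upper()
        if len(seq) != len(self.pattern):
            return False
        for base, code in zip(seq, self.pattern):
            if base == "N":
                if code != "N":
                    return False
            elif base not in IUPAC_CODES[code]:
                return False
        return True

    def reverse_complement(self) -> "IUPACPattern":
        return IUPACPattern("".join(_CODE_COMPLEMENT[c] for c in reversed(self.pattern)))

    def instantiate(self, rng: np.random.Generator) -> str:
        """Replace each degenerate code by a uniformly sampled allowed base."""
        out = []
        for code in self.pattern:
            bases = IUPAC_CODES[code]
            out.append(bases if len(bases) == 1 else bases[rng.integers(len(bases))])
        return "".join(out)


class MatchHit(NamedTuple):
    """One pattern occurrence, always in plus-strand coordinates."""

    position: int
    strand: str           # '+' or '-'
    matched_seq: str      # plus-strand slice; its revcomp satisfies the pattern for '-'


# --------------------------------------------------------------------------
# scanning
# --------------------------------------------------------------------------

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# boolean allowed-base vectors over (A, C, G, T, N) per code; the reference 'N'
# slot is permitted only for the pattern code 'N'
_ALLOWED5 = {
    code: np.array([b in bases for b in "ACGT"] + [code == "N"], dtype=bool)
    for code, bases in IUPAC_CODES.items()
}


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"sequence contains non-ACGTN character {bad!r}")
    return arr


def _scan_one_strand(enc: np.ndarray, pattern: IUPACPattern) -> np.ndarray:
    plen = len(pattern)
    n = len(enc)
    if n < plen:
        return np.empty(0, dtype=np.intp)
    nwin = n - plen + 1
    ok = np.ones(nwin, dtype=bool)
    for k, code in enumerate(pattern.pattern):
        ok &= _ALLOWED5[code][enc[k : k + nwin]]
    return np.flatnonzero(ok)


def iupac_scan(
    sequence: str,
    pattern: IUPACPattern | str,
    both_strands: bool = True,
) -> list[MatchHit]:
    """All occurrences of ``pattern`` in ``sequence``.

    Minus-strand hits are found by scanning the reverse-complemented pattern on
    the plus strand, so their coordinates and ``matched_seq`` refer to the plus
    strand directly.  Overlapping hits are all reported.
    """
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    sequence = sequence.upper()
    enc = _encode(sequence)
    plen = len(pattern)
    hits = [
        MatchHit(int(p), "+", sequence[p : p + plen])
        for p in _scan_one_strand(enc, pattern)
    ]
    if both_strands:
        hits += [
            MatchHit(int(p), "-", sequence[p : p + plen])
            for p in _scan_one_strand(enc, pattern.reverse_complement())
        ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


class ConsensusSummary(NamedTuple):
    n_with_match: int
    n_total: int
    fraction: float


def consensus_fraction(
    regions: Sequence[tuple[int, int]],
    genome: str,
    pattern: IUPACPattern | str,
    both_strands: bool = True,
) -> ConsensusSummary:
    """Fraction of regions containing >=1 consensus occurrence on either strand.

    ``regions`` are 0-based half-open ``(start, end)`` intervals on ``genome``.
    A region counts once however many hits it contains.
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    n_with = 0
    for start, end in ((r[0], r[1]) for r in regions):
        if not (0 <= start < end <= len(genome)):
            raise ValueError(f"region [{start},{end}) outside genome of length {len(genome)}")
        if iupac_scan(genome[start:end], pattern, both_strands=both_strands):
            n_with += 1
    return ConsensusSummary(n_with, len(regions), n_with / len(regions))


# --------------------------------------------------------------------------
# PWM summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Column base frequencies over (A, C, G, T) with per-column information content."""

    freqs: np.ndarray              # shape (L, 4), rows sum to 1
    n_sequences: int
    info_content: np.ndarray = field(repr=False)  # bits, shape (L,), in [0, 2]

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


def build_pwm(sequences: Sequence[str], pseudocount: float = 0.0) -> PWM:
    """Position frequency summary of equal-length aligned sequences.

    Information content per column is ``2 + sum_b f_b log2 f_b`` bits against a
    uniform background; ``pseudocount`` is added to every base count before
    normalisation.
    """
    if len(sequences) < 2:
        raise ValueError("need >=2 sequences to build a PWM")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    length = len(sequences[0])
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.full((length, 4), float(pseudocount))
    for seq in sequences:
        seq = seq.upper()
        if len(seq) != length:
            raise ValueError("sequences must have equal aligned length")
        for col, base in enumerate(seq):
            if base not in idx:
                raise ValueError(f"non-ACGT base {base!r} in PWM input")
            counts[col, idx[base]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PWM(freqs=freqs, n_sequences=len(sequences), info_content=info)


def export_region_fasta(
    regions: Sequence[tuple[int, int]],
    genome: str,
    path,
    flank: int = 0,
    chrom: str = "genome",
) -> None:
    """Write one FASTA record per region for external motif discovery.

    Record IDs encode 1-based inclusive coordinates of the (flanked) slice,
    e.g. ``genome:101-180``.  Symmetric flanks are clipped at genome ends.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    with open(path, "w") as fh:
        for start, end in ((r[0], r[1]) for r in regions):
            s = max(0, start - flank)
            e = min(len(genome), end + flank)
            if not s < e:
                raise ValueError(f"empty region [{start},{end})")
            fh.write(f">{chrom}:{s + 1}-{e}\n")
            seq = genome[s:e]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
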