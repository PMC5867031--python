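"""Paired-end read merging and expected-error quality filtering.

The pre-clustering QC mirrors the USEARCH workflow used for amplicon
genotyping: mates are merged over their best ungapped overlap, and the
merged reads are filtered on expected errors

    E = sum_i 10^(-Q_i / 10)

with reads retained iff ``E <= max_ee`` (the classic maxEE 1 rule).

In the overlap, agreeing bases take the higher of the two quality scores
(capped at ``qmax``); disagreeing bases take the higher-quality base
with quality ``|Q1 - Q2|`` — posterior-style quality updating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from famedit.guides import reverse_complement

__all__ = [
    "MergedRead",
    "merge_pairs",
    "expected_error_filter",
    "expected_errors",
    "read_fastq",
]


@dataclass
class MergedRead:
    sequence: str
    qualities: np.ndarray
    sample_id: str = ""
    read_id: str = ""

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")

    @property
    def expected_errors(self) -> float:
        return expected_errors(self.qualities)


def expected_errors(qualities: Sequence[int]) -> float:
    """E = sum over bases of 10^(-Q/10)."""
    q = np.asarray(qualities, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative Phred score")
    return float(np.sum(10.0 ** (-q / 10.0)))


def _overlap_candidates(s1: str, s2rc: str, min_overlap: int) -> List[int]:
    """Candidate overlap lengths from exact k-mer anchors of the mate-2
    prefix found in mate 1 (several anchor offsets tolerate errors)."""
    cands = set()
    k = 16
    for off in (0, k, 2 * k):
        if off + k > len(s2rc):
            break
        anchor = s2rc[off : off + k]
        start = 0
        while True:
            pos = s1.find(anchor, start)
            if pos < 0:
                break
            o = len(s1) - (pos - off)
            if min_overlap <= o <= min(len(s1), len(s2rc)):
                cands.add(o)
            start = pos + 1
    return sorted(cands)


def _score_overlap(a1: np.ndarray, a2: np.ndarray, o: int) -> int:
    """Mismatch count for overlap length o."""
    return int(np.count_nonzero(a1[len(a1) - o :] != a2[:o]))


def merge_pairs(
    seq1: str,
    qual1: Sequence[int],
    seq2: str,
    qual2: Sequence[int],
    min_overlap: int = 20,
    max_diff_fraction: float = 0.25,
    qmax: int = 41,
    sample_id: str = "",
    read_id: str = "",
    exhaustive: bool = False,
) -> Tuple[Optional[MergedRead], str]:
    """Merge a read pair over its best ungapped overlap.

    ``seq2`` is the reverse-strand mate and is reverse-complemented
    before overlap search.  Among overlap lengths >= ``min_overlap`` the
    one with the lowest mismatch *fraction* wins (ties: the longer
    overlap) — ranking by fraction rather than raw match score keeps a
    short perfect overlap from losing to a longer, repeat-shifted one in
    tandem-repeat amplicons.  The pair is rejected when no overlap
    reaches ``min_overlap`` or the best overlap's mismatch fraction
    exceeds ``max_diff_fraction``.

    Returns ``(MergedRead, "ok")`` or ``(None, reason)``.  The default
    search seeds candidate overlaps from exact 16-mer anchors and falls
    back to the exhaustive scan whenever the anchored search finds no
    acceptable overlap, so it is equivalent to ``exhaustive=True``.
    """
    q1 = np.asarray(qual1, dtype=np.int16)
    q2 = np.asarray(qual2, dtype=np.int16)
    if len(seq1) != len(q1) or len(seq2) != len(q2):
        raise ValueError("sequence/quality length mismatch")
    s2 = reverse_complement(seq2)
    q2 = q2[::-1]
    a1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    max_o = min(len(seq1), len(s2))
    if max_o < min_overlap:
        return None, "no_overlap"

    def best_over(cands: Iterable[int]):
        best = None  # (fraction, -o, mismatches, o)
        for o in cands:
            mism = _score_overlap(a1, a2, o)
            key = (mism / o, -o)
            if best is None or key < best[:2]:
                best = (key[0], key[1], mism, o)
        return best

    best = None
    if not exhaustive:
        best = best_over(_overlap_candidates(seq1, s2, min_overlap))
        if best is not None and best[0] > max_diff_fraction:
            best = None  # anchored hit too noisy; re-check exhaustively
    if best is None:
        best = best_over(range(min_overlap, max_o + 1))
    if best is None:
        return None, "no_overlap"
    frac, _, mism, o = best
    if frac > max_diff_fraction:
        return None, "too_many_diffs"

    n1, n2 = len(seq1), len(s2)
    merged = list(seq1[: n1 - o])
    quals = list(int(x) for x in q1[: n1 - o])
    for k in range(o):
        b1, b2 = seq1[n1 - o + k], s2[k]
        x, y = int(q1[n1 - o + k]), int(q2[k])
        if b1 == b2:
            merged.append(b1)
            quals.append(min(max(x, y), qmax))
        elif x >= y:
            merged.append(b1)
            quals.append(abs(x - y))
        else:
            merged.append(b2)
            quals.append(abs(x - y))
    merged.extend(s2[o:])
    quals.extend(int(x) for x in q2[o:])
    return (
        MergedRead("".join(merged), np.array(quals, dtype=np.int16), sample_id, read_id),
        "ok",
    )


def expected_error_filter(
    reads: Iterable[MergedRead], max_ee: float = 1.0
) -> Tuple[List[MergedRead], int]:
    """Retain reads with expected errors E <= max_ee (inclusive).

    Returns (retained_reads, rejected_count)."""
    kept: List[MergedRead] = []
    rejected = 0
    for r in reads:
        if r.expected_errors <= max_ee:
            kept.append(r)
        else:
            rejected += 1
    return kept, rejected


def read_fastq(path, sample_id: str = "") -> List[Tuple[str, str, np.ndarray]]:
    """Read a Phred+33 FASTQ file into (read_id, sequence, qualities) tuples."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record in {path}")
            quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33
            if np.any(quals < 0):
                raise ValueError(f"non-Phred+33 quality string in {path}")
            out.append((header[1:].split()[0], seq, quals))
    return out
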