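"""Microhomology enumeration and MMEJ attribution of deletions.

Microhomology-mediated end joining (MMEJ) anneals a pair of short direct
repeats flanking a double-strand break and deletes the intervening
sequence together with one repeat copy.  Given a reference and a cut
site, :func:`find_microhomologies` enumerates every maximal direct-repeat
pair whose implied deletion spans the break; :func:`attribute_deletions`
then marks observed deletions as MMEJ-consistent when they coincide with
a repeat pair's implied deletion.

The deletion implied by a pair with copies starting at ``left_start`` and
``right_start`` removes ``reference[left_start:right_start]`` — size
``right_start - left_start`` — and leaves exactly one copy of the repeat.
In the gliadin target region such repeats of 3-36 bp are pervasive and
explain the over-representation of particular deletion sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

__all__ = ["MicrohomologyPair", "find_microhomologies", "attribute_deletions"]


@dataclass(frozen=True)
class MicrohomologyPair:
    repeat_sequence: str
    left_start: int
    right_start: int
    spans_cut: bool

    @property
    def length(self) -> int:
        return len(self.repeat_sequence)

    @property
    def predicted_deletion_size(self) -> int:
        return self.right_start - self.left_start

    def apply_deletion(self, reference: str) -> str:
        """Return the reference with the implied MMEJ deletion applied."""
        return reference[: self.left_start] + reference[self.right_start :]


def find_microhomologies(
    reference: str,
    cut_site: int,
    min_len: int = 3,
    max_len: int = 36,
    search_radius: int = 200,
    require_spanning: bool = True,
) -> List[MicrohomologyPair]:
    """Enumerate maximal direct-repeat pairs around ``cut_site``.

    A pair is *maximal* when it cannot be extended by one base on either
    side while keeping the two copies identical; each maximal pair is
    reported once, for its full length, provided that length lies in
    ``[min_len, max_len]``.  Both copies must start within
    ``search_radius`` of the cut.  With ``require_spanning`` (default),
    only pairs whose implied deletion can remove the break are kept: some
    placement of the deletion interval, slid across the repeat, contains
    the cut boundary (``left_start <= cut_site <= right_start + length``).

    Results are sorted by predicted deletion size, then position.
    """
    if not 0 <= cut_site <= len(reference):
        raise ValueError("cut_site outside reference")
    if min_len < 1 or max_len < min_len:
        raise ValueError("invalid repeat length bounds")
    ref = reference.upper()
    n = len(ref)
    lo = max(0, cut_site - search_radius)
    hi = min(n, cut_site + search_radius)
    pairs: List[MicrohomologyPair] = []
    for i in range(lo, hi):
        for j in range(i + 1, hi):
            if ref[i] != ref[j]:
                continue
            # left-maximality: the pair cannot be extended 5'
            if i > 0 and ref[i - 1] == ref[j - 1]:
                continue
            # common extension (right-maximal by construction)
            length = 1
            while j + length < n and ref[i + length] == ref[j + length]:
                length += 1
            if not (min_len <= length <= max_len):
                continue
            spans = i <= cut_site <= j + length
            if require_spanning and not spans:
                continue
            pairs.append(MicrohomologyPair(ref[i : i + length], i, j, spans))
    pairs.sort(key=lambda p: (p.predicted_deletion_size, p.left_start, p.right_start))
    return pairs


def attribute_deletions(
    observed: Iterable,
    pairs: Sequence[MicrohomologyPair],
    reference: str,
    tolerance: int = 0,
) -> List[bool]:
    """Mark each observed deletion as MMEJ-consistent or not.

    Deletion calls must carry left-aligned, 0-based half-open ``start``
    and ``end`` coordinates on the same reference the pairs were derived
    from.  With ``tolerance=0`` a deletion is consistent iff its interval
    equals a pair's implied deletion interval under left-alignment
    equivalence; with a positive tolerance, a size match within
    ``tolerance`` plus interval overlap with the pair's sliding range is
    accepted.
    """
    ref = reference.upper()
    flags: List[bool] = []
    for call in observed:
        if getattr(call, "edit_type", "deletion") != "deletion":
            flags.append(False)
            continue
        start, end = call.start, call.end
        if not (0 <= start <= end <= len(ref)):
            raise ValueError("deletion coordinates outside reference")
        size = end - start
        hit = False
        for p in pairs:
            if abs(p.predicted_deletion_size - size) > tolerance:
                continue
            if tolerance == 0:
                # pairs are maximal, so (left_start, right_start) is the
                # left-aligned placement of the implied deletion
                if start == p.left_start and end == p.right_start:
                    hit = True
                    break
            else:
                if start <= p.right_start + p.length and end >= p.left_start:
                    hit = True
                    break
        flags.append(hit)
    return flags
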