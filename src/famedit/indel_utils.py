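"""Left-alignment normalization of indels on a reference.

In repetitive sequence an indel has several equivalent placements that
produce the same edited string; all coordinates in this package use the
5'-most (left-aligned) placement, 0-based half-open, following the usual
variant-normalization convention.
"""

from __future__ import annotations

from typing import Tuple

__all__ = ["left_align_deletion", "left_align_insertion"]


def left_align_deletion(ref: str, start: int, end: int, floor: int = 0) -> Tuple[int, int]:
    """Shift the deleted interval ``[start, end)`` to its 5'-most
    equivalent placement, never crossing ``floor``."""
    while start > floor and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def left_align_insertion(
    ref: str, pos: int, inserted: str, floor: int = 0
) -> Tuple[int, str]:
    """Shift an insertion at ``pos`` to its 5'-most equivalent placement,
    rotating the inserted sequence accordingly."""
    while pos > floor and inserted and inserted[-1] == ref[pos - 1]:
        inserted = ref[pos - 1] + inserted[:-1]
        pos -= 1
    return pos, inserted
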