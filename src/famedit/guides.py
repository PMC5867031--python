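"""Guide RNA definitions and target-site location.

A SpCas9 guide is described by its 20-nt protospacer written 5'->3' with
the NGG PAM immediately 3' of it.  The 12 PAM-proximal nucleotides form
the *seed*, the region where mismatches most strongly abolish cleavage;
the blunt double-strand break falls ``cut_offset`` (canonically 3) bases
5' of the PAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

SEED_LENGTH = 12

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideRNA:
    """A SpCas9 guide: 20-nt protospacer, NGG PAM, blunt cut 3 bp 5' of the PAM."""

    name: str
    protospacer: str
    pam_rule: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self) -> None:
        # 20 nt is the canonical SpCas9 protospacer; truncated guides are
        # accepted down to the 12-nt seed length
        if not SEED_LENGTH <= len(self.protospacer) <= 30:
            raise ValueError(
                f"guide {self.name!r}: protospacer must be {SEED_LENGTH}-30 nt, "
                f"got {len(self.protospacer)}"
            )
        if not (0 < self.cut_offset < len(self.protospacer)):
            raise ValueError(f"guide {self.name!r}: invalid cut_offset")

    @property
    def seed(self) -> str:
        """The 12 PAM-proximal nucleotides of the protospacer."""
        return derive_seed(self)


def derive_seed(guide: GuideRNA) -> str:
    """Return the seed: the 12 nt of the protospacer adjacent to the PAM."""
    if len(guide.protospacer) < SEED_LENGTH:
        raise ValueError(
            f"protospacer of {guide.name!r} is shorter than {SEED_LENGTH} nt"
        )
    return guide.protospacer[-SEED_LENGTH:]


# The two guides used against the alpha-gliadin family.
SGALPHA1 = GuideRNA("sgAlpha-1", "GCCACAAGAGCAAGTTCCAT")
SGALPHA2 = GuideRNA("sgAlpha-2", "GGTTGTGATGGAAATGGTTG")


@dataclass(frozen=True)
class GuideSite:
    """A located protospacer+PAM occurrence on a reference sequence.

    ``cut_site`` is the 0-based position of the first reference base 3' of
    the blunt break on the forward strand (i.e. the break lies between
    ``cut_site - 1`` and ``cut_site``).
    """

    guide_name: str
    start: int
    end: int
    strand: str
    cut_site: int
    mismatches: int
    pam: str


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def locate_guide(
    sequence: str, guide: GuideRNA, max_mismatches: int = 4
) -> Optional[GuideSite]:
    """Locate the best protospacer+NGG occurrence of ``guide`` on either strand.

    The PAM must match NGG exactly; up to ``max_mismatches`` are tolerated
    over the 20-nt protospacer.  Returns the lowest-mismatch site (ties:
    leftmost forward-strand coordinate, then '+' strand), or None.
    """
    sequence = sequence.upper()
    proto = guide.protospacer.upper()
    n, L = len(sequence), len(proto)
    best: Optional[GuideSite] = None
    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        for i in range(0, n - L - 2):
            pam = seq[i + L : i + L + 3]
            if pam[1:3] != "GG":
                continue
            mm = _mismatches(seq[i : i + L], proto)
            if mm > max_mismatches:
                continue
            cut_local = i + L - guide.cut_offset
            if strand == "+":
                start, end, cut = i, i + L + 3, cut_local
            else:
                # map the break boundary back to forward coordinates
                start, end, cut = n - (i + L + 3), n - i, n - cut_local
            site = GuideSite(guide.name, start, end, strand, cut, mm, pam)
            if (
                best is None
                or mm < best.mismatches
                or (mm == best.mismatches and (site.start, strand) < (best.start, best.strand))
            ):
                best = site
    return best
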