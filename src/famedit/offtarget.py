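"""Seed+PAM off-target site scanning.

Potential SpCas9 off-target sites are defined by the guide's minimal
active sequence: the 12-nt seed immediately 5' of an NGG PAM.  The
scanner reports every position, on both strands, where the seed aligns
with at most ``max_mismatches`` mismatches and the PAM matches NGG
exactly (the N position is unconstrained).  Genome mode is the special
case of perfect seed matches (``max_mismatches = 0``).

Ambiguity codes in the database are treated conservatively: an ``N`` (or
any non-ACGT code) never matches a seed base or a PAM G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple, Union

import numpy as np
from Bio import SeqIO

from famedit.guides import GuideRNA, derive_seed, reverse_complement

__all__ = ["OffTargetHit", "scan_seed_pam", "scan_genome_mode"]

SITE_LEN = 15  # 12-nt seed + 3-nt PAM


@dataclass(frozen=True)
class OffTargetHit:
    sequence_id: str
    position: int  # 0-based start of the seed+PAM span on the forward strand
    strand: str
    matched_site: str  # forward-strand bases of the span
    seed_mismatches: int
    pam: str  # PAM as read on the hit strand


def _load_database(
    database: Union[str, Dict[str, str], Iterable[Tuple[str, str]]]
) -> List[Tuple[str, str]]:
    if isinstance(database, dict):
        return list(database.items())
    if isinstance(database, (str, bytes)) or hasattr(database, "read"):
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(database, "fasta")]
    return list(database)


def _scan_strand(seq_arr: np.ndarray, seed: str, max_mismatches: int) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised scan of one strand; returns (positions, mismatch counts)."""
    n = seq_arr.size
    if n < SITE_LEN:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    m = n - SITE_LEN + 1
    gg = (seq_arr[13 : 13 + m] == ord("G")) & (seq_arr[14 : 14 + m] == ord("G"))
    mism = np.zeros(m, dtype=np.int16)
    for k, base in enumerate(seed):
        mism += seq_arr[k : k + m] != ord(base)
    ok = gg & (mism <= max_mismatches)
    pos = np.flatnonzero(ok)
    return pos, mism[pos]


def scan_seed_pam(
    guide: GuideRNA,
    database: Union[str, Dict[str, str], Iterable[Tuple[str, str]]],
    max_mismatches: int = 2,
) -> List[OffTargetHit]:
    """Scan a sequence database for seed+NGG sites of ``guide``.

    ``database`` may be a FASTA path, a dict of id -> sequence, or an
    iterable of (id, sequence) pairs.  Overlapping sites are all
    reported; hits are sorted by (sequence_id, position, strand).
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    seed = derive_seed(guide).upper()
    hits: List[OffTargetHit] = []
    for seq_id, seq in _load_database(database):
        fwd = seq.upper()
        n = len(fwd)
        arr_f = np.frombuffer(fwd.encode(), dtype=np.uint8)
        rev = reverse_complement(fwd)
        arr_r = np.frombuffer(rev.encode(), dtype=np.uint8)
        for strand, arr in (("+", arr_f), ("-", arr_r)):
            pos, mism = _scan_strand(arr, seed, max_mismatches)
            for p, mm in zip(pos, mism):
                p = int(p)
                if strand == "+":
                    fstart = p
                    site = fwd[p : p + SITE_LEN]
                    pam = site[12:]
                else:
                    fstart = n - (p + SITE_LEN)
                    site = fwd[fstart : fstart + SITE_LEN]
                    pam = rev[p + 12 : p + SITE_LEN]
                hits.append(
                    OffTargetHit(seq_id, fstart, strand, site, int(mm), pam)
                )
    hits.sort(key=lambda h: (h.sequence_id, h.position, h.strand))
    return hits


def scan_genome_mode(
    guide: GuideRNA,
    database: Union[str, Dict[str, str], Iterable[Tuple[str, str]]],
) -> List[OffTargetHit]:
    """Whole-genome mode: perfect matches of the 12-nt seed plus PAM."""
    return scan_seed_pam(guide, database, max_mismatches=0)
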