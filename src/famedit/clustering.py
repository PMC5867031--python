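"""Dereplication of merged reads into unique amplicon variants.

Clustering is at 100% identity: a variant cluster is the set of reads
whose sequences are exactly equal, with per-sample read counts n and
frequencies n/N.  Low-support (cluster, sample) entries (n below
``min_reads``) are removed before frequencies are computed, and a
variant counts as *represented* in a sample when its frequency exceeds
``min_frequency`` (default 0.3%).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

__all__ = [
    "VariantCluster",
    "dereplicate",
    "filter_low_support",
    "compute_frequencies",
    "select_represented",
]


@dataclass
class VariantCluster:
    cluster_id: str
    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)
    frequencies: Dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def _ordered(clusters: Iterable[VariantCluster]) -> List[VariantCluster]:
    """Deterministic cluster ordering: total count descending, then sequence."""
    out = sorted(clusters, key=lambda c: (-c.total_count, c.sequence))
    width = max(4, len(str(len(out))))
    for i, c in enumerate(out, start=1):
        c.cluster_id = f"C{i:0{width}d}"
    return out


def dereplicate(merged_reads: Iterable) -> List[VariantCluster]:
    """Collapse reads into one cluster per distinct sequence.

    Reads must carry ``sample_id``; per-sample counts are exact and sum
    to the input read count.
    """
    table: Dict[str, Counter] = defaultdict(Counter)
    for r in merged_reads:
        table[r.sequence][r.sample_id] += 1
    clusters = [
        VariantCluster("", seq, dict(counts)) for seq, counts in table.items()
    ]
    return _ordered(clusters)


def filter_low_support(
    clusters: Iterable[VariantCluster], min_reads: int = 5
) -> Tuple[List[VariantCluster], Set[str]]:
    """Drop (cluster, sample) entries with fewer than ``min_reads`` reads.

    Samples with less than ``min_reads`` in a given cluster are removed
    from that cluster; clusters left with no samples are dropped.
    Returns the surviving clusters and the set of samples that lost all
    their clusters (reported empty).
    """
    before: Set[str] = set()
    kept: List[VariantCluster] = []
    for c in clusters:
        before.update(c.counts)
        counts = {s: n for s, n in c.counts.items() if n >= min_reads}
        if counts:
            kept.append(VariantCluster(c.cluster_id, c.sequence, counts))
    after = set().union(*(c.counts for c in kept)) if kept else set()
    return _ordered(kept), before - after


def compute_frequencies(clusters: Iterable[VariantCluster]) -> List[VariantCluster]:
    """Set frequency = n/N per sample, N being the sample's retained total."""
    clusters = list(clusters)
    totals: Dict[str, int] = defaultdict(int)
    for c in clusters:
        for s, n in c.counts.items():
            totals[s] += n
    for c in clusters:
        c.frequencies = {s: n / totals[s] for s, n in c.counts.items() if totals[s] > 0}
    return clusters


def select_represented(
    clusters: Iterable[VariantCluster], min_frequency: float = 0.003
) -> List[VariantCluster]:
    """Keep (cluster, sample) entries with frequency strictly above
    ``min_frequency``; clusters with no represented sample are dropped."""
    out: List[VariantCluster] = []
    for c in clusters:
        keep = {s for s, f in c.frequencies.items() if f > min_frequency}
        if keep:
            out.append(
                VariantCluster(
                    c.cluster_id,
                    c.sequence,
                    {s: n for s, n in c.counts.items() if s in keep},
                    {s: f for s, f in c.frequencies.items() if s in keep},
                )
            )
    return _ordered(out)
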