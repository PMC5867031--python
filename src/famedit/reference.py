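"""Wild-type reference gene library: construction and annotation.

The alpha-gliadin amplicon is internal to the coding sequence, so every
unique wild-type variant can be translated in a fixed frame and
annotated: pseudogene status (a premature stop codon before the final
codon of the translated span), counts of the three overlapping coeliac
DQ2.5 epitopes of the 33-mer region, and guide match positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from famedit.guides import GuideRNA, GuideSite, locate_guide

__all__ = [
    "ReferenceGene",
    "DEFAULT_EPITOPES",
    "build_reference",
    "classify_pseudogene",
    "count_epitopes",
    "translate_amplicon",
]

# The three tandemly organised 9-mer epitopes of the immunodominant
# 33-mer peptide, as recognised by coeliac-patient T cells.
DEFAULT_EPITOPES: Dict[str, str] = {
    "DQ2.5-glia-a1a": "PFPQPELPY",
    "DQ2.5-glia-a2": "PQPELPYPQ",
    "DQ2.5-glia-a1b": "PYPQPELPY",
}


@dataclass
class ReferenceGene:
    gene_id: str
    sequence: str
    protein: str = ""
    is_pseudogene: bool = False
    premature_stop_aa: Optional[int] = None
    epitope_counts: Dict[str, int] = field(default_factory=dict)
    guide_matches: Dict[str, GuideSite] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


def translate_amplicon(sequence: str, frame: int = 0, span: Optional[Tuple[int, int]] = None) -> str:
    """Translate ``sequence[span]`` in ``frame`` (span defaults to the whole
    sequence trimmed to a codon multiple)."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if span is None:
        start = frame
        end = start + (len(sequence) - start) // 3 * 3
    else:
        start, end = span
        if (end - start) % 3 != 0:
            raise ValueError("translated span length must be a multiple of 3")
    region = sequence[start:end].upper()
    return str(Seq(region).translate())


def classify_pseudogene(
    sequence: str, frame: int = 0, span: Optional[Tuple[int, int]] = None
) -> Tuple[bool, Optional[int]]:
    """Flag a gene as a pseudogene if a stop codon occurs strictly before
    the final codon of the translated span.

    Returns ``(flag, stop_position)`` with the first stop's position in
    0-based amino-acid coordinates (None when no premature stop).  A stop
    at the very last codon does not make a pseudogene.
    """
    protein = translate_amplicon(sequence, frame, span)
    pos = protein.find("*")
    if 0 <= pos < len(protein) - 1:
        return True, pos
    return False, None


def count_epitopes(protein: str, epitopes: Mapping[str, str] = DEFAULT_EPITOPES) -> Dict[str, int]:
    """Count occurrences of each epitope peptide, allowing overlaps.

    Every start position is examined, so tandem 33-mer-like repeats with
    overlapping epitope copies are counted in full.
    """
    counts: Dict[str, int] = {}
    for name, pep in epitopes.items():
        if not pep:
            raise ValueError(f"empty epitope {name!r}")
        k = len(pep)
        counts[name] = sum(
            1 for i in range(len(protein) - k + 1) if protein[i : i + k] == pep
        )
    return counts


def build_reference(
    wt_clusters: Sequence,
    line: str = "WT",
    wt_labels: Optional[set] = None,
    guides: Sequence[GuideRNA] = (),
    frame: int = 0,
    epitopes: Mapping[str, str] = DEFAULT_EPITOPES,
    guide_max_mismatches: int = 4,
) -> List[ReferenceGene]:
    """Build the wild-type unique-gene library from represented clusters.

    One :class:`ReferenceGene` is created per cluster, with stable ids
    ``G{line}_{rank}`` following the deterministic cluster ordering
    (total count descending, then sequence).  If ``wt_labels`` is given,
    any cluster carrying counts for a sample outside that set is rejected
    — the library must be built from wild-type material only.
    """
    if not wt_clusters:
        raise ValueError("empty wild-type input: a reference library is required")
    if wt_labels is not None:
        for c in wt_clusters:
            extra = set(c.counts) - set(wt_labels)
            if extra:
                raise ValueError(
                    f"cluster {c.cluster_id!r} carries non-wild-type samples: {sorted(extra)}"
                )
    width = max(2, len(str(len(wt_clusters))))
    genes: List[ReferenceGene] = []
    for rank, cluster in enumerate(wt_clusters, start=1):
        seq = cluster.sequence
        protein = translate_amplicon(seq, frame)
        flag, stop = classify_pseudogene(seq, frame)
        gene = ReferenceGene(
            gene_id=f"G{line}_{rank:0{width}d}",
            sequence=seq,
            protein=protein,
            is_pseudogene=flag,
            premature_stop_aa=stop,
            epitope_counts=count_epitopes(protein, epitopes),
        )
        for g in guides:
            site = locate_guide(seq, g, max_mismatches=guide_max_mismatches)
            if site is not None:
                gene.guide_matches[g.name] = site
        genes.append(gene)
    return genes
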