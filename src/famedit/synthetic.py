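"""Synthetic gliadin-like families, Cas9-edited allele pools and reads.

This module makes the whole pipeline testable without external data.  It
emulates the structure of the wheat alpha-gliadin amplicon family:

* ~45 paralogous genes diverged from a common ancestor by random SNPs,
  all carrying the guide target region in a conserved block (the guides
  were designed against conserved sequence, so by default the
  protospacer+PAM is excluded from divergence);
* a 33-mer-like region built from tandem repeats of the three DQ2.5
  epitope codings, with a per-gene repeat number that makes paralogs
  length-distinct;
* a configurable fraction of pseudogenes carrying an engineered in-frame
  premature stop codon.  Paralog SNPs are resampled when they would
  create a stop, mimicking purifying selection, so the pseudogene count
  is exactly the planted one;
* Cas9-induced indels concentrated at the cut site, with deletion sizes
  drawn from a weight table in which microhomology-consistent sizes can
  be enriched (``mmej_bias``), and insertions copied from a
  transformation vector, another family member, or random sequence;
* paired-end reads with Phred+33 qualities and substitution-type
  sequencing error at the rate implied by the emitted quality scores.

Every simulated allele and read is tracked in a truth table, so
recovered mutation spectra can be compared with the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from famedit.guides import GuideRNA, SGALPHA2, locate_guide, reverse_complement
from famedit.mmej import find_microhomologies
from famedit.reference import (
    ReferenceGene,
    classify_pseudogene,
    count_epitopes,
    translate_amplicon,
)
from famedit.indel_utils import left_align_deletion, left_align_insertion

__all__ = [
    "FamilyConfig",
    "EditProfile",
    "TruthRecord",
    "TruthTable",
    "Allele",
    "SyntheticFamily",
    "SampleReads",
    "ReadPair",
    "generate_family",
    "apply_edits",
    "simulate_reads",
    "write_fasta",
    "write_fastq_pair",
    "default_vector",
]

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ("TAA", "TAG", "TGA")

# fixed codon choices used to reverse-translate the epitope peptides
_CODON = {"P": "CCA", "F": "TTT", "Q": "CAA", "E": "GAG", "L": "CTT", "Y": "TAT"}

# the 33-mer's three tandem epitopes, concatenated into one repeat unit
_EPITOPE_UNIT_PEPTIDE = "PFPQPELPY" + "PQPELPYPQ" + "PYPQPELPY"
EPITOPE_UNIT = "".join(_CODON[aa] for aa in _EPITOPE_UNIT_PEPTIDE)  # 81 nt

_LEFT_FLANK_LEN = 180  # nt; the protospacer+PAM is planted at 129..151
_GUIDE_PLANT_POS = 129


@dataclass(frozen=True)
class FamilyConfig:
    """Parameters of a simulated gliadin-like gene family.

    ``gene_length`` is the length of the constant backbone (flanks) in
    bases; the total gene length is ``gene_length + 81 * repeats`` where
    the per-gene epitope repeat number is drawn uniformly from
    ``epitope_repeat_range``.
    """

    n_genes: int = 45
    gene_length: int = 270
    snp_rate: float = 0.02
    pseudogene_fraction: float = 0.4
    epitope_repeat_range: Tuple[int, int] = (1, 3)
    rng_seed: int = 0
    guide: GuideRNA = SGALPHA2
    conserve_target: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise ValueError("pseudogene_fraction must be in [0, 1]")
        if not 0.0 <= self.snp_rate < 1.0:
            raise ValueError("snp_rate must be in [0, 1)")
        lo, hi = self.epitope_repeat_range
        if lo < 1 or hi < lo:
            raise ValueError("epitope_repeat_range must satisfy 1 <= min <= max")
        if self.gene_length % 3 != 0 or self.gene_length < _LEFT_FLANK_LEN + 30:
            raise ValueError(
                f"gene_length must be a multiple of 3 and >= {_LEFT_FLANK_LEN + 30}"
            )


def _default_size_weights(max_size: int, scale: float) -> Dict[int, float]:
    return {s: math.exp(-s / scale) for s in range(1, max_size + 1)}


@dataclass(frozen=True)
class EditProfile:
    """Distribution of Cas9 editing outcomes at the cut site.

    ``nhej_fraction`` is the proportion of alleles of each targeted gene
    that carry an indel; ``deletion_size_weights`` /
    ``insertion_size_weights`` are unnormalised weights over deletion
    sizes 1-126 and insertion sizes 1-158 (the observed ranges);
    ``mmej_bias`` multiplies the weight of deletion sizes predicted by a
    flanking microhomology pair, and such deletions are placed at the
    repeat; ``insertion_origin_mix`` gives (vector, family, random)
    proportions for the copied insertion sequence.
    """

    nhej_fraction: float = 0.75
    deletion_size_weights: Optional[Dict[int, float]] = None
    insertion_size_weights: Optional[Dict[int, float]] = None
    insertion_fraction: float = 0.19
    mmej_bias: float = 5.0
    insertion_origin_mix: Tuple[float, float, float] = (0.5, 0.5, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.nhej_fraction <= 1.0:
            raise ValueError("nhej_fraction must be in [0, 1]")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise ValueError("insertion_fraction must be in [0, 1]")
        if self.mmej_bias < 0:
            raise ValueError("mmej_bias must be nonnegative")
        if abs(sum(self.insertion_origin_mix) - 1.0) > 1e-9 or any(
            p < 0 for p in self.insertion_origin_mix
        ):
            raise ValueError("insertion_origin_mix must be nonnegative and sum to 1")
        for weights, limit, label in (
            (self.deletion_size_weights, 126, "deletion"),
            (self.insertion_size_weights, 158, "insertion"),
        ):
            if weights is None:
                continue
            if not weights:
                raise ValueError(f"empty {label}_size_weights")
            for s, w in weights.items():
                if not 1 <= s <= limit:
                    raise ValueError(f"{label} size {s} outside [1, {limit}]")
                if w < 0:
                    raise ValueError(f"negative {label} weight for size {s}")

    def deletion_weights(self) -> Dict[int, float]:
        if self.deletion_size_weights is not None:
            return dict(self.deletion_size_weights)
        return _default_size_weights(126, 15.0)

    def insertion_weights(self) -> Dict[int, float]:
        if self.insertion_size_weights is not None:
            return dict(self.insertion_size_weights)
        return _default_size_weights(158, 30.0)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated allele."""

    allele_id: str
    gene_id: str
    edit_type: str  # none | deletion | insertion
    size: int  # signed: deletions negative, insertions positive
    start: int  # 0-based half-open on the parent reference (left-aligned)
    end: int
    inserted_sequence: str
    origin: str  # vector | family | random | "" for unedited/deletions

    @property
    def is_edited(self) -> bool:
        return self.edit_type != "none"


@dataclass
class TruthTable:
    records: List[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_allele(self) -> Dict[str, TruthRecord]:
        return {r.allele_id: r for r in self.records}

    @property
    def nhej_fraction(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.is_edited for r in self.records) / len(self.records)

    def to_tsv(self, path) -> None:
        cols = [
            "allele_id", "gene_id", "edit_type", "size",
            "start", "end", "inserted_sequence", "origin",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                fh.write(
                    f"{r.allele_id}\t{r.gene_id}\t{r.edit_type}\t{r.size}\t"
                    f"{r.start}\t{r.end}\t{r.inserted_sequence}\t{r.origin}\n"
                )


@dataclass(frozen=True)
class Allele:
    allele_id: str
    gene_id: str
    sequence: str
    record: TruthRecord


@dataclass
class SyntheticFamily:
    genes: List[ReferenceGene]
    config: FamilyConfig
    planted_pseudogenes: Tuple[str, ...]
    epitope_repeats: Dict[str, int]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene(self, gene_id: str) -> ReferenceGene:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def write_fasta(self, path) -> None:
        write_fasta(self.genes, path)


def write_fasta(genes: Iterable[ReferenceGene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")


def _random_sense_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _apply_snps(
    seq: List[str], rng: np.random.Generator, snp_rate: float, protected: range
) -> None:
    """Substitute bases in place at snp_rate, never creating a stop codon."""
    if snp_rate <= 0:
        return
    hits = np.flatnonzero(rng.random(len(seq)) < snp_rate)
    bases = "ACGT"
    for p in hits:
        p = int(p)
        if p in protected:
            continue
        codon_start = p - p % 3
        alts = [b for b in bases if b != seq[p]]
        order = rng.permutation(len(alts))
        for k in order:
            old = seq[p]
            seq[p] = alts[int(k)]
            codon = "".join(seq[codon_start : codon_start + 3])
            if codon not in _STOP_CODONS:
                break
            seq[p] = old


def generate_family(config: FamilyConfig) -> SyntheticFamily:
    """Generate a paralogous gene family with a known truth table.

    All genes share one ancestor backbone carrying the guide target; they
    differ by i.i.d. substitutions at ``snp_rate`` (outside the conserved
    target when ``conserve_target``) and by their epitope repeat number.
    Exactly ``round(n_genes * pseudogene_fraction)`` genes receive an
    engineered premature stop codon in the 3' flank.  Deterministic under
    ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_genes
    if n == 0:
        return SyntheticFamily([], config, (), {})

    proto_pam = config.guide.protospacer + "TGG"
    left = list(_random_sense_codons(rng, _LEFT_FLANK_LEN // 3))
    left = list("".join(left))
    left[_GUIDE_PLANT_POS : _GUIDE_PLANT_POS + len(proto_pam)] = list(proto_pam)
    right_len = config.gene_length - _LEFT_FLANK_LEN
    right = _random_sense_codons(rng, right_len // 3)
    left_str = "".join(left)

    lo, hi = config.epitope_repeat_range
    repeats = rng.integers(lo, hi + 1, size=n)
    n_pseudo = int(round(n * config.pseudogene_fraction))
    pseudo_idx = set(int(i) for i in rng.choice(n, size=n_pseudo, replace=False))
    protected = (
        range(_GUIDE_PLANT_POS, _GUIDE_PLANT_POS + len(proto_pam))
        if config.conserve_target
        else range(0)
    )

    width = max(2, len(str(n)))
    genes: List[ReferenceGene] = []
    planted: List[str] = []
    repeat_map: Dict[str, int] = {}
    seen: Dict[str, int] = {}
    for i in range(n):
        r = int(repeats[i])
        base = left_str + EPITOPE_UNIT * r + right
        for attempt in range(100):
            seq = list(base)
            _apply_snps(seq, rng, config.snp_rate, protected)
            if i in pseudo_idx:
                # engineered premature stop in the 3' flank, never the
                # final codon and never inside the conserved target
                first = (_LEFT_FLANK_LEN + 81 * r) // 3
                last = len(seq) // 3 - 2
                codon_i = int(rng.integers(first, last + 1))
                stop = _STOP_CODONS[int(rng.integers(0, 3))]
                seq[codon_i * 3 : codon_i * 3 + 3] = list(stop)
            s = "".join(seq)
            if s not in seen or config.snp_rate == 0:
                break
        seen[s] = i
        gene_id = f"SIM_{i + 1:0{width}d}"
        protein = translate_amplicon(s)
        flag, stop_aa = classify_pseudogene(s)
        gene = ReferenceGene(
            gene_id=gene_id,
            sequence=s,
            protein=protein,
            is_pseudogene=flag,
            premature_stop_aa=stop_aa,
            epitope_counts=count_epitopes(protein),
        )
        site = locate_guide(s, config.guide)
        if site is not None:
            gene.guide_matches[config.guide.name] = site
        genes.append(gene)
        repeat_map[gene_id] = r
        if i in pseudo_idx:
            planted.append(gene_id)
    return SyntheticFamily(genes, config, tuple(planted), repeat_map)


@lru_cache(maxsize=1)
def default_vector(length: int = 3000) -> str:
    """A synthetic stand-in for the transformation vector sequence,
    generated from a fixed seed (used as the default source of
    vector-derived insertions)."""
    rng = np.random.default_rng(0xFA9ED17)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _sample_size(
    rng: np.random.Generator, sizes: np.ndarray, probs: np.ndarray
) -> int:
    return int(rng.choice(sizes, p=probs))


def apply_edits(
    family: Union[SyntheticFamily, Sequence[ReferenceGene]],
    guide: GuideRNA,
    profile: EditProfile,
    rng_seed: int = 0,
    alleles_per_gene: int = 4,
    target_genes: Union[None, int, Sequence[str]] = None,
    vector: Optional[str] = None,
    guide_max_mismatches: int = 4,
    mmej_min_len: int = 3,
    mmej_max_len: int = 36,
    mmej_search_radius: int = 200,
) -> Tuple[List[Allele], TruthTable]:
    """Create an allele pool with Cas9 edits and its truth table.

    Each gene contributes ``alleles_per_gene`` allele copies, emulating
    the fixed complement of gene copies in a single plant.  For each
    targeted gene, ``round(nhej_fraction * alleles_per_gene)`` copies
    (chosen at random) carry exactly one indel overlapping the cut site;
    the rest stay wild type.  ``target_genes`` may be a list of gene ids,
    an integer number of genes to draw at random, or None for all
    targetable genes.  Deletion sizes follow the profile weights with
    ``mmej_bias`` applied to microhomology-predicted sizes; such
    deletions are placed at the predicting repeat pair.  Truth
    coordinates are left-aligned on the parent reference.
    """
    genes = list(family.genes) if isinstance(family, SyntheticFamily) else list(family)
    if alleles_per_gene < 1:
        raise ValueError("alleles_per_gene must be >= 1")
    rng = np.random.default_rng(rng_seed)

    sites = {}
    for g in genes:
        site = g.guide_matches.get(guide.name) or locate_guide(
            g.sequence, guide, max_mismatches=guide_max_mismatches
        )
        if site is not None:
            sites[g.gene_id] = site
    if genes and not sites:
        raise ValueError(f"guide {guide.name!r} matches no gene in the family")

    targetable = [g for g in genes if g.gene_id in sites]
    if target_genes is None:
        targets = {g.gene_id for g in targetable}
    elif isinstance(target_genes, int):
        if target_genes > len(targetable):
            raise ValueError("target_genes exceeds the number of targetable genes")
        picked = rng.choice(len(targetable), size=target_genes, replace=False)
        targets = {targetable[int(i)].gene_id for i in picked}
    else:
        targets = set(target_genes)
        missing = targets - set(sites)
        if missing:
            raise ValueError(f"guide {guide.name!r} has no site in genes {sorted(missing)}")

    del_w = profile.deletion_weights()
    ins_w = profile.insertion_weights()
    vec = vector if vector is not None else default_vector()

    pool: List[Allele] = []
    records: List[TruthRecord] = []
    other_gene_seqs = [g.sequence for g in genes]
    for g in genes:
        seq = g.sequence
        is_target = g.gene_id in targets
        n_edit = int(round(profile.nhej_fraction * alleles_per_gene)) if is_target else 0
        edit_copies = set(
            int(i) for i in rng.choice(alleles_per_gene, size=n_edit, replace=False)
        )
        cut = sites[g.gene_id].cut_site if g.gene_id in sites else None
        pairs = (
            find_microhomologies(
                seq, cut, mmej_min_len, mmej_max_len, mmej_search_radius
            )
            if cut is not None
            else []
        )
        pairs_by_size: Dict[int, list] = {}
        for p in pairs:
            if 1 <= p.predicted_deletion_size <= max(del_w):
                pairs_by_size.setdefault(p.predicted_deletion_size, []).append(p)
        sizes = np.array(sorted(del_w), dtype=int)
        weights = np.array(
            [
                del_w[s] * (profile.mmej_bias if s in pairs_by_size else 1.0)
                for s in sizes
            ]
        )
        del_probs = weights / weights.sum()
        ins_sizes = np.array(sorted(ins_w), dtype=int)
        iw = np.array([ins_w[s] for s in ins_sizes], dtype=float)
        ins_probs = iw / iw.sum()

        for copy in range(alleles_per_gene):
            allele_id = f"{g.gene_id}.{copy + 1}"
            if copy not in edit_copies:
                rec = TruthRecord(allele_id, g.gene_id, "none", 0, 0, 0, "", "")
                pool.append(Allele(allele_id, g.gene_id, seq, rec))
                records.append(rec)
                continue
            if rng.random() < profile.insertion_fraction:
                size = _sample_size(rng, ins_sizes, ins_probs)
                origin = ("vector", "family", "random")[
                    int(rng.choice(3, p=profile.insertion_origin_mix))
                ]
                if origin == "vector":
                    start = int(rng.integers(0, len(vec) - size + 1))
                    ins = vec[start : start + size]
                elif origin == "family":
                    donors = [s for s in other_gene_seqs if s != seq] or [seq]
                    donor = donors[int(rng.integers(0, len(donors)))]
                    start = int(rng.integers(0, len(donor) - size + 1))
                    ins = donor[start : start + size]
                else:
                    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
                pos, ins_norm = left_align_insertion(seq, cut, ins)
                edited = seq[:cut] + ins + seq[cut:]
                rec = TruthRecord(
                    allele_id, g.gene_id, "insertion", size, pos, pos, ins_norm, origin
                )
            else:
                size = _sample_size(rng, sizes, del_probs)
                if size in pairs_by_size:
                    cand = pairs_by_size[size]
                    p = cand[int(rng.integers(0, len(cand)))]
                    start, end = p.left_start, p.right_start
                else:
                    lo_s = max(1, cut - size)
                    hi_s = min(cut, len(seq) - size - 1)
                    start = int(rng.integers(lo_s, hi_s + 1)) if hi_s >= lo_s else lo_s
                    end = start + size
                edited = seq[:start] + seq[end:]
                nstart, nend = left_align_deletion(seq, start, end)
                rec = TruthRecord(
                    allele_id, g.gene_id, "deletion", -size, nstart, nend, "", ""
                )
            pool.append(Allele(allele_id, g.gene_id, edited, rec))
            records.append(rec)
    return pool, TruthTable(records)


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray


@dataclass
class SampleReads:
    sample_id: str
    pairs: List[ReadPair]
    read_allele: Dict[str, str]  # read_id -> allele_id
    truth: TruthTable

    @property
    def true_nhej_percent(self) -> float:
        """Percent of simulated reads drawn from an edited allele."""
        if not self.pairs:
            return float("nan")
        by = self.truth.by_allele()
        edited = sum(1 for rid, aid in self.read_allele.items() if by[aid].is_edited)
        return 100.0 * edited / len(self.pairs)


def _inject_errors(
    template: str, rng: np.random.Generator, p: float
) -> str:
    if p <= 0:
        return template
    k = rng.binomial(len(template), p)
    if k == 0:
        return template
    pos = rng.choice(len(template), size=k, replace=False)
    seq = list(template)
    for j in pos:
        j = int(j)
        alts = [b for b in "ACGT" if b != seq[j]]
        seq[j] = alts[int(rng.integers(0, 3))]
    return "".join(seq)


def simulate_reads(
    pool: Sequence[Allele],
    depth: int,
    error_profile: Union[None, int, float] = 30,
    read_length: int = 280,
    rng_seed: int = 0,
    min_overlap: int = 20,
    sample_id: str = "S1",
    truth: Optional[TruthTable] = None,
) -> SampleReads:
    """Simulate ``depth`` paired-end reads uniformly over the allele pool.

    Each mate covers ``min(read_length, amplicon_length)`` bases from its
    end of the amplicon; mate 2 is reverse-complemented.  Errors are
    substitution-only, injected at the rate implied by the uniform Phred
    quality ``error_profile`` (``None`` or 0 disables errors and emits
    Q40).  Raises if an unedited amplicon cannot provide ``min_overlap``
    bases of mate overlap at the configured read length.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if truth is None:
        truth = TruthTable([a.record for a in pool])
    rng = np.random.default_rng(rng_seed)
    if error_profile is None or error_profile == 0:
        q, p = 40, 0.0
    else:
        q = int(error_profile)
        if q < 2:
            raise ValueError("error_profile must be a Phred score >= 2, or 0/None")
        p = 10.0 ** (-q / 10.0)

    for a in pool:
        if not a.record.is_edited:
            L = len(a.sequence)
            rl = min(read_length, L)
            if 2 * rl - L < min_overlap:
                raise ValueError(
                    f"unedited amplicon {a.allele_id} ({L} bp) leaves mate overlap "
                    f"{2 * rl - L} < min_overlap={min_overlap} at read_length={read_length}"
                )

    pairs: List[ReadPair] = []
    read_allele: Dict[str, str] = {}
    if depth == 0 or not pool:
        return SampleReads(sample_id, pairs, read_allele, truth)

    idx = rng.integers(0, len(pool), size=depth)
    qual_cache: Dict[int, np.ndarray] = {}
    width = len(str(depth))
    for r, ai in enumerate(idx):
        a = pool[int(ai)]
        L = len(a.sequence)
        rl = min(read_length, L)
        if rl not in qual_cache:
            qual_cache[rl] = np.full(rl, q, dtype=np.int16)
        quals = qual_cache[rl]
        m1 = _inject_errors(a.sequence[:rl], rng, p)
        m2 = _inject_errors(reverse_complement(a.sequence[L - rl :]), rng, p)
        rid = f"{sample_id}_{r + 1:0{width}d}"
        pairs.append(ReadPair(rid, m1, quals, m2, quals))
        read_allele[rid] = a.allele_id
    return SampleReads(sample_id, pairs, read_allele, truth)


def write_fastq_pair(sample: SampleReads, path1, path2) -> None:
    """Write mates to two Phred+33 FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rp in sample.pairs:
            q1 = "".join(chr(33 + int(x)) for x in rp.qual1)
            q2 = "".join(chr(33 + int(x)) for x in rp.qual2)
            f1.write(f"@{rp.read_id}/1\n{rp.seq1}\n+\n{q1}\n")
            f2.write(f"@{rp.read_id}/2\n{rp.seq2}\n+\n{q2}\n")
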