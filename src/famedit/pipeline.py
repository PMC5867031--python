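"""End-to-end orchestration of the amplicon genotyping workflow.

``run_analysis`` is the in-memory core: it takes per-sample read pairs
(wild type and mutant), merges and quality-filters them, dereplicates
all samples jointly at 100% identity, applies the read-support and
representation thresholds, builds the wild-type reference library,
assigns mutant variants and calls indels, attributes deletions to
microhomology, and returns per-sample mutation spectra.

``run_pipeline`` is the file-based wrapper used by the CLI: it reads a
YAML config with a sample manifest and guide definitions, runs the same
core, and writes the report bundle (TSV tables plus a run log with
every threshold).
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from famedit import __version__
from famedit.calling import (
    Assignment,
    IndelCall,
    MutationSpectrum,
    assign_reference,
    call_indels,
    classify_insertion_origin,
    make_aligner,
    summarize_spectrum,
)
from famedit.clustering import (
    VariantCluster,
    compute_frequencies,
    dereplicate,
    filter_low_support,
    select_represented,
)
from famedit.guides import GuideRNA
from famedit.mmej import attribute_deletions, find_microhomologies
from famedit.read_prep import MergedRead, expected_error_filter, merge_pairs, read_fastq
from famedit.reference import ReferenceGene, build_reference

__all__ = ["PipelineParams", "PipelineResult", "run_analysis", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the workflow, logged with every run."""

    min_overlap: int = 20
    max_diff_fraction: float = 0.25
    max_ee: float = 1.0
    min_reads: int = 5
    min_frequency: float = 0.003
    cut_window: int = 20
    mmej_min_len: int = 3
    mmej_max_len: int = 36
    mmej_search_radius: int = 200
    mmej_tolerance: int = 0
    min_identity: float = 0.5
    prescreen: int = 0
    frame: int = 0
    insertion_origin_min_len: int = 10
    line: str = "WT"


@dataclass
class SampleQC:
    sample_id: str
    input_pairs: int = 0
    merged: int = 0
    merge_rejected: int = 0
    ee_rejected: int = 0

    @property
    def retained(self) -> int:
        return self.merged - self.ee_rejected


@dataclass
class PipelineResult:
    params: PipelineParams
    qc: Dict[str, SampleQC]
    clusters: List[VariantCluster]  # represented clusters, all samples
    library: List[ReferenceGene]
    assignments: Dict[str, Assignment]  # cluster_id -> assignment (mutant variants)
    variant_calls: Dict[str, List[IndelCall]]
    spectra: Dict[str, MutationSpectrum]  # mutant samples
    mmej_fraction: Dict[str, Optional[float]]  # sample -> MMEJ-consistent read fraction
    empty_samples: set = field(default_factory=set)

    @property
    def wt_variant_count(self) -> int:
        return len(self.library)

    @property
    def pseudogene_count(self) -> int:
        return sum(g.is_pseudogene for g in self.library)

    def mutated_gene_count(self, pooled: bool = True) -> int:
        """Distinct reference genes with a represented mutant derivative,
        pooled over all mutant samples (or the max per sample)."""
        if pooled:
            genes = set()
            for s in self.spectra.values():
                genes |= s.mutated_genes
            return len(genes)
        return max((s.mutated_gene_count for s in self.spectra.values()), default=0)


def _merge_sample(
    sample_id: str, pairs: Sequence, params: PipelineParams
) -> Tuple[List[MergedRead], SampleQC]:
    qc = SampleQC(sample_id, input_pairs=len(pairs))
    merged: List[MergedRead] = []
    cache: Dict[Tuple, Tuple[Optional[Tuple[str, tuple]], str]] = {}
    for rp in pairs:
        key = (rp.seq1, rp.qual1.tobytes(), rp.seq2, rp.qual2.tobytes())
        if key in cache:
            payload, reason = cache[key]
        else:
            m, reason = merge_pairs(
                rp.seq1,
                rp.qual1,
                rp.seq2,
                rp.qual2,
                min_overlap=params.min_overlap,
                max_diff_fraction=params.max_diff_fraction,
            )
            payload = (m.sequence, tuple(int(x) for x in m.qualities)) if m else None
            cache[key] = (payload, reason)
        if payload is None:
            qc.merge_rejected += 1
            continue
        qc.merged += 1
        merged.append(MergedRead(payload[0], list(payload[1]), sample_id, rp.read_id))
    kept, rejected = expected_error_filter(merged, max_ee=params.max_ee)
    qc.ee_rejected = rejected
    return kept, qc


def _restrict(clusters: Sequence[VariantCluster], samples: set) -> List[VariantCluster]:
    out = []
    for c in clusters:
        counts = {s: n for s, n in c.counts.items() if s in samples}
        if counts:
            out.append(
                VariantCluster(
                    c.cluster_id,
                    c.sequence,
                    counts,
                    {s: f for s, f in c.frequencies.items() if s in samples},
                )
            )
    return out


def run_analysis(
    wt_samples: Mapping[str, Sequence],
    mutant_samples: Mapping[str, Sequence],
    guide: GuideRNA,
    vectors: Sequence[str] = (),
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run the complete analysis on in-memory read pairs.

    ``wt_samples`` and ``mutant_samples`` map sample labels to sequences
    of read pairs (objects with seq1/qual1/seq2/qual2, e.g.
    :class:`famedit.synthetic.ReadPair`).  The wild-type samples define
    the reference library; spectra are computed for mutant samples.
    """
    overlap = set(wt_samples) & set(mutant_samples)
    if overlap:
        raise ValueError(f"samples labelled both WT and mutant: {sorted(overlap)}")

    merged_all: List[MergedRead] = []
    qc: Dict[str, SampleQC] = {}
    for sample_id, pairs in list(wt_samples.items()) + list(mutant_samples.items()):
        kept, sample_qc = _merge_sample(sample_id, pairs, params)
        merged_all.extend(kept)
        qc[sample_id] = sample_qc

    clusters = dereplicate(merged_all)
    clusters, empty = filter_low_support(clusters, min_reads=params.min_reads)
    clusters = compute_frequencies(clusters)
    represented = select_represented(clusters, min_frequency=params.min_frequency)

    wt_set, mut_set = set(wt_samples), set(mutant_samples)
    wt_clusters = _restrict(represented, wt_set)
    wt_clusters.sort(key=lambda c: (-c.total_count, c.sequence))
    library = build_reference(
        wt_clusters,
        line=params.line,
        wt_labels=wt_set,
        guides=[guide],
        frame=params.frame,
    )

    aligner = make_aligner()
    assignments: Dict[str, Assignment] = {}
    variant_calls: Dict[str, List[IndelCall]] = {}
    mut_clusters = _restrict(represented, mut_set)
    family_seqs = [g.sequence for g in library]
    lib_by_id = {g.gene_id: g for g in library}
    for c in mut_clusters:
        asg = assign_reference(
            c.sequence,
            library,
            variant_id=c.cluster_id,
            aligner=aligner,
            min_identity=params.min_identity,
            prescreen=params.prescreen,
        )
        assignments[c.cluster_id] = asg
        if not asg.assigned:
            continue
        gene = lib_by_id[asg.gene_id]
        site = gene.guide_matches.get(guide.name)
        calls = call_indels(
            asg.alignment,
            site,
            cut_window=params.cut_window,
            variant_id=c.cluster_id,
            gene_id=asg.gene_id,
        )
        final = []
        for call in calls:
            if call.edit_type == "insertion":
                origin = classify_insertion_origin(
                    call.inserted_sequence,
                    vectors=vectors,
                    family=[s for s in family_seqs if s != gene.sequence],
                    min_length=params.insertion_origin_min_len,
                )
                call = dataclasses.replace(call, origin=origin)
            final.append(call)
        variant_calls[c.cluster_id] = final

    spectra = summarize_spectrum(variant_calls, assignments, mut_clusters)
    for s in mut_set:
        spectra.setdefault(s, MutationSpectrum(s))

    # MMEJ attribution of proximal deletions, read-weighted per sample
    pair_cache: Dict[str, list] = {}
    consistent_reads: Dict[str, int] = {s: 0 for s in mut_set}
    deletion_reads: Dict[str, int] = {s: 0 for s in mut_set}
    for c in mut_clusters:
        asg = assignments.get(c.cluster_id)
        if asg is None or not asg.assigned:
            continue
        gene = lib_by_id[asg.gene_id]
        site = gene.guide_matches.get(guide.name)
        if site is None:
            continue
        dels = [
            k
            for k in variant_calls.get(c.cluster_id, [])
            if k.edit_type == "deletion" and k.proximal
        ]
        if not dels:
            continue
        if asg.gene_id not in pair_cache:
            pair_cache[asg.gene_id] = find_microhomologies(
                gene.sequence,
                site.cut_site,
                params.mmej_min_len,
                params.mmej_max_len,
                params.mmej_search_radius,
            )
        flags = attribute_deletions(
            dels, pair_cache[asg.gene_id], gene.sequence, tolerance=params.mmej_tolerance
        )
        for sample_id, n in c.counts.items():
            deletion_reads[sample_id] += n * len(dels)
            consistent_reads[sample_id] += n * sum(flags)
    mmej_fraction = {
        s: (consistent_reads[s] / deletion_reads[s] if deletion_reads[s] else None)
        for s in mut_set
    }

    return PipelineResult(
        params=params,
        qc=qc,
        clusters=represented,
        library=library,
        assignments=assignments,
        variant_calls=variant_calls,
        spectra=spectra,
        mmej_fraction=mmej_fraction,
        empty_samples=empty,
    )


# ---------------------------------------------------------------------------
# file-based wrapper


@dataclass
class _FilePair:
    read_id: str
    seq1: str
    qual1: "object"
    seq2: str
    qual2: "object"


def _load_sample(r1_path: str, r2_path: str) -> List[_FilePair]:
    import numpy as np

    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in read count: {r1_path}, {r2_path}")
    return [
        _FilePair(id1, s1, np.asarray(q1), s2, np.asarray(q2))
        for (id1, s1, q1), (_, s2, q2) in zip(r1, r2)
    ]


def run_pipeline(config_path, out_dir=None) -> PipelineResult:
    """Run the pipeline from a YAML config; write the report bundle.

    Config keys: ``samples`` (list of {id, role: wt|mutant, r1, r2}),
    ``guide`` ({name, protospacer}), optional ``vector_fasta`` (list of
    paths), optional ``params`` (PipelineParams fields), ``output_dir``.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent
    params = PipelineParams(**cfg.get("params", {}))
    gcfg = cfg["guide"]
    guide = GuideRNA(gcfg["name"], gcfg["protospacer"])
    vectors: List[str] = []
    from Bio import SeqIO

    for vp in cfg.get("vector_fasta", []):
        vectors.extend(str(r.seq) for r in SeqIO.parse(base / vp, "fasta"))
    wt, mut = {}, {}
    for s in cfg["samples"]:
        dest = wt if s["role"].lower() in ("wt", "wild-type", "wildtype") else mut
        dest[s["id"]] = _load_sample(base / s["r1"], base / s["r2"])
    result = run_analysis(wt, mut, guide, vectors=vectors, params=params)

    out = Path(out_dir or cfg.get("output_dir", "famedit_out"))
    out.mkdir(parents=True, exist_ok=True)
    write_report(result, out, guide)
    return result


def write_report(result: PipelineResult, out_dir, guide: GuideRNA) -> None:
    """Write the TSV report bundle and the self-describing run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = sorted(
        {s for c in result.clusters for s in c.counts}
        | set(result.qc)
    )
    with open(out / "clusters.tsv", "w") as fh:
        head = ["cluster_id", "length"]
        head += [f"n_{s}" for s in samples] + [f"freq_{s}" for s in samples]
        fh.write("\t".join(head + ["sequence"]) + "\n")
        for c in result.clusters:
            row = [c.cluster_id, str(len(c))]
            row += [str(c.counts.get(s, 0)) for s in samples]
            row += [f"{c.frequencies.get(s, 0.0):.6f}" for s in samples]
            fh.write("\t".join(row + [c.sequence]) + "\n")
    with open(out / "library.tsv", "w") as fh:
        ep_names = sorted(next(iter(result.library)).epitope_counts) if result.library else []
        fh.write(
            "\t".join(
                ["gene_id", "length", "is_pseudogene", "premature_stop_aa"]
                + ep_names
                + ["guide_site", "guide_cut"]
            )
            + "\n"
        )
        for g in result.library:
            site = g.guide_matches.get(guide.name)
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        str(len(g)),
                        str(int(g.is_pseudogene)),
                        "" if g.premature_stop_aa is None else str(g.premature_stop_aa),
                    ]
                    + [str(g.epitope_counts.get(e, 0)) for e in ep_names]
                    + [
                        "" if site is None else f"{site.start}-{site.end}({site.strand})",
                        "" if site is None else str(site.cut_site),
                    ]
                )
                + "\n"
            )
    with open(out / "library.fasta", "w") as fh:
        for g in result.library:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")
    with open(out / "calls.tsv", "w") as fh:
        fh.write(
            "variant_id\tgene_id\tedit_type\tsize\tstart\tend\t"
            "inserted_sequence\torigin\tdistance_to_cut\tproximal\n"
        )
        for cid in sorted(result.variant_calls):
            for k in result.variant_calls[cid]:
                fh.write(
                    f"{k.variant_id}\t{k.gene_id}\t{k.edit_type}\t{k.size}\t"
                    f"{k.start}\t{k.end}\t{k.inserted_sequence}\t{k.origin}\t"
                    f"{'' if k.distance_to_cut is None else k.distance_to_cut}\t"
                    f"{int(k.proximal)}\n"
                )
    with open(out / "spectra.tsv", "w") as fh:
        fh.write(
            "sample_id\tassigned_reads\tmutant_reads\tunassigned_reads\t"
            "nhej_percent\tmutated_gene_count\tmmej_consistent_fraction\n"
        )
        for s in sorted(result.spectra):
            spec = result.spectra[s]
            nhej = spec.nhej_percent
            mm = result.mmej_fraction.get(s)
            fh.write(
                f"{s}\t{spec.assigned_reads}\t{spec.mutant_reads}\t"
                f"{spec.unassigned_reads}\t"
                f"{'' if nhej is None else f'{nhej:.4f}'}\t"
                f"{spec.mutated_gene_count}\t"
                f"{'' if mm is None else f'{mm:.4f}'}\n"
            )
    with open(out / "qc.tsv", "w") as fh:
        fh.write("sample_id\tinput_pairs\tmerged\tmerge_rejected\tee_rejected\tretained\n")
        for s in sorted(result.qc):
            q = result.qc[s]
            fh.write(
                f"{s}\t{q.input_pairs}\t{q.merged}\t{q.merge_rejected}\t"
                f"{q.ee_rejected}\t{q.retained}\n"
            )
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"famedit {__version__} (python {sys.version.split()[0]})\n")
        fh.write(f"guide\t{guide.name}\t{guide.protospacer}\tseed={guide.seed}\n")
        for f_ in dataclasses.fields(result.params):
            fh.write(f"param\t{f_.name}\t{getattr(result.params, f_.name)}\n")
        fh.write(f"wt_variant_count\t{result.wt_variant_count}\n")
        fh.write(f"pseudogene_count\t{result.pseudogene_count}\n")
        fh.write(f"mutated_gene_count_pooled\t{result.mutated_gene_count()}\n")
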