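import io
from collections import Counter

import numpy as np
import pytest

from famedit.guides import SGALPHA2, locate_guide, reverse_complement
from famedit.mmej import find_microhomologies
from famedit.synthetic import (
    Allele,
    EditProfile,
    FamilyConfig,
    apply_edits,
    generate_family,
    simulate_reads,
)


def _fasta_bytes(family):
    buf = io.StringIO()
    for g in family:
        buf.write(f">{g.gene_id}\n{g.sequence}\n")
    return buf.getvalue()


class TestGenerateFamily:
    def test_empty_family(self):
        fam = generate_family(FamilyConfig(n_genes=0))
        assert len(fam) == 0 and _fasta_bytes(fam) == ""

    def test_seed_determinism(self):
        cfg = FamilyConfig(n_genes=45, pseudogene_fraction=0.4, rng_seed=7)
        assert _fasta_bytes(generate_family(cfg)) == _fasta_bytes(generate_family(cfg))

    def test_pseudogene_count_by_independent_stop_scan(self):
        """40% of 45 genes carry a premature stop, found by scanning codons."""
        cfg = FamilyConfig(n_genes=45, pseudogene_fraction=0.4, rng_seed=7)
        fam = generate_family(cfg)
        stops = {"TAA", "TAG", "TGA"}
        n_pseudo = 0
        for g in fam:
            codons = [g.sequence[i : i + 3] for i in range(0, len(g.sequence), 3)]
            if any(c in stops for c in codons[:-1]):
                n_pseudo += 1
        assert n_pseudo == 18
        assert sum(g.is_pseudogene for g in fam) == 18
        assert set(fam.planted_pseudogenes) == {
            g.gene_id for g in fam if g.is_pseudogene
        }

    def test_all_genes_carry_guide_site_and_distinct_sequences(self):
        cfg = FamilyConfig(n_genes=30, snp_rate=0.02, rng_seed=3)
        fam = generate_family(cfg)
        assert len({g.sequence for g in fam}) == 30
        for g in fam:
            assert SGALPHA2.name in g.guide_matches

    def test_epitope_repeats_drive_length_classes(self):
        cfg = FamilyConfig(n_genes=40, epitope_repeat_range=(1, 3), rng_seed=5)
        fam = generate_family(cfg)
        lengths = {len(g) for g in fam}
        assert lengths <= {270 + 81, 270 + 162, 270 + 243}
        for g in fam:
            assert len(g) == 270 + 81 * fam.epitope_repeats[g.gene_id]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FamilyConfig(pseudogene_fraction=1.5)
        with pytest.raises(ValueError):
            FamilyConfig(n_genes=-1)
        with pytest.raises(ValueError):
            FamilyConfig(epitope_repeat_range=(3, 1))


class TestApplyEdits:
    def test_zero_nhej_leaves_pool_unedited(self, small_family):
        pool, truth = apply_edits(
            small_family, SGALPHA2, EditProfile(nhej_fraction=0.0), rng_seed=1
        )
        parents = {g.gene_id: g.sequence for g in small_family}
        assert all(a.sequence == parents[a.gene_id] for a in pool)
        assert all(not r.is_edited for r in truth)
        assert len(truth) == len(pool)

    def test_forced_single_deletion_outcome(self, small_family):
        profile = EditProfile(
            nhej_fraction=1.0,
            deletion_size_weights={1: 1.0},
            insertion_fraction=0.0,
        )
        pool, truth = apply_edits(small_family, SGALPHA2, profile, rng_seed=2)
        parents = {g.gene_id: len(g.sequence) for g in small_family}
        assert all(len(a.sequence) == parents[a.gene_id] - 1 for a in pool)
        assert all(r.edit_type == "deletion" and r.size == -1 for r in truth)

    def test_guide_absent_raises_with_guide_name(self):
        from famedit.reference import ReferenceGene
        from famedit.guides import GuideRNA

        other = GuideRNA("sgNone", "ACGTACGTACGTACGTACGT")
        genes = [ReferenceGene("X", "ATGC" * 100)]
        with pytest.raises(ValueError, match="sgNone"):
            apply_edits(genes, other, EditProfile(), rng_seed=0)

    def test_mmej_bias_enriches_repeat_consistent_size(self, small_family):
        """With mmej_bias the sampler's categorical distribution multiplies
        the weight of microhomology-predicted sizes; empirical frequencies
        over 10,000 draws must match the analytic distribution."""
        gene = small_family.genes[0]
        cut = gene.guide_matches[SGALPHA2.name].cut_site
        pairs = find_microhomologies(gene.sequence, cut, 3, 36, 200)
        weights = {5: 1.0, 11: 1.0, 36: 1.0, 75: 1.0}
        mmej_sizes = {p.predicted_deletion_size for p in pairs} & set(weights)
        assert mmej_sizes, "family gene should carry repeats predicting some size"
        bias = 5.0
        profile = EditProfile(
            nhej_fraction=1.0,
            deletion_size_weights=weights,
            insertion_fraction=0.0,
            mmej_bias=bias,
        )
        pool, truth = apply_edits(
            [gene], SGALPHA2, profile, rng_seed=9, alleles_per_gene=10_000
        )
        counts = Counter(-r.size for r in truth)
        w = {s: v * (bias if s in mmej_sizes else 1.0) for s, v in weights.items()}
        total = sum(w.values())
        n = len(truth)
        for s, v in w.items():
            p = v / total
            se = (p * (1 - p) / n) ** 0.5
            assert abs(counts[s] / n - p) < 4 * se + 1e-9

    def test_mmej_size_deletions_placed_at_repeat(self, small_family):
        gene = small_family.genes[0]
        cut = gene.guide_matches[SGALPHA2.name].cut_site
        pairs = find_microhomologies(gene.sequence, cut, 3, 36, 200)
        by_size = {}
        for p in pairs:
            by_size.setdefault(p.predicted_deletion_size, []).append(p)
        profile = EditProfile(
            nhej_fraction=1.0,
            deletion_size_weights={s: 1.0 for s in list(by_size)[:3]},
            insertion_fraction=0.0,
        )
        pool, truth = apply_edits([gene], SGALPHA2, profile, rng_seed=4, alleles_per_gene=50)
        for r in truth:
            size = -r.size
            assert any(
                (r.start, r.end) == (p.left_start, p.right_start) for p in by_size[size]
            )

    def test_insertion_origins_recorded(self, small_family):
        profile = EditProfile(
            nhej_fraction=1.0,
            insertion_fraction=1.0,
            insertion_origin_mix=(0.4, 0.4, 0.2),
        )
        pool, truth = apply_edits(small_family, SGALPHA2, profile, rng_seed=5)
        origins = {r.origin for r in truth}
        assert origins <= {"vector", "family", "random"}
        assert all(r.size == len(r.inserted_sequence) > 0 for r in truth)
        assert all(r.start == r.end for r in truth)


class TestSimulateReads:
    def test_noiseless_reads_reconstruct_alleles(self, small_family):
        pool, truth = apply_edits(
            small_family, SGALPHA2, EditProfile(nhej_fraction=0.0), rng_seed=1
        )
        sample = simulate_reads(pool, 100, None, rng_seed=2)
        by_id = {a.allele_id: a.sequence for a in pool}
        for rp in sample.pairs:
            src = by_id[sample.read_allele[rp.read_id]]
            L = len(src)
            rl = len(rp.seq1)
            assert rp.seq1 == src[:rl]
            assert rp.seq2 == reverse_complement(src[L - rl :])

    def test_zero_depth_empty(self, small_family):
        pool, _ = apply_edits(
            small_family, SGALPHA2, EditProfile(nhej_fraction=0.0), rng_seed=1
        )
        sample = simulate_reads(pool, 0, None, rng_seed=2)
        assert sample.pairs == [] and sample.read_allele == {}

    def test_q20_error_rate_matches_phred(self, small_family):
        """Uniform Q20 implies a 1% per-base substitution rate."""
        pool, _ = apply_edits(
            small_family, SGALPHA2, EditProfile(nhej_fraction=0.0), rng_seed=1
        )
        sample = simulate_reads(pool, 400, 20, rng_seed=3)
        by_id = {a.allele_id: a.sequence for a in pool}
        mism = total = 0
        for rp in sample.pairs:
            src = by_id[sample.read_allele[rp.read_id]]
            rl = len(rp.seq1)
            mism += sum(a != b for a, b in zip(rp.seq1, src[:rl]))
            total += rl
        assert total > 1e5
        p = 0.01
        se = (p * (1 - p) / total) ** 0.5
        assert abs(mism / total - p) < 3 * se
        assert all(int(q) == 20 for q in sample.pairs[0].qual1)

    def test_seed_determinism_and_depth_conservation(self, small_family):
        pool, _ = apply_edits(
            small_family, SGALPHA2, EditProfile(nhej_fraction=0.0), rng_seed=1
        )
        s1 = simulate_reads(pool, 250, 25, rng_seed=11)
        s2 = simulate_reads(pool, 250, 25, rng_seed=11)
        assert [(r.seq1, r.seq2) for r in s1.pairs] == [(r.seq1, r.seq2) for r in s2.pairs]
        assert len(s1.pairs) == 250

    def test_insufficient_overlap_raises(self, small_family):
        pool, _ = apply_edits(
            small_family, SGALPHA2, EditProfile(nhej_fraction=0.0), rng_seed=1
        )
        with pytest.raises(ValueError, match="min_overlap"):
            simulate_reads(pool, 10, None, read_length=200, min_overlap=100)
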