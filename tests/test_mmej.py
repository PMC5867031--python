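import numpy as np
import pytest

from famedit.calling import IndelCall
from famedit.mmej import MicrohomologyPair, attribute_deletions, find_microhomologies


def brute_force_pairs(seq, cut, min_len=3, max_len=36, radius=200, spanning=True):
    """Independent enumeration of maximal direct-repeat pairs, using
    slice comparison and explicit extendability checks."""
    n = len(seq)
    lo, hi = max(0, cut - radius), min(n, cut + radius)
    out = set()
    for i in range(lo, hi):
        for j in range(i + 1, hi):
            # longest common extension via slice comparison
            L = 0
            limit = n - j
            while L < limit and seq[i : i + L + 1] == seq[j : j + L + 1]:
                L += 1
            if L == 0:
                continue
            left_extendable = i > 0 and seq[i - 1] == seq[j - 1]
            if left_extendable:
                continue
            if not (min_len <= L <= max_len):
                continue
            if spanning and not (i <= cut <= j + L):
                continue
            out.add((seq[i : i + L], i, j))
    return out


class TestFindMicrohomologies:
    def test_toy_acg_pair(self):
        seq = "TTTACGAAACGTTT"
        pairs = find_microhomologies(seq, 8, min_len=3)
        acg = [p for p in pairs if p.repeat_sequence == "ACG"]
        assert len(acg) == 1
        p = acg[0]
        assert (p.left_start, p.right_start) == (3, 8)
        assert p.predicted_deletion_size == 5
        assert p.apply_deletion(seq) == "TTTACGTTT"

    def test_repeat_free_sequence_empty(self):
        # alternating pattern offers no direct repeat of length >= 4
        seq = "ACGTTGCAACGT"[:8] + "TTAAGGCC"
        pairs = find_microhomologies(seq, 8, min_len=4, max_len=8, search_radius=8)
        assert pairs == brute_force_pairs(seq, 8, 4, 8, 8) == set() or (
            {(p.repeat_sequence, p.left_start, p.right_start) for p in pairs}
            == brute_force_pairs(seq, 8, 4, 8, 8)
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        cut = int(rng.integers(50, 250))
        got = {
            (p.repeat_sequence, p.left_start, p.right_start)
            for p in find_microhomologies(seq, cut)
        }
        assert got == brute_force_pairs(seq, cut)

    @pytest.mark.parametrize("seed", range(10))
    def test_deletion_leaves_exactly_one_copy(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        cut = 150
        for p in find_microhomologies(seq, cut):
            deleted = p.apply_deletion(seq)
            # the two annealing copies collapse into one surviving copy
            assert deleted[p.left_start : p.left_start + p.length] == p.repeat_sequence
            count_before = sum(
                seq[i : i + p.length] == p.repeat_sequence for i in range(len(seq))
            )
            count_after = sum(
                deleted[i : i + p.length] == p.repeat_sequence
                for i in range(len(deleted))
            )
            if count_before == 2:
                # repeat unique to the pair: exactly one copy remains
                assert count_after == 1
            else:
                # short repeats recur elsewhere; incidental occurrences inside
                # the deleted interval may go too, but never below the junction copy
                assert 1 <= count_after <= count_before - 1

    def test_monotone_in_radius_and_length_bounds(self):
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        cut = 150
        small = {
            (p.repeat_sequence, p.left_start, p.right_start)
            for p in find_microhomologies(seq, cut, 4, 10, 60)
        }
        large = {
            (p.repeat_sequence, p.left_start, p.right_start)
            for p in find_microhomologies(seq, cut, 3, 36, 150)
        }
        assert small <= large

    def test_sorted_by_predicted_size_then_position(self):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        pairs = find_microhomologies(seq, 150)
        keys = [(p.predicted_deletion_size, p.left_start, p.right_start) for p in pairs]
        assert keys == sorted(keys)


class TestAttributeDeletions:
    def test_toy_consistent_deletion(self):
        seq = "TTTACGAAACGTTT"
        pairs = find_microhomologies(seq, 8, min_len=3)
        call = IndelCall("v1", "g1", "deletion", -5, 3, 8)
        assert attribute_deletions([call], pairs, seq) == [True]

    def test_single_base_deletion_not_consistent(self):
        seq = "TTTACGAAACGTTT"
        pairs = find_microhomologies(seq, 8, min_len=3)
        call = IndelCall("v1", "g1", "deletion", -1, 7, 8)
        assert attribute_deletions([call], pairs, seq) == [False]

    def test_mmej_bias_increases_consistent_fraction(self, small_family):
        """A paired simulation: deletions drawn with mmej_bias=5 are
        MMEJ-consistent significantly more often than the unbiased draw."""
        from famedit.guides import SGALPHA2
        from famedit.synthetic import EditProfile, apply_edits

        def consistent_fraction(bias, seed):
            profile = EditProfile(
                nhej_fraction=1.0, insertion_fraction=0.0, mmej_bias=bias
            )
            pool, truth = apply_edits(
                small_family, SGALPHA2, profile, rng_seed=seed, alleles_per_gene=250
            )
            n_cons = n_tot = 0
            cache = {}
            for r in truth:
                gene = small_family.gene(r.gene_id)
                if r.gene_id not in cache:
                    cut = gene.guide_matches[SGALPHA2.name].cut_site
                    cache[r.gene_id] = (
                        find_microhomologies(gene.sequence, cut),
                        gene.sequence,
                    )
                pairs, seq = cache[r.gene_id]
                call = IndelCall("v", r.gene_id, "deletion", r.size, r.start, r.end)
                n_cons += attribute_deletions([call], pairs, seq)[0]
                n_tot += 1
            return n_cons, n_tot

        c1, n1 = consistent_fraction(1.0, 31)
        c5, n5 = consistent_fraction(5.0, 32)
        p1, p5 = c1 / n1, c5 / n5
        pooled = (c1 + c5) / (n1 + n5)
        se = (pooled * (1 - pooled) * (1 / n1 + 1 / n5)) ** 0.5
        assert (p5 - p1) / se > 3  # two-proportion z-test

    def test_reference_bound_check(self):
        call = IndelCall("v1", "g1", "deletion", -5, 3, 80)
        with pytest.raises(ValueError):
            attribute_deletions([call], [], "ACGT")
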