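"""Mutation-index estimation: block partition, exact search, greedy bound."""

import numpy as np
import pytest

from repeatsig.catalog import RepeatRegion, detect_repeats
from repeatsig.history import (
    SizeLimitError,
    estimate_index,
    estimate_index_exact,
    partition_blocks,
)
from repeatsig.patterns import canonical_rotation, rotations
from repeatsig.synthetic import simulate_history

FIG_REGION = "ACGTACGTACATAGAT"


def region_of(seq, pattern):
    return RepeatRegion(
        "s", 0, len(seq), canonical_rotation(pattern),
        min(100.0, len(seq) / len(pattern)), seq,
    )


class TestPartition:
    def test_worked_example_blocks(self):
        part = partition_blocks(FIG_REGION, "ACGT")
        assert part.blocks == ["ACGT", "ACGT", "ACAT", "AGAT"]
        assert part.d == 4

    def test_perfect_repeat_partitions_evenly(self):
        part = partition_blocks("GTGAGTGAGTGA", "GTGA")
        assert part.blocks == ["GTGA"] * 3
        assert part.distances == [0, 0, 0]

    def test_rotated_pattern_finds_phase(self):
        part = partition_blocks("GTGAGTGAGTGA", canonical_rotation("GTGA"))
        assert part.blocks == ["GTGA"] * 3

    def test_region_equal_to_pattern(self):
        part = partition_blocks("ACGT", "ACGT")
        assert part.blocks == ["ACGT"]
        assert part.d == 1

    def test_region_shorter_than_pattern_rejected(self):
        with pytest.raises(ValueError):
            partition_blocks("AC", "ACGT")


class TestExact:
    def test_worked_example_index(self):
        idx = estimate_index_exact(FIG_REGION, 4)
        assert (idx.m, idx.d) == (2, 4)

    def test_perfect_repeat_is_zero(self):
        idx = estimate_index_exact("GTGAGTGAGTGA", 4)
        assert (idx.m, idx.d) == (0, 3)

    def test_guard_rejects_large_inputs(self):
        with pytest.raises(SizeLimitError):
            estimate_index_exact("A" * 30, 2)
        with pytest.raises(SizeLimitError):
            estimate_index_exact("ACGTACGTACGT", 6)

    @pytest.mark.parametrize("seed", range(40))
    def test_exact_below_perfect_repeat_hamming_bound(self, seed):
        """Exact m never exceeds the Hamming distance to the best 4-fold
        repeat of any 2-mer (sampled from the 4^8 length-8 space)."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=8))
        bound = min(
            sum(a != b for a, b in zip(seq, pat * 4))
            for pat in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=2))
        )
        assert estimate_index_exact(seq, 2).m <= bound


class TestGreedy:
    def test_worked_example_matches_exact(self):
        idx = estimate_index(region_of(FIG_REGION, "ACGT"))
        assert (idx.m, idx.d) == (2, 4)

    @pytest.mark.parametrize(
        "seq,pattern",
        [("GTGAGTGAGTGA", "GTGA"), ("AAAAAAA", "A"), ("ACACACAC", "AC")],
    )
    def test_perfect_repeats_have_zero_m(self, seq, pattern):
        assert estimate_index(region_of(seq, pattern)).m == 0

    def test_zero_law_rotated_phase(self):
        # perfect repeat of a rotation of its pattern
        assert estimate_index(region_of("TGAGTGAGTGAG", "GTGA")).m == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_single_substitution_costs_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 6))
        pat = "".join(rng.choice(list("ACGT"), size=p))
        seq = pat * int(rng.integers(3, 8))
        i = int(rng.integers(len(seq)))
        sub = rng.choice([c for c in "ACGT" if c != seq[i]])
        mutated = seq[:i] + sub + seq[i + 1 :]
        assert estimate_index(region_of(mutated, pat)).m <= 1

    @pytest.mark.parametrize("seed", range(60))
    def test_greedy_dominates_exact(self, seed):
        """The polynomial estimate is an upper bound on the exact minimum."""
        rng = np.random.default_rng(1000 + seed)
        p = int(rng.integers(2, 5))
        pat = "".join(rng.choice(list("ACGT"), size=p))
        h = simulate_history(
            pat, int(rng.integers(1, 5)), int(rng.integers(0, 3)), seed
        )
        seq = h.final_sequence
        if len(seq) > 20:
            pytest.skip("outside exact-search guard")
        exact = estimate_index_exact(seq, p).m
        greedy = estimate_index(region_of(seq, pat)).m
        assert greedy >= exact

    def test_witness_bound_on_cohort_sample(self, small_cohort):
        """Estimated m stays within the simulated mutation count for the
        overwhelming majority of generated regions."""
        items = list(small_cohort.histories.items())[:400]
        bad = 0
        for (_, _), h in items:
            reg = region_of(h.final_sequence, h.root_pattern)
            if estimate_index(reg).m > h.witness_mutations:
                bad += 1
        assert bad / len(items) <= 0.01

    def test_detected_regions_yield_valid_indices(self, small_cohort):
        sid, seq = next(iter(small_cohort.samples.items()))
        for r in detect_repeats(seq, sid)[:20]:
            idx = estimate_index(r)
            assert idx.m >= 0
            assert idx.d >= 1
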