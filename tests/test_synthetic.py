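"""Cohort generator: event replay, determinism, planted structure."""

import numpy as np
import pytest
from scipy import stats

from repeatsig.synthetic import (
    CohortSpec,
    generate_cohort,
    replay,
    simulate_history,
)


def replay_oracle(root, events):
    """Independent re-execution of a history's event list."""
    blocks = [root]
    for ev in events:
        if ev.kind == "duplication":
            blocks.insert(ev.index + 1, blocks[ev.index])
            continue
        seq = "".join(blocks)
        lens = [len(b) for b in blocks]
        pos, bi = ev.index, 0
        limit = lens[bi] + (1 if ev.kind == "insertion" else 0)
        while pos >= limit and bi < len(blocks) - 1:
            pos -= lens[bi]
            bi += 1
            limit = lens[bi] + (1 if ev.kind == "insertion" else 0)
        b = blocks[bi]
        if ev.kind == "substitution":
            blocks[bi] = b[:pos] + ev.detail + b[pos + 1 :]
        elif ev.kind == "deletion":
            blocks[bi] = b[:pos] + b[pos + 1 :]
        else:
            blocks[bi] = b[:pos] + ev.detail + b[pos:]
    return "".join(blocks)


class TestSimulateHistory:
    def test_pure_duplication_triples_the_pattern(self):
        h = simulate_history("GTGA", 2, 0, rng_seed=1)
        assert h.final_sequence == "GTGAGTGAGTGA"
        assert h.final_block_count == 3

    def test_no_events_is_identity(self):
        h = simulate_history("A", 0, 0, rng_seed=0)
        assert h.final_sequence == "A"
        assert h.events == []

    @pytest.mark.parametrize("seed", range(25))
    def test_replay_reproduces_final_sequence(self, seed):
        rng = np.random.default_rng(seed)
        pat = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
        h = simulate_history(
            pat, int(rng.integers(0, 8)), int(rng.integers(0, 5)), seed
        )
        assert replay(h.root_pattern, h.events) == h.final_sequence
        assert replay_oracle(h.root_pattern, h.events) == h.final_sequence
        assert h.witness_mutations == sum(
            1 for e in h.events if e.kind != "duplication"
        )

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            simulate_history("", 1, 0, 0)


class TestGenerateCohort:
    def test_seed_determinism(self):
        spec = CohortSpec(
            n_classes=2, samples_per_class=(5, 5), n_regions=10,
            signal_regions=frozenset({0}), effect_class=1, seed=9,
        )
        c1 = generate_cohort(spec)
        c2 = generate_cohort(spec)
        assert c1.samples == c2.samples
        assert c1.reference == c2.reference
        assert c1.ground_truth.equals(c2.ground_truth)

    def test_replay_closure_over_all_histories(self, small_cohort):
        for hist in list(small_cohort.histories.values())[:500]:
            assert replay(hist.root_pattern, hist.events) == hist.final_sequence

    def test_zero_rates_give_perfect_repeats(self, perfect_cohort):
        truth = perfect_cohort.ground_truth
        present = truth[truth.present]
        assert (present.witness_m == 0).all()
        for row in present.head(200).itertuples():
            seq = perfect_cohort.samples[row.sample_id][row.start : row.end]
            pat_len = len(seq) // row.true_d
            assert seq == seq[:pat_len] * row.true_d

    def test_null_cohort_classes_exchangeable(self):
        """With zero shifts no region separates the classes (Bonferroni
        Poisson-rate tests at alpha 0.01)."""
        spec = CohortSpec(
            n_classes=2, samples_per_class=(40, 40), n_regions=25,
            signal_regions=frozenset(), effect_class=0,
            m_shift=0.0, d_shift=0.0, seed=77,
        )
        truth = generate_cohort(spec, keep_histories=False).ground_truth
        present = truth[truth.present]
        n_regions = present.region.nunique()
        rejected = 0
        for _, grp in present.groupby("region"):
            a = grp[grp["class"] == "class_01"].witness_m
            b = grp[grp["class"] == "class_02"].witness_m
            # two-sample Poisson rate test via normal approximation
            res = stats.poisson_means_test(a.sum(), len(a), b.sum(), len(b))
            if res.pvalue < 0.01 / n_regions:
                rejected += 1
        assert rejected == 0

    def test_signal_class_shifts_mutation_counts(self, small_cohort):
        truth = small_cohort.ground_truth
        present = truth[truth.present]
        sig = present[present.region < 5]
        effect = sig[sig["class"] == "class_03"].witness_m.mean()
        others = sig[sig["class"] != "class_03"].witness_m.mean()
        assert effect > others + 1.5  # shift of 3 expected

    def test_mismatched_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(
                n_classes=3, samples_per_class=(5, 5), n_regions=5,
                signal_regions=frozenset(), effect_class=0,
            ).validate()

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = CohortSpec(
            n_classes=2, samples_per_class=(4, 6), n_regions=8,
            signal_regions=frozenset({1, 3}), effect_class=1, seed=3,
        )
        spec.to_yaml(tmp_path / "spec.yaml")
        assert CohortSpec.from_yaml(tmp_path / "spec.yaml") == spec
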