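"""Profile alignment: normalized edit distance and the gap-cost DP."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatsig.align import (
    AlignedMatrix,
    AlignParams,
    ProfileAligner,
    align_profiles,
    build_matrix,
    normalized_edit_distance,
)
from tests.helpers import profile_of

PATTERNS = st.text(alphabet="ACGT", min_size=1, max_size=6)


class TestNormalizedEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("CG", "CGTA", 2 / 3), ("CG", "CG", 0.0), ("A", "CCC", 3 / 2)],
    )
    def test_known_values(self, a, b, expected):
        assert normalized_edit_distance(a, b) == pytest.approx(expected)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            normalized_edit_distance("", "A")

    @settings(max_examples=150, deadline=None)
    @given(PATTERNS, PATTERNS)
    def test_symmetric_zero_iff_equal_bounded(self, a, b):
        d = normalized_edit_distance(a, b)
        assert d == pytest.approx(normalized_edit_distance(b, a))
        assert 0 <= d <= 2
        assert (d == 0) == (a == b)


def brute_force_cost(q_patterns, r_patterns, gap=0.4):
    """Exhaustive minimum over all monotone alignments."""
    nq, nr = len(q_patterns), len(r_patterns)
    best = float("inf")
    for k in range(min(nq, nr) + 1):
        for qi in itertools.combinations(range(nq), k):
            for ri in itertools.combinations(range(nr), k):
                cost = sum(
                    normalized_edit_distance(q_patterns[a], r_patterns[b])
                    for a, b in zip(qi, ri)
                )
                cost += gap * (nq - k + nr - k)
                best = min(best, cost)
    return best


class TestAlignProfiles:
    def test_paper_worked_example(self, paper_profiles):
        query, reference = paper_profiles
        res = align_profiles(query, reference)
        assert res.cost == pytest.approx(0.4)
        assert [e.pattern if e else None for e in res.pairs] == ["A", None, "CG"]
        # the alternative pairing CG-CGTA would cost 0 + 2/3 + 0.4
        alt = normalized_edit_distance("CG", "CGTA") + 0.4
        assert res.cost < alt

    def test_self_alignment_is_free(self, paper_profiles):
        _, reference = paper_profiles
        res = align_profiles(reference, reference)
        assert res.cost == 0
        assert res.n_gaps == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_dp_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = ["A", "C", "AC", "CG", "ACG", "CGT", "AT", "GGT"]
        nq, nr = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        q = profile_of("q", [(alphabet[i] , 0, 2) for i in rng.integers(0, 8, nq)])
        r = profile_of("r", [(alphabet[i], 0, 2) for i in rng.integers(0, 8, nr)])
        res = align_profiles(q, r)
        expected = brute_force_cost(
            [e.pattern for e in q.entries], [e.pattern for e in r.entries]
        )
        assert res.cost == pytest.approx(expected)

    def test_close_patterns_pair_up(self):
        """Patterns within the 0.4 match threshold are paired, not gapped."""
        q = profile_of("q", [("ACGTA", 1, 5)])
        r = profile_of("r", [("ACGTT", 0, 4)])
        res = align_profiles(q, r)
        assert res.pairs[0] is not None
        assert res.n_gaps == 0


class TestBuildMatrix:
    def test_paper_row_with_gap_fill(self, paper_profiles):
        query, reference = paper_profiles
        matrix = build_matrix([query], reference)
        np.testing.assert_array_equal(
            matrix.values.to_numpy()[0], [0, 7, 0, 0, 1, 4]
        )

    def test_identical_profiles_identical_rows(self, paper_profiles):
        _, reference = paper_profiles
        clones = [
            profile_of(f"s{i}", [("A", 0, 8), ("CGTA", 0, 3), ("CG", 1, 3)])
            for i in range(3)
        ]
        matrix = build_matrix(clones, reference)
        expected = [0, 8, 0, 3, 1, 3]
        for row in matrix.values.to_numpy():
            np.testing.assert_array_equal(row, expected)

    def test_empty_reference_rejected(self, paper_profiles):
        query, _ = paper_profiles
        with pytest.raises(ValueError):
            build_matrix([query], profile_of("empty", []))

    def test_column_stability_under_new_samples(self, paper_profiles):
        query, reference = paper_profiles
        one = build_matrix([query], reference)
        extra = profile_of("other", [("A", 2, 9)])
        two = build_matrix([query, extra], reference)
        np.testing.assert_array_equal(
            one.values.loc["patient1"], two.values.loc["patient1"]
        )

    def test_dropout_shows_up_as_zero_slots(self):
        """With dropout 0.2 about 20% of region slots are (0, 0)-filled."""
        rng = np.random.default_rng(3)
        n_regions, n_samples, dropout = 40, 60, 0.2
        reference = profile_of(
            "ref", [("ACG", 0, 5) for _ in range(n_regions)]
        )
        profiles = []
        total = kept = 0
        for s in range(n_samples):
            keep = rng.random(n_regions) >= dropout
            entries = [("ACG", 1, 5) for k in keep if k]
            total += n_regions
            kept += int(keep.sum())
            profiles.append(profile_of(f"s{s}", entries))
        matrix = build_matrix(profiles, reference)
        vals = matrix.values.to_numpy().reshape(n_samples, n_regions, 2)
        filled = (vals.sum(axis=2) == 0).mean()
        # binomial 99% interval around the dropout rate
        se = np.sqrt(dropout * (1 - dropout) / total)
        assert abs(filled - dropout) < 3 * se + 0.01

    def test_matrix_tsv_round_trip(self, paper_profiles, tmp_path):
        query, reference = paper_profiles
        query.class_label = "g1"
        matrix = build_matrix([query], reference)
        path = tmp_path / "matrix.tsv"
        matrix.to_tsv(path)
        back = AlignedMatrix.read_tsv(path)
        assert back.values.equals(matrix.values)
        assert list(back.labels) == ["g1"]


class TestProfileAligner:
    def test_fit_transform_matches_build_matrix(self, paper_profiles):
        query, reference = paper_profiles
        aligner = ProfileAligner().fit(reference)
        out = aligner.transform([query])
        assert out.values.equals(build_matrix([query], reference).values)

    def test_params_round_trip(self):
        aligner = ProfileAligner(gap_cost=0.5)
        assert aligner.get_params()["gap_cost"] == 0.5
        aligner.set_params(gap_cost=0.4)
        assert aligner.get_params()["gap_cost"] == 0.4

    def test_transform_before_fit_raises(self, paper_profiles):
        query, _ = paper_profiles
        with pytest.raises(RuntimeError):
            ProfileAligner().transform([query])
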