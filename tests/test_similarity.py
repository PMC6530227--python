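import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grvec import (
    GroupRepresentative,
    GroupSample,
    ProteinRecord,
    ZeroVectorError,
    angle_theta,
    build_representative,
    compute_adjacency,
    cross_group,
    magnitude_D,
    pairwise_matrix,
    similarity_vector,
    worked_example,
    write_phylip,
)

from conftest import random_protein


def gr_of(values, name="g"):
    v = np.zeros(400)
    v[: len(values)] = values
    return GroupRepresentative(name, v, n_sequences=2, member_ids=("a", "b"))


def sample_of(*seqs, name="s"):
    return GroupSample(
        name, [ProteinRecord(f"p{i}", f"p{i}", s) for i, s in enumerate(seqs)]
    )


small_vectors = st.lists(
    st.integers(min_value=0, max_value=9), min_size=400, max_size=400
).map(lambda xs: np.array(xs, dtype=float))


class TestMagnitude:
    def test_zero_on_identical(self):
        g = gr_of([1, 2, 3])
        assert magnitude_D(g, g) == 0.0

    def test_single_coordinate_difference(self):
        a, b = gr_of([5]), gr_of([2])
        assert magnitude_D(a, b) == 3.0

    def test_matches_exact_sum_of_squares_oracle(self):
        rng = np.random.default_rng(21)
        counts = rng.integers(0, 8, size=400)
        halves = rng.integers(0, 16, size=400)  # 2x a half-integer median
        expected = math.sqrt(
            float(
                sum(
                    (Fraction(int(c)) - Fraction(int(h), 2)) ** 2
                    for c, h in zip(counts, halves)
                )
            )
        )
        got = magnitude_D(gr_of(counts), gr_of(halves / 2.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            magnitude_D(np.zeros(400), np.zeros(20))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(small_vectors, small_vectors, small_vectors)
    def test_triangle_inequality(self, u, v, w):
        assert magnitude_D(u, w) <= magnitude_D(u, v) + magnitude_D(v, w) + 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(small_vectors, small_vectors)
    def test_symmetry_and_identity_of_indiscernibles(self, u, v):
        assert magnitude_D(u, v) == pytest.approx(magnitude_D(v, u))
        assert (magnitude_D(u, v) == 0.0) == bool(np.array_equal(u, v))

    def test_unit_normalization_mode(self):
        u, v = gr_of([3, 4]), gr_of([4, 3])
        expected = float(
            np.linalg.norm(u.values / np.linalg.norm(u.values) - v.values / np.linalg.norm(v.values))
        )
        assert magnitude_D(u, v, normalize="unit") == pytest.approx(expected)

    def test_length_normalization_mode(self):
        u, v = gr_of([2, 2]), gr_of([1, 3])
        assert magnitude_D(u, v, normalize="length") == pytest.approx(
            float(np.linalg.norm(u.values / 4 - v.values / 4))
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown normalization"):
            magnitude_D(gr_of([1]), gr_of([1]), normalize="zscore")


class TestAngle:
    def test_zero_for_positive_scalar_multiples(self):
        u = gr_of([1, 2, 3])
        v = gr_of([2.5, 5, 7.5])
        assert angle_theta(u, v) == 0.0  # clamp makes this exact

    def test_right_angle_for_disjoint_supports(self):
        u = np.zeros(400)
        v = np.zeros(400)
        u[0], v[399] = 3, 7
        assert angle_theta(u, v) == pytest.approx(math.pi / 2)

    def test_pi_for_antiparallel_with_clamp(self):
        u = np.ones(400)
        assert angle_theta(u, -u) == math.pi

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        small_vectors.filter(lambda v: v.any()),
        st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
    )
    def test_scale_invariance(self, u, c):
        v = u + 1  # strictly positive partner
        assert angle_theta(c * u, v) == pytest.approx(angle_theta(u, v), abs=1e-9)
        assert angle_theta(u, c * v) == pytest.approx(angle_theta(u, v), abs=1e-9)

    def test_agrees_with_high_precision_oracle(self):
        from decimal import Decimal, getcontext

        rng = np.random.default_rng(33)
        for _ in range(10):
            u = rng.integers(0, 9, size=400)
            v = rng.integers(0, 17, size=400) / 2.0
            getcontext().prec = 50
            dot = sum(Decimal(int(a)) * Decimal(b) for a, b in zip(u, v.astype(str)))
            nu = sum(Decimal(int(a)) ** 2 for a in u).sqrt()
            nv = sum(Decimal(b) ** 2 for b in v.astype(str)).sqrt()
            expected = math.acos(min(1.0, max(-1.0, float(dot / (nu * nv)))))
            assert angle_theta(u.astype(float), v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_error_names_the_offender(self):
        rec = ProteinRecord("tiny", "tiny", "W")
        av = compute_adjacency(rec)
        with pytest.raises(ZeroVectorError, match="tiny"):
            angle_theta(av, gr_of([1, 2]))
        with pytest.raises(ZeroVectorError, match=r"GR\[empty\]"):
            angle_theta(gr_of([1, 2]), gr_of([], name="empty"))


class TestSimilarityVector:
    def test_identical_members_all_zero(self):
        sv = similarity_vector(
            sample_of("WTFE", "WTFE", "WTFE"),
            build_representative(sample_of("WTFE", "WTFE", "WTFE")),
        )
        assert [(e.D, e.theta) for e in sv.entries] == [(0.0, 0.0)] * 3

    def test_one_entry_per_member_in_input_order(self, example_sample):
        gr = build_representative(example_sample)
        sv = similarity_vector(example_sample, gr)
        assert [e.sequence_id for e in sv.entries] == example_sample.ids()
        assert len(sv.entries) == len(example_sample)

    def test_two_member_group_is_equidistant_from_its_representative(
        self, example_sample
    ):
        # even-n median of two vectors is their midpoint
        gr = build_representative(example_sample)
        sv = similarity_vector(example_sample, gr)
        assert sv.entries[0].D == pytest.approx(sv.entries[1].D)
        avs = [compute_adjacency(r) for r in example_sample.records]
        assert sv.entries[0].D == pytest.approx(magnitude_D(avs[0], avs[1]) / 2)


class TestCrossGroup:
    def test_own_representative_degenerates_to_similarity_vector(self, example_sample):
        gr = build_representative(example_sample)
        a = similarity_vector(example_sample, gr)
        b = cross_group(example_sample, gr)
        assert a.entries == b.entries

    def test_output_tagged_with_both_groups(self, example_sample):
        foreign = gr_of([1] * 50, name="other_family")
        sv = cross_group(example_sample, foreign)
        assert sv.sample_name == "worked_example"
        assert sv.group_name == "other_family"
        rows = sv.rows()
        assert rows[0]["group"] == "worked_example"
        assert rows[0]["gr_group"] == "other_family"

    def test_statistics_depend_only_on_the_two_vectors(self, example_sample):
        # relabelling which side is "foreign" cannot change D/theta
        gr = build_representative(example_sample)
        direct = [(e.D, e.theta) for e in similarity_vector(example_sample, gr).entries]
        crossed = [(e.D, e.theta) for e in cross_group(example_sample, gr).entries]
        assert direct == crossed


class TestPairwiseMatrix:
    def test_identical_pair_gives_zero_matrix(self):
        pm = pairwise_matrix(sample_of("WTFE", "WTFE"), metric="theta")
        assert np.array_equal(pm.values, np.zeros((2, 2)))

    @pytest.mark.parametrize("metric", ["D", "theta"])
    def test_symmetric_with_zero_diagonal(self, metric):
        rng = np.random.default_rng(4)
        seqs = [random_protein(rng, 60) for _ in range(4)]
        pm = pairwise_matrix(sample_of(*seqs), metric=metric)
        assert np.array_equal(pm.values, pm.values.T)
        assert np.array_equal(np.diag(pm.values), np.zeros(4))

    def test_evaluation_count_is_n_choose_2(self):
        rng = np.random.default_rng(8)
        sample = sample_of(*[random_protein(rng, 40) for _ in range(7)])
        pm = pairwise_matrix(sample, metric="theta")
        assert pm.n_evaluations == 21  # n(n-1)/2 at n=7

    def test_needs_two_records(self):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_matrix(sample_of("WTFE"))

    def test_zero_vector_member_fails_for_theta(self):
        with pytest.raises(ZeroVectorError):
            pairwise_matrix(sample_of("WT", "A"), metric="theta")

    def test_phylip_export(self, tmp_path):
        pm = pairwise_matrix(sample_of("WTFE", "WTFA", "ATFE"), metric="D")
        path = tmp_path / "m.phy"
        write_phylip(pm, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "3"
        assert len(lines) == 4
        assert lines[1].startswith("p0")


def test_similarity_vector_versus_matrix_cost():
    rng = np.random.default_rng(17)
    sample = sample_of(*[random_protein(rng, 50) for _ in range(7)])
    gr = build_representative(sample)
    sv = similarity_vector(sample, gr)
    pm = pairwise_matrix(sample, metric="theta")
    assert len(sv.entries) == 7  # n evaluations per statistic
    assert pm.n_evaluations == 21  # vs n(n-1)/2
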