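"""Spearman similarity machinery: brute-force rank oracle, aggregation,
significance testing, and the dissimilarity matrix contracts."""

import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from emgesture import (
    dissimilarity,
    intra_subject_similarity,
    intra_task_similarity,
    rms_patterns,
    similarity_significance,
    spearman,
)
from emgesture.similarity import InsufficientDataError, RMSPattern


def rank_pearson_oracle(x, y):
    """Independent oracle: Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0])
        assert spearman(x, x) == pytest.approx(1.0)
        order = np.argsort(x)
        y = np.empty_like(x)
        y[order] = np.sort(x)[::-1]  # exact rank reversal
        assert spearman(x, y) == pytest.approx(-1.0)

    def test_adjacent_rank_swap(self):
        # one adjacent swap: sum d^2 = 2 -> r = 1 - 12/504
        x = np.arange(8, dtype=float)
        y = x.copy()
        y[3], y[4] = y[4], y[3]
        assert spearman(x, y) == pytest.approx(1 - 12 / 504)

    def test_constant_vector_is_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman(np.ones(8), np.arange(8.0)))

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8)
            assert abs(spearman(x, y) - rank_pearson_oracle(x, y)) < 1e-12

    def test_handles_ties_via_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.arange(8.0)
        assert spearman(x, y) == pytest.approx(rank_pearson_oracle(x, y), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        r = spearman(x, y)
        assert spearman(np.exp(x), y**3) == pytest.approx(r, abs=1e-12)
        assert spearman(y, x) == pytest.approx(r, abs=1e-12)  # symmetry


def block_patterns(pid, code, values_15x8):
    return [
        RMSPattern(pid, code, k + 1, values_15x8[k]) for k in range(len(values_15x8))
    ]


class TestRmsPatterns:
    def test_block_normalisation_and_count(self, cohort_pipeline):
        patterns = cohort_pipeline["patterns"]
        by_block = {}
        for p in patterns:
            by_block.setdefault((p.participant_id, p.movement_code), []).append(p.values)
        assert all(len(v) == 15 for v in by_block.values())
        for vals in by_block.values():
            assert np.vstack(vals).max() == pytest.approx(1.0)

    def test_controls_excluded(self, cohort_pipeline):
        codes = {p.movement_code for p in cohort_pipeline["patterns"]}
        assert codes == {f"F{i}" for i in range(1, 7)}

    def test_scaling_invariance(self, cohort_pipeline):
        from emgesture.io import FeatureMatrix

        fm = cohort_pipeline["fm"]
        scaled = fm.df.copy()
        rms_cols = [f"RMS_ch{c}" for c in range(1, 9)]
        scaled[rms_cols] = scaled[rms_cols] * 10.0
        p1 = rms_patterns(fm)
        p2 = rms_patterns(FeatureMatrix(scaled))
        assert np.allclose(
            np.vstack([p.values for p in p1]), np.vstack([p.values for p in p2])
        )

    def test_incomplete_block_skipped_with_warning(self, cohort_pipeline):
        from emgesture.io import FeatureMatrix

        df = cohort_pipeline["fm"].df
        truncated = df[~((df.participant_id == 1) & (df.movement_code == "F1")
                         & (df.repetition_index == 5))]
        with pytest.warns(UserWarning, match="12 observations"):
            pats = rms_patterns(FeatureMatrix(truncated))
        assert not any(
            p.participant_id == 1 and p.movement_code == "F1" for p in pats
        )


class TestIntraSubjectSimilarity:
    def test_identical_patterns_give_unit_similarity(self):
        base = np.linspace(0.1, 1.0, 8)
        pats = block_patterns(1, "F1", np.tile(base, (15, 1)))
        (rep,) = intra_subject_similarity(pats)
        assert rep.aggregate == pytest.approx(1.0)
        assert rep.pairwise.shape == (15, 15)
        assert np.allclose(rep.pairwise, 1.0)

    def test_aggregate_invariant_to_observation_relabelling(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 1.0, (15, 8))
        (r1,) = intra_subject_similarity(block_patterns(1, "F1", vals))
        perm = rng.permutation(15)
        (r2,) = intra_subject_similarity(block_patterns(1, "F1", vals[perm]))
        assert r1.aggregate == pytest.approx(r2.aggregate, abs=1e-12)

    def test_pairwise_matrix_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(4)
        (rep,) = intra_subject_similarity(
            block_patterns(2, "F3", rng.uniform(0, 1, (15, 8)))
        )
        assert np.allclose(rep.pairwise, rep.pairwise.T)
        assert np.allclose(np.diag(rep.pairwise), 1.0)


class TestSignificance:
    def test_tight_positive_values_highly_significant(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.9, 0.01, 105)
        # closed form: t = mean / (sd/sqrt(n)) ~ 900 -> p astronomically small
        assert similarity_significance(vals) < 1e-10

    def test_exactly_symmetric_values_give_half(self):
        # sample mean exactly zero -> t = 0 -> one-sided p = 0.5
        rng = np.random.default_rng(6)
        half = rng.normal(0.0, 0.5, 100)
        vals = np.concatenate([half, -half])
        assert similarity_significance(vals) == pytest.approx(0.5, abs=1e-12)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            similarity_significance(np.array([0.5, 0.6]))


class TestIntraTask:
    def test_shared_profile_gives_unit_coefficient(self):
        base = np.linspace(0.1, 1.0, 8)
        pats = []
        for pid in range(1, 5):
            pats += block_patterns(pid, "F1", np.tile(base, (15, 1)))
        assert intra_task_similarity(pats)["F1"] == pytest.approx(1.0)

    def test_independent_profiles_give_near_zero(self):
        """Permutation oracle: unrelated per-subject patterns decorrelate."""
        rng = np.random.default_rng(7)
        coeffs = []
        for _ in range(50):
            pats = []
            for pid in range(1, 5):
                base = rng.uniform(0.1, 1.0, 8)
                pats += block_patterns(pid, "F1", np.tile(base, (15, 1)))
            coeffs.append(intra_task_similarity(pats)["F1"])
        assert abs(np.mean(coeffs)) < 0.1

    def test_single_subject_rejected(self):
        pats = block_patterns(1, "F1", np.random.default_rng(0).uniform(0, 1, (15, 8)))
        with pytest.raises(InsufficientDataError):
            intra_task_similarity(pats)


@pytest.fixture(scope="module")
def two_movement_patterns():
    rng = np.random.default_rng(8)
    up = np.sort(rng.uniform(0.1, 1.0, 8))
    pats = block_patterns(1, "F1", np.tile(up, (15, 1)))
    pats += block_patterns(1, "F2", np.tile(up[::-1], (15, 1)))
    return pats


class TestDissimilarity:
    def test_rank_reversed_pair_gives_two(self, two_movement_patterns):
        (dm,) = dissimilarity(two_movement_patterns)
        assert dm.values[0, 1] == pytest.approx(2.0)

    def test_matrix_contracts(self, cohort_pipeline):
        for dm in cohort_pipeline["dissimilarities"]:
            v = dm.values
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 0.0)
            assert np.all((v >= -1e-12) & (v <= 2 + 1e-12))

    def test_entries_match_one_minus_spearman(self, cohort_pipeline):
        dm = cohort_pipeline["dissimilarities"][0]
        pats = [
            p for p in cohort_pipeline["patterns"] if p.participant_id == dm.participant_id
        ]
        by_code = {}
        for p in pats:
            by_code.setdefault(p.movement_code, []).append(p.values)
        means = {}
        for code, vals in by_code.items():
            m = np.vstack(vals).mean(axis=0)
            means[code] = m / m.max()
        for a, b in combinations(range(len(dm.movement_codes)), 2):
            expected = 1 - spearman(means[dm.movement_codes[a]], means[dm.movement_codes[b]])
            assert dm.values[a, b] == pytest.approx(expected, abs=1e-12)

    def test_threshold_flags(self, two_movement_patterns):
        (dm,) = dissimilarity(two_movement_patterns)
        assert dm.threshold_flag[0, 1]
        assert not dm.threshold_flag[0, 0]


def test_parameter_recovery_monotone_in_noise():
    """Lowering simulator noise monotonically raises intra-subject similarity."""
    from conftest import flexion_pipeline

    means = []
    for factor in (1.0, 0.5, 0.1):
        res = flexion_pipeline(21, n_participants=3, noise_factor=factor)
        means.append(np.mean([r.aggregate for r in res["similarity_reports"]]))
    assert means[0] < means[1] < means[2]
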