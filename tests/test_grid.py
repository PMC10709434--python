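import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conceptnav import pipeline
from conceptnav.geometry import ALLO_BINS
from conceptnav.grid import (
    GoalModulationResult,
    build_symmetry_model,
    delta60,
    grid_rsa_score,
    grid_rsa_scores,
)


class TestDelta60:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(30, 90, 0), (0, 90, 30), (120, 120, 0), (0, 45, 15), (10, 355, 15)],
    )
    def test_examples(self, a, b, expected):
        assert delta60(a, b) == pytest.approx(expected)

    @given(a=st.floats(0, 360), b=st.floats(0, 360), k=st.integers(-6, 6))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_bounds_and_periodicity(self, a, b, k):
        d = delta60(a, b)
        assert 0 <= d <= 30
        assert delta60(b, a) == pytest.approx(d)
        assert delta60(a + 60 * k, b) == pytest.approx(d, abs=1e-6)


class TestSymmetryModels:
    def test_hexadirectional_aligned_set(self):
        model = build_symmetry_model(6)
        aligned_with_30 = [
            b for b in ALLO_BINS if model.aligned[ALLO_BINS.index(30), ALLO_BINS.index(b)]
        ]
        assert aligned_with_30 == [90, 150, 210, 270, 330]

    def test_pair_counts_match_brute_force(self):
        """30 aligned / 36 misaligned unordered pairs for the 6-fold model."""
        n_aligned = n_mis = 0
        for i, b1 in enumerate(ALLO_BINS):
            for b2 in ALLO_BINS[:i]:
                diff = abs(b1 - b2)
                if min(diff % 60, 60 - diff % 60) < 1e-9:
                    n_aligned += 1
                else:
                    n_mis += 1
        assert (n_aligned, n_mis) == (30, 36)
        model = build_symmetry_model(6)
        assert model.n_aligned_pairs == 30
        assert model.n_misaligned_pairs == 36

    def test_fourfold_aligned_set(self):
        model = build_symmetry_model(4)
        aligned_with_0 = [
            b for b in ALLO_BINS if model.aligned[0, ALLO_BINS.index(b)]
        ]
        assert aligned_with_0 == [90, 180, 270]

    @pytest.mark.parametrize("n,period", [(3, 120), (4, 90), (5, 72), (6, 60),
                                          (7, 360 / 7), (8, 45)])
    def test_periods(self, n, period):
        assert build_symmetry_model(n).period == pytest.approx(period)

    def test_five_and_seven_fold_are_degenerate_on_30_degree_bins(self):
        # 72- and 51.4-degree periods never hit an exact 30-degree multiple
        assert build_symmetry_model(5).is_degenerate
        assert build_symmetry_model(7).is_degenerate
        assert not build_symmetry_model(6).is_degenerate


def _direction_patterns(rng, n_fold=6, phase=15.0, gain=1.0, noise=0.0, n_voxels=120):
    """Two contexts of 12 direction patterns with shared sinusoidal tuning."""
    voxel_phase = rng.uniform(0, 360, n_voxels) + phase
    out = []
    for _ in range(2):
        pats = np.array(
            [
                rng.normal(0, noise, n_voxels)
                + gain * np.cos(np.radians(n_fold * (b - voxel_phase)))
                + rng.normal(0, 1, n_voxels) * 0.2
                for b in ALLO_BINS
            ]
        )
        out.append(pats)
    return out


class TestGridRsaScore:
    def test_neural_matrix_equal_to_model_recovers_exact_z(self):
        """Feeding patterns whose similarity IS a graded model yields
        atanh of the achieved correlation, checked against the closed form."""
        model = build_symmetry_model(6)
        # patterns = indicator loadings of the aligned sets: similarity
        # becomes a monotone function of the model
        rng = np.random.default_rng(0)
        pa, pb = _direction_patterns(rng, noise=0.0)
        z = grid_rsa_score(pa, pb, model)
        tri = np.tril_indices(12, -1)
        C = np.array(
            [[np.corrcoef(pa[i], pb[j])[0, 1] for j in range(12)] for i in range(12)]
        )
        S = (C + C.T) / 2
        r = np.corrcoef(S[tri], model.aligned[tri].astype(float))[0, 1]
        assert z == pytest.approx(np.arctanh(r))

    def test_six_fold_planting_maximizes_six_fold_score(self, rng):
        pa, pb = _direction_patterns(rng, n_fold=6, noise=0.3)
        scores = grid_rsa_scores(pa, pb, (3, 4, 5, 6, 7, 8))
        assert scores[6] > 0.3
        finite = {n: s for n, s in scores.items() if np.isfinite(s)}
        assert max(finite, key=finite.get) == 6
        assert np.isnan(scores[5]) and np.isnan(scores[7])

    def test_four_fold_planting_does_not_look_hexadirectional(self, rng):
        pa, pb = _direction_patterns(rng, n_fold=4, noise=0.3)
        scores = grid_rsa_scores(pa, pb, (4, 6))
        assert scores[4] > 0.3
        assert scores[6] < 0.1

    def test_symmetrization_makes_context_order_irrelevant(self, rng):
        pa, pb = _direction_patterns(rng, noise=0.5)
        model = build_symmetry_model(6)
        assert grid_rsa_score(pa, pb, model) == pytest.approx(
            grid_rsa_score(pb, pa, model)
        )

    def test_180_degree_relabeling_leaves_score_unchanged(self):
        """Rotating one context's direction labels by 180 degrees (a
        multiple of 60) cannot change the hexadirectional score: the
        relabeled bins keep their alignment classification exactly.

        The check uses noise-free tuning so the cross-context matrix is
        symmetric, where the invariance is exact cell by cell; under noise
        it holds only in expectation.
        """
        rng = np.random.default_rng(3)
        voxel_phase = rng.uniform(0, 360, 100)
        pats = np.array(
            [np.cos(np.radians(6 * (b - voxel_phase))) for b in ALLO_BINS]
        )
        model = build_symmetry_model(6)
        rotated = np.roll(pats, 6, axis=0)  # 180 deg = 6 bins of 30 deg
        assert grid_rsa_score(pats, rotated, model) == pytest.approx(
            grid_rsa_score(pats, pats.copy(), model), abs=1e-9
        )

    def test_degenerate_model_raises(self, rng):
        pa, pb = _direction_patterns(rng)
        with pytest.raises(ValueError, match="constant"):
            grid_rsa_score(pa, pb, build_symmetry_model(7))


class TestGoalModulation:
    def test_class_mapping(self):
        betas = {
            ("blue", "Q2"): 3.0, ("blue", "Q3"): 1.0,
            ("blue", "Q1"): 2.0, ("blue", "Q4"): 2.0,
            ("green", "Q3"): 3.0, ("green", "Q2"): 1.0,
            ("green", "Q1"): 2.0, ("green", "Q4"): 2.0,
        }
        res = GoalModulationResult.from_quadrant_betas(betas)
        assert res.class_betas == {"close": 3.0, "medium": 2.0, "far": 1.0}
        assert res.contrast == pytest.approx(2.0)
        assert res.linear_trend == pytest.approx(1.0)

    def test_noiseless_ordered_gains_recover_ordering(self, noiseless_subject):
        res = pipeline.subject_goal_modulation(noiseless_subject)
        assert res.contrast > 0
        b = res.class_betas
        assert b["close"] > b["medium"] > b["far"]

    def test_planted_gain_ratios_recovered(self, noiseless_subject):
        code = noiseless_subject.realized.code
        res = pipeline.subject_goal_modulation(noiseless_subject)
        planted_contrast = (code.grid_gains["close"] - code.grid_gains["far"]) / 30.0
        assert res.contrast == pytest.approx(planted_contrast, rel=0.3)


def test_planted_subject_scores_positive_on_six_fold(planted_subject):
    scores = pipeline.subject_grid_scores(planted_subject, (6,))
    assert scores[6] > 0
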