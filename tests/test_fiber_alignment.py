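import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.stats import mannwhitneyu, spearmanr

from biocoil import (
    RatioResult,
    alignment_score,
    combine_ratios,
    fluorescence_ratio,
    mann_whitney,
    structure_tensor,
    synthesize_fibers,
)


class TestStructureTensor:
    def test_constant_image_has_zero_energy_and_coherency(self):
        field = structure_tensor(np.full((64, 64), 3.7))
        assert np.allclose(field.energy, 0.0)
        assert np.all(field.coherency == 0.0)

    def test_diagonal_grating_orientation_and_coherency(self):
        """A 1-D grating along the diagonal has a single gradient direction:
        coherency 1 and a 45-degree orientation in the interior."""
        x = np.arange(128)
        X, Y = np.meshgrid(x, x)
        grating = np.sin(2 * np.pi * (X + Y) / 10.0)
        field = structure_tensor(grating, sigma_gradient=1.0, sigma_window=2.0)
        inner = (slice(20, -20), slice(20, -20))
        assert field.coherency[inner].min() > 0.98
        assert np.abs(np.abs(field.angle_deg[inner]) - 45.0).max() < 1.0

    def test_rotation_equivariance(self):
        img = synthesize_fibers(kappa=4, mean_angle_deg=20, seed=7)
        f0 = structure_tensor(img)
        f90 = structure_tensor(np.rot90(img))
        np.testing.assert_allclose(
            np.rot90(f0.coherency), f90.coherency, atol=1e-10
        )

    def test_coherency_bounded_on_arbitrary_inputs(self):
        """Fuzz: coherency stays in [0,1] for rough, spiky and flat images."""
        rng = np.random.default_rng(123)
        cases = [
            rng.exponential(size=(40, 40)),
            np.zeros((32, 32)),
            rng.integers(0, 2, size=(64, 64)).astype(float) * 1e6,
            np.outer(np.arange(48), np.ones(48)),
        ]
        for img in cases:
            c = structure_tensor(img).coherency
            assert np.all(c >= 0.0) and np.all(c <= 1.0)

    def test_matches_skimage_orientation_and_coherency(self):
        """Cross-check orientation and coherency against the independent
        scikit-image structure tensor (central-difference gradients, so the
        raw tensors differ in scale; the derived angle and coherency must
        agree)."""
        from skimage.feature import structure_tensor as sk_tensor

        img = synthesize_fibers(kappa=2, seed=11, shape=(96, 96))
        mine = structure_tensor(img, sigma_gradient=1.0, sigma_window=3.0)
        Arr, Arc, Acc = sk_tensor(img, sigma=3.0, mode="reflect", order="rc")
        angle_sk = 0.5 * np.degrees(np.arctan2(2 * Arc, Acc - Arr))
        coh_sk = np.sqrt((Arr - Acc) ** 2 + 4 * Arc**2) / np.maximum(Arr + Acc, 1e-12)
        inner = (slice(10, -10), slice(10, -10))
        # axial angle difference, folded to [0, 90]
        dang = np.abs(((mine.angle_deg - angle_sk + 90.0) % 180.0) - 90.0)
        assert np.median(dang[inner]) < 3.0
        assert np.median(np.abs(mine.coherency - coh_sk)[inner]) < 0.05

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            structure_tensor(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            structure_tensor(np.zeros((64, 64)), sigma_gradient=0.0)
        with pytest.raises(ValueError):
            structure_tensor(np.full((64, 64), np.nan))


class TestAlignmentScore:
    def test_parallel_stripes_score_near_100(self):
        y = np.arange(256)[:, None] * np.ones((1, 256))
        stripes = 0.5 + 0.5 * np.sin(2 * np.pi * y / 8.0)
        assert alignment_score(stripes).score >= 95.0

    def test_isotropic_filtered_noise_scores_low(self):
        rng = np.random.default_rng(0)
        noise = ndi.gaussian_filter(rng.normal(size=(256, 256)), 2.0)
        score = alignment_score(noise - noise.min()).score
        assert score <= 20.0  # measured 12.2 for this seed

    def test_intensity_scale_invariance(self):
        img = synthesize_fibers(kappa=4, seed=3)
        s1 = alignment_score(img).score
        s2 = alignment_score(1000.0 * img).score
        assert s2 == pytest.approx(s1, abs=1e-9)

    def test_rotation_invariance(self):
        img = synthesize_fibers(kappa=4, seed=3)
        s1 = alignment_score(img).score
        s2 = alignment_score(np.rot90(img)).score
        assert s2 == pytest.approx(s1, rel=0.02)

    def test_mask_restricts_scoring(self):
        img = synthesize_fibers(kappa=1000, seed=5)
        mask = np.zeros(img.shape, dtype=bool)
        mask[64:192, 64:192] = True
        res = alignment_score(img, mask=mask)
        assert res.n_pixels_used <= mask.sum()
        with pytest.raises(ValueError, match="empty mask"):
            alignment_score(img, mask=np.zeros(img.shape, dtype=bool))

    def test_score_bounds(self):
        for seed in range(3):
            img = synthesize_fibers(kappa=1.0, seed=seed)
            assert 0.0 <= alignment_score(img).score <= 100.0


class TestSynthesizeFibers:
    def test_seed_reproducibility_and_requirement(self):
        a = synthesize_fibers(kappa=2, seed=9)
        b = synthesize_fibers(kappa=2, seed=9)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, synthesize_fibers(kappa=2, seed=10))
        with pytest.raises(ValueError, match="seed"):
            synthesize_fibers(kappa=2)

    def test_nonnegative_and_fiber_signal_present(self):
        img = synthesize_fibers(kappa=0, seed=1)
        assert np.all(img >= 0.0)
        assert img.max() > 0.5  # fibers clearly above background

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            synthesize_fibers(fiber_length=0.0, seed=1)
        with pytest.raises(ValueError):
            synthesize_fibers(kappa=-1.0, seed=1)

    def test_concentrated_orientations_align(self):
        """kappa = 1000 fibers are near-parallel: score >= 90; kappa = 0
        isotropic fibers stay far below (measured ~27 over seeds)."""
        high = alignment_score(synthesize_fibers(kappa=1000.0, seed=0)).score
        low = alignment_score(synthesize_fibers(kappa=0.0, seed=0)).score
        assert high >= 90.0
        assert low <= 35.0
        assert high - low > 40.0

    def test_score_monotone_in_kappa(self):
        """Parameter recovery: mean score over 10 seeds rises monotonically
        with the orientation concentration (Spearman rho >= 0.9)."""
        kappas = [0.0, 1.0, 2.0, 4.0, 8.0, 1000.0]
        means = [
            np.mean(
                [
                    alignment_score(synthesize_fibers(kappa=k, seed=s)).score
                    for s in range(10)
                ]
            )
            for k in kappas
        ]
        rho = spearmanr(kappas, means).statistic
        assert rho >= 0.9


class TestMannWhitney:
    def test_exact_enumeration_small_example(self):
        """a = {1,2,3}, b = {4,5}: U_a = 0; 2 of the 10 equally likely
        labelings are as extreme, so the two-sided exact p = 0.2."""
        res = mann_whitney([1, 2, 3], [4, 5])
        assert res.U == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.2, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.p_value == 1.0

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=7), rng.normal(1.0, 1.0, size=6)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r2.U == pytest.approx(len(a) * len(b) - r1.U)

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(size=6), rng.normal(0.8, 1.0, size=8)
        mine = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine.method == "exact"
        assert mine.U == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_branch_agrees_with_scipy_on_ties(self):
        rng = np.random.default_rng(3)
        a = np.round(rng.normal(size=25), 1)
        b = np.round(rng.normal(0.5, 1.0, size=30), 1)
        mine = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mine.method == "normal"
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_normal_approximation_close_to_exact_at_n8(self):
        """For n_a = n_b = 8 tie-free samples the normal approximation with
        continuity correction tracks exact enumeration within 0.02."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1.0, size=8)
            p_exact = mann_whitney(a, b, method="exact").p_value
            p_norm = mann_whitney(a, b, method="normal").p_value
            assert abs(p_exact - p_norm) < 0.02

    def test_reports_group_summaries(self):
        res = mann_whitney([10.0, 14.5, 20.0], [5.0, 8.7, 12.0])
        assert res.median_a == 14.5
        assert res.median_b == 8.7
        assert res.ratio_of_medians == pytest.approx(14.5 / 8.7)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFluorescenceRatio:
    def test_identical_inputs(self):
        r = fluorescence_ratio((100.0, 10.0), (100.0, 10.0))
        assert r.ratio == 1.0
        assert r.sd == pytest.approx(np.sqrt(2) * 0.1)

    def test_zero_variance(self):
        r = fluorescence_ratio((108.0, 0.0), (100.0, 0.0))
        assert r.ratio == pytest.approx(1.08)
        assert r.sd == 0.0

    def test_propagation_formula(self):
        r = fluorescence_ratio((110.0, 11.0), (100.0, 10.0))
        assert r.ratio == pytest.approx(1.10)
        assert r.sd == pytest.approx(1.10 * np.sqrt(0.01 + 0.01), rel=1e-12)
        assert r.sd == pytest.approx(0.1556, abs=1e-4)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fluorescence_ratio((110.0, 1.0), (0.0, 1.0))

    def test_inverse_variance_combination(self):
        combined = combine_ratios(
            [RatioResult(1.1, 0.1), RatioResult(1.0, 0.1), RatioResult(1.2, 0.2)]
        )
        w = np.array([100.0, 100.0, 25.0])
        assert combined.ratio == pytest.approx(
            (w * np.array([1.1, 1.0, 1.2])).sum() / w.sum()
        )
        assert combined.sd == pytest.approx(1.0 / np.sqrt(w.sum()))
        with pytest.raises(ValueError):
            combine_ratios([RatioResult(1.0, 0.0)])
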