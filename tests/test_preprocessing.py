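import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnirscal.preprocessing import (
    MathTreatment,
    Recipe,
    ScatterCorrection,
    detrend,
    gap_segment_derivative,
    msc,
    snv,
)
from fnirscal.spectra_io import SpectraSet, default_grid


class TestMathTreatmentCode:
    def test_parse_round_trips(self):
        assert str(MathTreatment.parse("1.4.4.1")) == "1.4.4.1"
        assert MathTreatment.parse("2.5.5.1") == MathTreatment(2, 5, 5, 1)

    @pytest.mark.parametrize("bad", ["3.4.4.1", "1.0.4.1", "1.4", "a.b.c.d"])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            MathTreatment.parse(bad)


class TestSnv:
    def test_three_point_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_output_mean_zero_sd_one(self, rng):
        X = rng.normal(0.5, 0.2, (8, 120))
        out = snv(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            snv(np.array([5.0, 5.0, 5.0]))

    def test_idempotent(self, rng):
        X = rng.normal(0.5, 0.2, (5, 80))
        np.testing.assert_allclose(snv(snv(X)), snv(X), atol=1e-10)

    def test_row_order_invariant(self, rng):
        X = rng.normal(0.5, 0.2, (6, 50))
        perm = rng.permutation(6)
        np.testing.assert_allclose(snv(X)[perm], snv(X[perm]))


class TestDetrend:
    def test_annihilates_quadratic(self, grid):
        wl = grid
        spec = 0.3 + 1e-4 * wl + 2e-8 * wl**2
        out = detrend(spec, wl, order=2)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_residual_orthogonal_to_basis(self, rng, grid):
        spec = rng.normal(0.5, 0.1, grid.size)
        out = detrend(spec, grid, order=2)
        w = 2 * (grid - grid.min()) / (grid.max() - grid.min()) - 1
        for k in range(3):
            assert abs(out @ w**k) < 1e-8 * np.linalg.norm(out)

    def test_matches_normal_equations_oracle(self, rng):
        wl = default_grid(1100, 1298, 2)
        spec = rng.normal(0.5, 0.1, wl.size)
        # independent oracle: explicit normal equations on the raw wavelength basis
        B = np.vander(wl, 3, increasing=True)
        coef = np.linalg.solve(B.T @ B, B.T @ spec)
        np.testing.assert_allclose(detrend(spec, wl, 2), spec - B @ coef, atol=1e-8)


class TestMsc:
    def test_inverts_affine_distortion(self, rng, grid):
        ref = np.sin(grid / 200) + 1.0
        x = 3.0 + 2.0 * ref
        np.testing.assert_allclose(msc(x, ref), ref, atol=1e-10)

    def test_reference_passes_through(self, grid):
        ref = np.cos(grid / 300) + 2.0
        np.testing.assert_allclose(msc(ref, ref), ref, atol=1e-12)

    def test_batch_equals_per_spectrum_loop(self, rng, grid):
        ref = np.sin(grid / 150) + 1.5
        X = np.vstack([a + b * ref + rng.normal(0, 0.01, grid.size)
                       for a, b in [(0.1, 0.8), (-0.2, 1.3), (0.4, 2.1)]])
        batch = msc(X, ref)
        # scalar-regression oracle, one spectrum at a time
        for i in range(X.shape[0]):
            b = np.polyfit(ref, X[i], 1)[0]
            a = X[i].mean() - b * ref.mean()
            np.testing.assert_allclose(batch[i], (X[i] - a) / b, atol=1e-10)

    def test_zero_slope_rejected(self, grid):
        ref = np.sin(grid / 200) + 1.0
        flatish = np.full(grid.size, 0.7)
        with pytest.raises(ValueError, match="slope"):
            msc(flatish, ref)


class TestGapSegmentDerivative:
    def test_constant_spectrum_gives_zero(self, grid):
        spec = np.full(grid.size, 0.7)
        for code in ("1.4.4.1", "2.4.4.1", "1.5.5.1", "2.5.5.1"):
            out, _ = gap_segment_derivative(spec, grid, MathTreatment.parse(code))
            np.testing.assert_allclose(out, 0.0, atol=1e-14)

    @pytest.mark.parametrize("gap", [2, 3, 4, 5])
    def test_linear_ramp_first_derivative(self, gap):
        wl = default_grid(1100, 1298, 2)
        m = 0.003
        spec = m * np.arange(wl.size)
        out, _ = gap_segment_derivative(spec, wl, MathTreatment(1, gap, 1, 1))
        np.testing.assert_allclose(out, m * gap, atol=1e-12)

    @pytest.mark.parametrize("gap", [2, 4, 5])
    def test_quadratic_second_derivative(self, gap):
        wl = default_grid(1100, 1298, 2)
        i = np.arange(wl.size, dtype=float)
        out, _ = gap_segment_derivative(i**2, wl, MathTreatment(2, gap, 1, 1))
        np.testing.assert_allclose(out, 2.0 * gap**2, atol=1e-9)

    def test_smoothing_only_keeps_running_mean(self):
        wl = default_grid(1100, 1120, 2)
        spec = np.arange(wl.size, dtype=float) ** 1.5
        out, new_wl = gap_segment_derivative(spec, wl, MathTreatment(0, 1, 3, 1))
        expected = np.convolve(spec, np.ones(3) / 3, mode="valid")
        np.testing.assert_allclose(out, expected)
        np.testing.assert_allclose(new_wl, wl[1:-1])

    def test_linearity(self, rng, grid):
        t = MathTreatment.parse("2.4.4.1")
        x = rng.normal(0, 1, grid.size)
        y = rng.normal(0, 1, grid.size)
        a, b = 2.5, -1.3
        left, _ = gap_segment_derivative(a * x + b * y, grid, t)
        dx, _ = gap_segment_derivative(x, grid, t)
        dy, _ = gap_segment_derivative(y, grid, t)
        np.testing.assert_allclose(left, a * dx + b * dy, atol=1e-10)

    def test_short_spectrum_error_names_length(self):
        wl = default_grid(1100, 1110, 2)
        t = MathTreatment.parse("2.4.4.1")
        with pytest.raises(ValueError, match=str(t.min_length)):
            gap_segment_derivative(np.zeros(wl.size), wl, t)

    def test_grid_stays_uniform(self, rng, grid):
        for code in ("1.4.4.1", "2.5.5.1", "1.5.5.1"):
            _, wl = gap_segment_derivative(rng.normal(0, 1, grid.size), grid,
                                           MathTreatment.parse(code))
            steps = np.diff(wl)
            np.testing.assert_allclose(steps, steps[0])


class TestRecipe:
    def test_identity_recipe_is_noop(self, random_spectra):
        out = Recipe.parse("none/0.1.1.1").fit(random_spectra).apply(random_spectra)
        np.testing.assert_allclose(out.absorbance, random_spectra.absorbance)
        np.testing.assert_allclose(out.wavelengths, random_spectra.wavelengths)

    def test_batch_composition_matches_per_spectrum(self, random_spectra):
        recipe = Recipe.parse("SNV/1.4.4.1").fit(random_spectra)
        batch = recipe.apply(random_spectra)
        for i in range(random_spectra.n_samples):
            single = recipe.apply(random_spectra.select([i]))
            np.testing.assert_allclose(batch.absorbance[i], single.absorbance[0],
                                       atol=1e-12)

    def test_msc_reference_fixed_at_fit_time(self, random_spectra, rng, grid):
        recipe = Recipe.parse("MSC/1.4.4.1").fit(random_spectra)
        stored = recipe.scatter.reference.copy()
        other = SpectraSet(["z"], grid, rng.normal(0.4, 0.1, (1, grid.size)))
        recipe.apply(other)
        np.testing.assert_array_equal(recipe.scatter.reference, stored)

    def test_msc_unfitted_use_raises(self, random_spectra):
        with pytest.raises(RuntimeError, match="before fit"):
            Recipe.parse("MSC/1.4.4.1").apply(random_spectra)

    def test_recipe_string_round_trip(self):
        for text in ("SNV/1.4.4.1", "SNV+D/2.4.4.1", "MSC/2.5.5.1", "none/0.1.1.1"):
            assert str(Recipe.parse(text)) == text


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_snv_mean_sd_property(seed):
    """SNV output always has per-spectrum mean 0 and sample sd 1."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.5, rng.uniform(0.05, 1.0), (3, 40))
    out = snv(X)
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)
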