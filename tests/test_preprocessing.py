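"""Preprocessing: referencing, bucket integration, Pareto scaling,
mean/difference spectra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metabodx import (BucketTable, DataError, Spectrum, ValidationError,
                      apply_pareto, assemble_bucket_table, bucket_spectrum,
                      difference_spectrum, fit_pareto, mean_spectrum,
                      reference_to_lactate)

from conftest import fine_axis


def lorentzian(x, x0, fwhm, area=1.0):
    g = fwhm / 2.0
    return area * (g / np.pi) / ((x - x0) ** 2 + g ** 2)


class TestReferencing:
    def test_apex_moved_to_133(self):
        x = fine_axis()
        s = Spectrum(x, lorentzian(x, 1.35, 0.004), "a")
        out = reference_to_lactate(s)
        assert out.meta["reference_shift"] == pytest.approx(-0.02, abs=1e-9)
        apex = out.ppm[np.argmax(out.intensity)]
        assert apex == pytest.approx(1.33, abs=1e-9)

    def test_identity_when_already_referenced(self):
        x = fine_axis()
        s = Spectrum(x, lorentzian(x, 1.33, 0.004), "a")
        out = reference_to_lactate(s)
        assert out.meta["reference_shift"] == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(out.intensity, s.intensity)

    def test_flat_spectrum_flags_warning_without_shift(self):
        x = fine_axis(10001)
        s = Spectrum(x, np.zeros_like(x), "flat")
        out = reference_to_lactate(s)
        assert out.meta["reference_warning"] is True
        assert np.array_equal(out.ppm, s.ppm)

    def test_empty_window_rejected(self):
        x = np.linspace(5.0, 9.0, 5001)
        s = Spectrum(x, np.ones_like(x), "a")
        with pytest.raises(DataError):
            reference_to_lactate(s)

    def test_idempotent(self):
        x = fine_axis()
        s = Spectrum(x, lorentzian(x, 1.352, 0.004) + lorentzian(x, 5.0, 0.01),
                     "a")
        once = reference_to_lactate(s)
        twice = reference_to_lactate(once)
        assert np.allclose(once.ppm, twice.ppm, atol=1e-12)


class TestBucketing:
    def test_default_grid_has_898_buckets(self):
        x = fine_axis(8192)
        integ, centers = bucket_spectrum(Spectrum(x, np.zeros_like(x), "a"))
        assert centers.size == 898
        # water band absent: no center inside [4.50, 5.00)
        assert not np.any((centers >= 4.50) & (centers < 5.00))

    def test_constant_intensity_gives_width_area(self):
        x = fine_axis(8192)
        integ, _ = bucket_spectrum(Spectrum(x, np.ones_like(x), "a"))
        assert np.max(np.abs(integ - 0.01)) < 1e-9

    def test_narrow_peak_mass_concentrates_in_its_bucket(self):
        x = fine_axis(100001)
        s = Spectrum(x, lorentzian(x, 2.005, 0.001), "a")
        integ, centers = bucket_spectrum(s)
        j = np.argmin(np.abs(centers - 2.005))
        assert integ[j] > 0.9 * integ.sum()

    def test_additivity_of_split_intensity(self):
        rng = np.random.default_rng(0)
        x = fine_axis(8192)
        total = np.abs(rng.normal(size=x.size))
        u = rng.uniform(size=x.size)
        a, _ = bucket_spectrum(Spectrum(x, total * u, "a"))
        b, _ = bucket_spectrum(Spectrum(x, total * (1 - u), "b"))
        ref, _ = bucket_spectrum(Spectrum(x, total, "c"))
        assert np.allclose(a + b, ref, atol=1e-10)

    def test_coarse_axis_rejected(self):
        x = fine_axis(600)  # ~0.017 ppm spacing vs 0.01 buckets
        with pytest.raises(DataError, match="coarse"):
            bucket_spectrum(Spectrum(x, np.zeros_like(x), "a"))

    def test_descending_axis_same_result(self):
        x = fine_axis(8192)
        y = lorentzian(x, 3.0, 0.02)
        asc, _ = bucket_spectrum(Spectrum(x, y, "a"))
        desc, _ = bucket_spectrum(Spectrum(x[::-1].copy(), y[::-1].copy(), "b"))
        assert np.allclose(asc, desc, atol=1e-12)


class TestAssemble:
    def test_identical_spectra_identical_rows(self):
        x = fine_axis(8192)
        specs = [Spectrum(x, lorentzian(x, 3.0, 0.01), f"s{i}") for i in range(3)]
        t = assemble_bucket_table(specs, labels=[0, 0, 1])
        assert np.array_equal(t.matrix[0], t.matrix[1])
        assert np.array_equal(t.matrix[0], t.matrix[2])

    def test_duplicate_sample_id_rejected(self):
        x = fine_axis(8192)
        specs = [Spectrum(x, np.zeros_like(x), "dup") for _ in range(2)]
        with pytest.raises(ValidationError, match="dup"):
            assemble_bucket_table(specs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            assemble_bucket_table([])

    def test_insufficient_coverage_names_sample(self):
        x_full = fine_axis(8192)
        x_short = np.linspace(1.0, 5.0, 8192)
        specs = [Spectrum(x_full, np.zeros_like(x_full), "ok"),
                 Spectrum(x_short, np.zeros_like(x_short), "short")]
        with pytest.raises(DataError, match="short"):
            assemble_bucket_table(specs)


def _table(matrix):
    matrix = np.asarray(matrix, dtype=float)
    centers = 0.205 + 0.01 * np.arange(matrix.shape[1])
    return BucketTable(matrix, centers, 0.01,
                       [f"s{i}" for i in range(matrix.shape[0])])


class TestPareto:
    def test_three_point_column(self):
        t = _table([[1.0], [2.0], [3.0]])
        m = fit_pareto(t)
        assert m.mean[0] == pytest.approx(2.0)
        assert m.scale[0] == pytest.approx(1.0)
        scaled = apply_pareto(t, m)
        assert np.allclose(scaled.matrix[:, 0], [-1.0, 0.0, 1.0])

    def test_unequal_column(self):
        t = _table([[0.0], [0.0], [4.0], [4.0]])
        m = fit_pareto(t)
        assert m.scale[0] == pytest.approx(np.sqrt(np.sqrt(16 / 3)), abs=1e-4)
        scaled = apply_pareto(t, m)
        assert np.allclose(scaled.matrix[:, 0], [-1.316, -1.316, 1.316, 1.316],
                           atol=1e-3)

    def test_constant_column_degenerate(self):
        t = _table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        m = fit_pareto(t)
        assert m.degenerate[0] and not m.degenerate[1]
        scaled = apply_pareto(t, m)
        assert np.all(scaled.matrix[:, 0] == 0.0)

    def test_roundtrip_mean_zero_and_variance_equals_sd(self):
        rng = np.random.default_rng(3)
        t = _table(rng.lognormal(size=(20, 7)))
        m = fit_pareto(t)
        scaled = apply_pareto(t, m).matrix
        assert np.max(np.abs(scaled.mean(axis=0))) < 1e-10
        sd = t.matrix.std(axis=0, ddof=1)
        assert np.allclose(scaled.var(axis=0, ddof=1), sd, rtol=1e-10)

    def test_apply_never_refits(self):
        train = _table([[0.0], [2.0]])
        m = fit_pareto(train)
        test = _table([[10.0], [12.0], [14.0]])
        scaled = apply_pareto(test, m)
        # scaled with train mean 1 and scale sqrt(sd=sqrt2)
        expected = (np.array([10.0, 12.0, 14.0]) - 1.0) / np.sqrt(np.sqrt(2.0))
        assert np.allclose(scaled.matrix[:, 0], expected)

    def test_bucket_count_mismatch_rejected(self):
        m = fit_pareto(_table([[1.0, 2.0], [3.0, 4.0]]))
        with pytest.raises(ValidationError):
            apply_pareto(_table([[1.0]]), m)

    def test_single_sample_fit_rejected(self):
        with pytest.raises(ValidationError):
            fit_pareto(_table([[1.0]]))


class TestMeanDifference:
    def test_mean_of_identical_spectra(self):
        x = fine_axis(2001)
        y = lorentzian(x, 3.0, 0.02)
        m = mean_spectrum([Spectrum(x, y, f"s{i}") for i in range(4)])
        assert np.allclose(m.intensity, y)

    def test_self_difference_is_zero(self):
        x = fine_axis(2001)
        s = Spectrum(x, lorentzian(x, 3.0, 0.02), "a")
        d = difference_spectrum(s, s)
        assert np.all(d.intensity == 0.0)

    def test_hand_arithmetic(self):
        x = np.array([1.0, 2.0])
        a = mean_spectrum([Spectrum(x, [0.0, 4.0], "a1"),
                           Spectrum(x, [0.0, 0.0], "a2")])  # mean [0, 2]
        b = mean_spectrum([Spectrum(x, [1.0, 1.0], "b1"),
                           Spectrum(x, [1.0, 1.0], "b2")])  # mean [1, 1]
        d = difference_spectrum(a, b)
        assert np.allclose(d.intensity, [-1.0, 1.0])

    def test_axis_mismatch_rejected(self):
        a = Spectrum(np.array([1.0, 2.0]), [0.0, 0.0], "a")
        b = Spectrum(np.array([1.0, 3.0]), [0.0, 0.0], "b")
        with pytest.raises(ValidationError):
            difference_spectrum(a, b)


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_bucket_additivity_property(seed):
    """Trapezoid linearity: bucketing is additive over any nonnegative
    split of the intensity."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 10.0, 4096)
    total = np.abs(rng.normal(size=x.size))
    u = rng.uniform(size=x.size)
    region, width = (1.0, 3.0), 0.02
    a, _ = bucket_spectrum(Spectrum(x, total * u, "a"), region, width, ())
    b, _ = bucket_spectrum(Spectrum(x, total * (1 - u), "b"), region, width, ())
    ref, _ = bucket_spectrum(Spectrum(x, total, "c"), region, width, ())
    assert np.allclose(a + b, ref, atol=1e-10)
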