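import math

import numpy as np
import pytest

import postshim as ps
from postshim.generator import (
    WIDTH_SIGMA_RATIO,
    LGComponent,
    MultipletSpec,
    lg_peak,
    multiplet_heights,
    render_multiplet,
    sample_batch,
    sample_spectrum,
)


class TestLGPeak:
    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.7, 1.0])
    def test_value_at_center_is_height(self, gamma):
        comp = LGComponent(height=3.7, gaussian_fraction=gamma, center=5.0, width=1.1)
        assert lg_peak(np.array([5.0]), comp)[0] == pytest.approx(3.7)

    def test_lorentzian_half_height_at_half_width(self):
        comp = LGComponent(height=2.0, gaussian_fraction=0.0, center=0.0, width=0.8)
        vals = lg_peak(np.array([-0.8, 0.8]), comp)
        assert np.allclose(vals, 1.0)

    def test_gaussian_half_height_confirms_width_tie(self):
        comp = LGComponent(height=2.0, gaussian_fraction=1.0, center=0.0, width=0.8)
        # sigma * sqrt(2 ln 2) == w, so the Gaussian halves exactly at +-w
        assert comp.sigma == pytest.approx(0.8 / WIDTH_SIGMA_RATIO)
        vals = lg_peak(np.array([-0.8, 0.8]), comp)
        assert np.allclose(vals, 1.0)

    def test_random_draws_satisfy_center_and_half_height(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h = rng.uniform(0.1, 10)
            w = rng.uniform(0.2, 2.0)
            c = rng.uniform(-50, 50)
            for gamma in (0.0, 1.0):
                comp = LGComponent(height=h, gaussian_fraction=gamma, center=c, width=w)
                assert lg_peak(np.array([c]), comp)[0] == pytest.approx(h)
                assert lg_peak(np.array([c + w]), comp)[0] == pytest.approx(h / 2)


class TestMultipletHeights:
    @pytest.mark.parametrize(
        "m,expected",
        [
            (1, [1.0]),
            (2, [0.5, 0.5]),
            (3, [0.25, 0.5, 0.25]),
            (5, [1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16]),
            (7, [math.comb(6, k) / 64 for k in range(7)]),
        ],
    )
    def test_unit_sum_binomial_rows(self, m, expected):
        assert np.allclose(multiplet_heights(m), expected)

    def test_out_of_range_rejected(self):
        for m in (0, 8, -1):
            with pytest.raises(ValueError):
                multiplet_heights(m)


class TestRenderMultiplet:
    def _grid(self, n=2048, step=0.3406):
        return (np.arange(n) - n // 2) * step

    def test_singlet_height(self):
        grid = self._grid()
        spec = MultipletSpec(
            multiplicity=1, j1=0, j2=0, width=1.5, intensity=2.0,
            height_factor=1.5, gaussian_fraction=0.0, center=0.0,
        )
        vals = render_multiplet(grid, spec, width_factor=0.5, height_factor=1.2)
        assert vals.max() == pytest.approx(2.0 * 1.5 * 1.2, rel=1e-6)

    def test_doublet_positions_and_heights(self):
        grid = self._grid()
        spec = MultipletSpec(
            multiplicity=2, j1=10.0, j2=0, width=1.0, intensity=1.0,
            height_factor=1.0, gaussian_fraction=1.0, center=0.0,
        )
        vals = render_multiplet(grid, spec, width_factor=0.5, height_factor=1.0)
        peaks = grid[np.nonzero((vals > np.roll(vals, 1)) & (vals > np.roll(vals, -1)))[0]]
        assert len(peaks) == 2
        assert peaks[1] - peaks[0] == pytest.approx(10.0, abs=0.5)
        # 1:1 weights of 0.5 each, up to grid discretization of the maximum
        assert vals.max() == pytest.approx(0.5, abs=0.02)

    def test_secondary_split_conserves_area(self):
        grid = self._grid(4096)
        # pure Gaussian components: no truncated Lorentzian tails, so the
        # finite-grid integral conserves area to full precision
        base = dict(
            multiplicity=3, j1=8.0, width=1.2, intensity=2.0,
            height_factor=1.0, gaussian_fraction=1.0, center=0.0,
        )
        unsplit = render_multiplet(
            grid, MultipletSpec(j2=2.0, secondary_split=False, **base), 0.5, 1.0
        )
        split = render_multiplet(
            grid, MultipletSpec(j2=2.0, secondary_split=True, **base), 0.5, 1.0
        )
        assert np.trapezoid(split, grid) == pytest.approx(np.trapezoid(unsplit, grid), rel=1e-9)


class TestSampleSpectrum:
    def _config(self, **kw):
        kw.setdefault("n_points", 2048)
        return ps.SpectrumSamplingConfig(freq_step=0.3406, **kw)

    def test_seed_determinism(self):
        config = self._config()
        a, ra = sample_spectrum(config, np.random.default_rng(42))
        b, rb = sample_spectrum(config, np.random.default_rng(42))
        assert np.array_equal(a, b)
        assert ra["n_multiplets"] == rb["n_multiplets"]

    def test_parameters_within_documented_ranges(self):
        config = self._config()
        rng = np.random.default_rng(7)
        omega_half = config.effective_center_half_range()
        for _ in range(300):
            _, rec = sample_spectrum(config, rng)
            assert 2 <= rec["n_multiplets"] <= 5
            assert 0.2 <= rec["width_factor"] <= 1.0
            assert 0.5 <= rec["height_factor"] <= 2.0
            for m in rec["multiplets"]:
                assert 1 <= m.multiplicity <= 7
                assert 0.0 <= m.j1 <= 15.0 and 0.0 <= m.j2 <= 15.0
                assert 1.0 <= m.width <= 2.0
                assert 1.0 <= m.intensity <= 3.0
                assert 0.5 <= m.height_factor <= 4.0
                assert 0.0 <= m.gaussian_fraction <= 1.0
                assert -omega_half <= m.center <= omega_half

    def test_center_range_clipped_on_narrow_grids(self):
        narrow = self._config(n_points=256)
        half_span = 0.5 * 255 * 0.3406
        assert narrow.effective_center_half_range() == pytest.approx(0.9 * half_span)
        wide = ps.SpectrumSamplingConfig(freq_step=1.0, n_points=2048)
        assert wide.effective_center_half_range() == pytest.approx(279.02)


class TestMakeTrainingExample:
    def test_impulse_library_no_noise_is_identity(self, freq_step):
        imp = np.zeros(63)
        imp[31] = 1.0
        lib = ps.ResponseLibrary(imp[None, :], freq_step)
        clean = np.random.default_rng(0).uniform(0, 4, 512)
        ex = ps.make_training_example(clean, lib, noise_max=0.0, rng=np.random.default_rng(1))
        assert np.allclose(ex.distorted, clean, atol=1e-12)
        assert np.array_equal(ex.response, imp)

    def test_matches_direct_sum_convolution(self, small_library):
        rng = np.random.default_rng(3)
        clean = rng.uniform(0, 4, 256)
        ex = ps.make_training_example(clean, small_library, noise_max=0.0, rng=np.random.default_rng(9))
        r = ex.response
        c = (len(r) - 1) // 2
        expected = np.zeros_like(clean)
        for n in range(len(clean)):
            for j in range(len(r)):
                m = n - (j - c)
                if 0 <= m < len(clean):
                    expected[n] += r[j] * clean[m]
        assert np.allclose(ex.distorted, expected, atol=1e-12)

    def test_seed_reproducibility(self, small_library):
        clean = np.random.default_rng(5).uniform(0, 4, 512)
        a = ps.make_training_example(clean, small_library, 0.02, np.random.default_rng(77))
        b = ps.make_training_example(clean, small_library, 0.02, np.random.default_rng(77))
        assert np.array_equal(a.distorted, b.distorted)
        assert a.noise_sd == b.noise_sd

    def test_area_conserved_for_interior_peaks(self, small_library, freq_step):
        grid = (np.arange(2048) - 1024) * freq_step
        comp = LGComponent(height=5.0, gaussian_fraction=1.0, center=0.0, width=1.0)
        clean = lg_peak(grid, comp)
        ex = ps.make_training_example(clean, small_library, 0.0, np.random.default_rng(2))
        assert ex.distorted.sum() == pytest.approx(clean.sum(), rel=1e-6)

    def test_empty_library_rejected(self, freq_step):
        lib = ps.ResponseLibrary(np.zeros((0, 63)), freq_step)
        with pytest.raises(ValueError, match="empty"):
            ps.make_training_example(np.ones(256), lib, 0.0, np.random.default_rng(0))
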