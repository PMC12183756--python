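"""Synthetic calibration experiment: mis-shimmed singlet spectra with known
ground-truth response functions.

The real calibration experiment scans the two lowest axial shim coils (Z1,
Z2) around their optimum and records a narrow-singlet spectrum at each
setting.  Here the sample column is a uniform coordinate z in [-1, 1] and the
two coils add field offsets shaped like the first two Legendre polynomials,

    delta(z) = kappa1 * z1 * z  +  kappa2 * z2 * (3 z**2 - 1) / 2   [Hz]

so the inhomogeneity response is the probability density of delta(z) under
uniform z, convolved with the natural Lorentzian line.  Setting (0, 0) is
the perfectly shimmed state, whose response collapses to the natural line.

The calibration sample emulates a long-T2 chloroform-like singlet: the
natural half-width default (0.008 Hz) corresponds to T2 ~ 20 s, far below
the frequency step, so the observed calibration peaks are dominated by the
inhomogeneity — exactly the regime the calibration experiment is designed
for.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .extraction import ResponseFunction, conv_same
from .spectrum import Spectrum1D, write_spectrum_text

__all__ = [
    "ShimSetting",
    "CalibrationGrid",
    "FieldModel",
    "ResponseWindowError",
    "simulate_response",
    "simulate_ideal_singlet",
    "simulate_calibration_spectrum",
    "grid_settings",
    "simulate_calibration_dataset",
]

#: quadrature points along the sample column for the density of delta(z)
N_QUADRATURE = 200_000

#: fine-grid oversampling factor relative to the output step
OVERSAMPLE = 8

#: maximum tolerated response mass outside the N-point window
WINDOW_MASS_TOL = 1e-3


class ResponseWindowError(ValueError):
    """Response function does not fit the N-point window at this setting."""


@dataclass(frozen=True)
class ShimSetting:
    """Currents of the Z1/Z2 shim coils relative to the optimum (a.u.)."""

    z1: float
    z2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z1) and np.isfinite(self.z2)):
            raise ValueError("shim currents must be finite")


@dataclass(frozen=True)
class CalibrationGrid:
    """Rectangular scan of (z1, z2) settings, inclusive of both endpoints."""

    z1_start: float
    z1_stop: float
    z1_step: float
    z2_start: float
    z2_stop: float
    z2_step: float

    def __post_init__(self) -> None:
        if self.z1_step <= 0 or self.z2_step <= 0:
            raise ValueError("grid steps must be > 0")
        if self.z1_stop < self.z1_start or self.z2_stop < self.z2_start:
            raise ValueError("grid stop must be >= start")

    @property
    def n1(self) -> int:
        return int(np.floor((self.z1_stop - self.z1_start) / self.z1_step + 1e-9)) + 1

    @property
    def n2(self) -> int:
        return int(np.floor((self.z2_stop - self.z2_start) / self.z2_step + 1e-9)) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n1, self.n2)


@dataclass(frozen=True)
class FieldModel:
    """Physical stand-in mapping shim currents to spectral distortion.

    Attributes
    ----------
    kappa1, kappa2
        Coupling of the Z1 / Z2 currents to the linear / quadratic axial
        field profiles, in Hz per shim unit.  The defaults put the widest
        response of a +-100-unit scan near 18 Hz, comfortably inside a
        21 Hz window.
    w_nat
        Natural Lorentzian half-width at half-maximum of the calibration
        singlet (Hz).
    omega_s
        Singlet frequency (Hz).
    height
        Singlet peak height (a.u.).
    """

    kappa1: float = 0.045
    kappa2: float = 0.060
    w_nat: float = 0.008
    omega_s: float = 0.0
    height: float = 16.0

    def __post_init__(self) -> None:
        if not self.w_nat > 0:
            raise ValueError("w_nat must be > 0")
        if not (np.isfinite(self.kappa1) and np.isfinite(self.kappa2)):
            raise ValueError("couplings must be finite")

    def field_offset(self, setting: ShimSetting, z: np.ndarray) -> np.ndarray:
        """Frequency offset delta(z) along the sample column (Hz)."""
        return (
            self.kappa1 * setting.z1 * z
            + self.kappa2 * setting.z2 * 0.5 * (3.0 * z**2 - 1.0)
        )


def _lorentzian_cell_masses(centers: np.ndarray, step: float, hwhm: float) -> np.ndarray:
    """Integral of a unit-area Lorentzian over cells centered at ``centers``."""
    lo = (centers - 0.5 * step) / hwhm
    hi = (centers + 0.5 * step) / hwhm
    return (np.arctan(hi) - np.arctan(lo)) / np.pi


def simulate_response(
    setting: ShimSetting, model: FieldModel, freq_step: float, n_response: int
) -> ResponseFunction:
    """Ground-truth response function of one shim setting.

    The density of delta(z) is accumulated by midpoint quadrature over the
    sample column onto a fine grid of step ``freq_step / 8``, convolved with
    the cell-integrated natural Lorentzian, box-summed to the output step and
    renormalized to unit sum.  If more than 0.1% of the mass falls outside
    the ``n_response``-point window the setting is rejected — the window is
    too small for this distortion.
    """
    if n_response < 1 or n_response % 2 == 0:
        raise ValueError(f"n_response must be odd and >= 1, got {n_response}")
    if not freq_step > 0:
        raise ValueError(f"freq_step must be > 0, got {freq_step}")

    d = freq_step / OVERSAMPLE
    n_ext = 3 * n_response  # extended coarse window for convolution tails
    m_half = (OVERSAMPLE * n_ext) // 2
    m_fine = 2 * m_half + 1  # odd; fine centers at integer multiples of d
    centers = (np.arange(m_fine) - m_half) * d
    edges = np.concatenate([centers - 0.5 * d, [centers[-1] + 0.5 * d]])

    # midpoint quadrature over the sample column -> density of delta(z)
    z = (np.arange(N_QUADRATURE) + 0.5) / N_QUADRATURE * 2.0 - 1.0
    delta = model.field_offset(setting, z)
    if np.max(np.abs(delta)) >= centers[-1]:
        raise ResponseWindowError(
            f"field offsets reach {np.max(np.abs(delta)):.3g} Hz, beyond the "
            f"extended simulation window {centers[-1]:.3g} Hz at setting {setting}"
        )
    dens, _ = np.histogram(delta, bins=edges)
    dens = dens / float(N_QUADRATURE)

    kern = _lorentzian_cell_masses(centers, d, model.w_nat)

    # full convolution of two integer-centered grids: cell i of the full
    # product sits at (i - (m_fine - 1)) * d, again an integer multiple of d
    full = np.convolve(dens, kern)
    zero_idx = m_fine - 1  # index of frequency offset 0 in `full`

    # integrate 8 fine cells per coarse cell; the two boundary cells
    # straddle adjacent coarse cells, so they contribute half each --
    # this keeps the discretization exactly mirror-symmetric
    box = np.ones(OVERSAMPLE + 1)
    box[0] = box[-1] = 0.5
    half = (n_response - 1) // 2
    coarse = np.zeros(n_response)
    for m in range(-half, half + 1):
        idx = zero_idx + OVERSAMPLE * m + np.arange(-(OVERSAMPLE // 2), OVERSAMPLE // 2 + 1)
        coarse[m + half] = float(np.dot(box, full[idx]))

    outside = 1.0 - coarse.sum()  # density and kernel both have unit analytic mass
    if outside >= WINDOW_MASS_TOL:
        raise ResponseWindowError(
            f"{outside:.3e} of the response mass falls outside the "
            f"{n_response}-point window at setting {setting}; increase W / N"
        )
    coarse /= coarse.sum()
    return ResponseFunction(values=coarse, freq_step=freq_step, setting=(setting.z1, setting.z2))


def _singlet_grid(model: FieldModel, freq_step: float, n_points: int) -> np.ndarray:
    start = model.omega_s - (n_points // 2) * freq_step
    return start + freq_step * np.arange(n_points)


def simulate_ideal_singlet(
    model: FieldModel, freq_step: float, n_points: int
) -> Spectrum1D:
    """The undistorted calibration singlet: a pure natural-width Lorentzian.

    This is the reference whose convolution with each ground-truth response
    yields the simulated calibration spectra, and hence the reference to
    deconvolve against when validating response extraction end to end.
    """
    if n_points < 128:
        raise ValueError(f"n_points must be >= 128, got {n_points}")
    freqs = _singlet_grid(model, freq_step, n_points)
    vals = model.height * model.w_nat**2 / (model.w_nat**2 + (freqs - model.omega_s) ** 2)
    return Spectrum1D(freqs[0], freq_step, vals, {"role": "ideal_singlet"})


def simulate_calibration_spectrum(
    setting: ShimSetting,
    model: FieldModel,
    freq_step: float,
    n_points: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum1D:
    """One mis-shimmed calibration spectrum.

    The ideal singlet is convolved with the setting's ground-truth response
    and white Gaussian noise of standard deviation ``noise_sd`` is added;
    reproducible under ``seed``.
    """
    ideal = simulate_ideal_singlet(model, freq_step, n_points)
    plan_n = _default_response_length(setting, model, freq_step)
    resp = simulate_response(setting, model, freq_step, plan_n)
    vals = conv_same(ideal.values, resp.values)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    meta = {"z1": f"{setting.z1:g}", "z2": f"{setting.z2:g}"}
    return Spectrum1D(ideal.freq_start, freq_step, vals, meta)


def _default_response_length(
    setting: ShimSetting, model: FieldModel, freq_step: float
) -> int:
    """Odd window length generously covering this setting's field offsets.

    The half-window must clear both the inhomogeneity width and the natural
    Lorentzian tails (mass beyond x is ~(2/pi) w_nat/x, so ~800 half-widths
    keep it below the window tolerance).
    """
    width = 2.0 * abs(model.kappa1 * setting.z1) + 1.5 * abs(model.kappa2 * setting.z2)
    half_window = 0.75 * max(width, 1.0) + 800.0 * model.w_nat
    n = 2 * int(np.ceil(half_window / freq_step)) + 1
    return n


def grid_settings(grid: CalibrationGrid) -> list[ShimSetting]:
    """Row-major enumeration of all (z1, z2) combinations of the scan."""
    z1s = grid.z1_start + grid.z1_step * np.arange(grid.n1)
    z2s = grid.z2_start + grid.z2_step * np.arange(grid.n2)
    return [ShimSetting(float(a), float(b)) for a in z1s for b in z2s]


def simulate_calibration_dataset(
    grid: CalibrationGrid,
    model: FieldModel,
    freq_step: float,
    n_points: int,
    n_response: int,
    noise_sd: float,
    seed: int,
    out_dir,
) -> dict:
    """Write a full synthetic calibration dataset to ``out_dir``.

    Produces ``best.txt`` (the ideal singlet reference), one
    ``cal_<i>_<j>.txt`` per grid node, and ``ground_truth.h5`` holding the
    true response functions.  Per-spectrum noise seeds are derived from
    (seed, node index) so the grid is reproducible in any order.
    """
    import h5py

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = grid_settings(grid)
    best = simulate_ideal_singlet(model, freq_step, n_points)
    write_spectrum_text(best, out_dir / "best.txt")

    responses = np.zeros((len(settings), n_response))
    paths = []
    for idx, setting in enumerate(settings):
        resp = simulate_response(setting, model, freq_step, n_response)
        responses[idx] = resp.values
        vals = conv_same(best.values, resp.values)
        if noise_sd > 0:
            child = np.random.SeedSequence([seed, idx]).generate_state(1)[0]
            rng = np.random.default_rng(child)
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        i, j = divmod(idx, grid.n2)
        spec = Spectrum1D(
            best.freq_start, freq_step, vals,
            {"z1": f"{setting.z1:g}", "z2": f"{setting.z2:g}"},
        )
        fname = f"cal_{i:03d}_{j:03d}.txt"
        write_spectrum_text(spec, out_dir / fname)
        paths.append(fname)

    with h5py.File(out_dir / "ground_truth.h5", "w") as h5:
        h5.create_dataset("responses", data=responses)
        h5.attrs["freq_step"] = freq_step
        h5.attrs["grid_shape"] = grid.shape
    return {"n_spectra": len(settings), "files": paths, "grid_shape": grid.shape}
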