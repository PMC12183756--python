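"""Two-column ASCII spectrum I/O, resampling and peak-height normalization.

A 1D frequency-domain NMR spectrum is stored as a uniform frequency grid
(``freq_start`` + k * ``freq_step``) with real intensities.  The on-disk
format is plain text: ``#``-prefixed ``key: value`` header lines followed by
whitespace-separated (frequency_Hz, intensity) rows.  Both ascending and
descending frequency axes are accepted and normalized to ascending order.

Frequencies are Hz internally.  A file whose header declares
``unit: ppm`` is converted at read time using the
``spectrometer_frequency_MHz`` header key; if that key is missing the read
fails rather than guessing a field strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Spectrum1D",
    "NormalizationPolicy",
    "SpectrumParseError",
    "read_spectrum_text",
    "write_spectrum_text",
    "resample",
    "normalize_height",
    "denormalize_height",
]

#: relative tolerance on the uniformity of the frequency axis
GRID_RTOL = 1e-6

#: peak height the tallest point is scaled to before entering the network
DEFAULT_TARGET_HEIGHT = 16.0


class SpectrumParseError(ValueError):
    """Raised when a spectrum text file cannot be parsed."""


@dataclass
class Spectrum1D:
    """Uniformly sampled real spectrum.

    Parameters
    ----------
    freq_start
        Frequency of the first point in Hz.
    freq_step
        Frequency increment per point in Hz (> 0).
    values
        Real intensities, arbitrary units, length >= 2.
    meta
        Free-form annotations (e.g. ``spectrometer_frequency_MHz``).
    """

    freq_start: float
    freq_step: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.freq_step) or self.freq_step <= 0:
            raise ValueError(f"freq_step must be finite and > 0, got {self.freq_step}")
        if not np.isfinite(self.freq_start):
            raise ValueError("freq_start must be finite")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1D array of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must all be finite")

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def freq_stop(self) -> float:
        """Frequency of the last point (Hz)."""
        return self.freq_start + (self.n_points - 1) * self.freq_step

    def frequencies(self) -> np.ndarray:
        """The frequency axis in Hz."""
        return self.freq_start + self.freq_step * np.arange(self.n_points)

    def with_values(self, values: np.ndarray) -> "Spectrum1D":
        """Copy of this spectrum with ``values`` replaced (grid preserved)."""
        return Spectrum1D(self.freq_start, self.freq_step, np.asarray(values, float), dict(self.meta))

    def same_grid(self, other: "Spectrum1D", rtol: float = 1e-9) -> bool:
        return (
            self.n_points == other.n_points
            and abs(self.freq_start - other.freq_start) <= rtol * max(1.0, abs(self.freq_start))
            and abs(self.freq_step - other.freq_step) <= rtol * self.freq_step
        )


@dataclass(frozen=True)
class NormalizationPolicy:
    """Scale the tallest point of a spectrum to ``target_height``."""

    target_height: float = DEFAULT_TARGET_HEIGHT

    def __post_init__(self) -> None:
        if not (self.target_height > 0):
            raise ValueError("target_height must be > 0")


def read_spectrum_text(path) -> Spectrum1D:
    """Read a two-column ASCII spectrum file.

    Header lines start with ``#`` and may carry ``key: value`` metadata.
    Data rows are (frequency, intensity) pairs; the axis must be uniform to a
    relative tolerance of 1e-6 and may be ascending or descending.
    """
    path = Path(path)
    meta: dict = {}
    freqs: list[float] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two numeric columns, got {len(parts)}"
                )
            try:
                f, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if not (np.isfinite(f) and np.isfinite(v)):
                raise SpectrumParseError(f"{path}:{lineno}: non-finite value")
            freqs.append(f)
            vals.append(v)

    if len(freqs) < 2:
        raise SpectrumParseError(f"{path}: need at least 2 data rows, got {len(freqs)}")

    faxis = np.asarray(freqs)
    values = np.asarray(vals)
    if faxis[1] < faxis[0]:  # descending axis: normalize to ascending
        faxis = faxis[::-1]
        values = values[::-1]

    steps = np.diff(faxis)
    if np.any(steps <= 0):
        raise SpectrumParseError(f"{path}: frequency axis is not strictly monotone")
    step = float(np.mean(steps))
    if np.max(np.abs(steps - step)) > GRID_RTOL * abs(step):
        raise SpectrumParseError(
            f"{path}: non-uniform frequency axis (max deviation "
            f"{np.max(np.abs(steps - step)):.3g} Hz vs step {step:.6g} Hz)"
        )

    start = float(faxis[0])
    if meta.get("unit", "Hz").lower() == "ppm":
        if "spectrometer_frequency_MHz" not in meta:
            raise SpectrumParseError(
                f"{path}: ppm axis requires a 'spectrometer_frequency_MHz' header key"
            )
        mhz = float(meta["spectrometer_frequency_MHz"])
        start *= mhz
        step *= mhz
        meta["unit"] = "Hz"

    return Spectrum1D(freq_start=start, freq_step=step, values=values, meta=meta)


def write_spectrum_text(spectrum: Spectrum1D, path) -> None:
    """Write a spectrum as two-column ASCII with a ``#`` metadata header."""
    path = Path(path)
    freqs = spectrum.frequencies()
    with open(path, "w") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}: {value}\n")
        for f, v in zip(freqs, spectrum.values):
            fh.write(f"{float(f)!r} {float(v)!r}\n")


def resample(spectrum: Spectrum1D, target_step: float) -> Spectrum1D:
    """Resample onto a uniform grid of step ``target_step`` (Hz).

    Uses a cubic spline with flat (clamped-value) extrapolation at the edges;
    the new grid starts at the original ``freq_start`` and is clipped inward
    so it never extends past the original span.  Resampling to the native
    step returns the input unchanged.
    """
    if not (target_step > 0) or not np.isfinite(target_step):
        raise ValueError(f"target_step must be finite and > 0, got {target_step}")
    if abs(target_step - spectrum.freq_step) <= 1e-12 * spectrum.freq_step:
        return spectrum
    span = (spectrum.n_points - 1) * spectrum.freq_step
    if span < 2 * target_step:
        raise ValueError(
            f"spectrum span {span:.6g} Hz too small for target step {target_step:.6g} Hz"
        )
    n_new = int(np.floor(span / target_step)) + 1
    new_freqs = spectrum.freq_start + target_step * np.arange(n_new)
    spline = CubicSpline(spectrum.frequencies(), spectrum.values, extrapolate=False)
    out = spline(new_freqs)
    # flat extrapolation guard: points numerically past the last node
    out = np.where(np.isnan(out), spectrum.values[-1], out)
    return Spectrum1D(spectrum.freq_start, target_step, out, dict(spectrum.meta))


def normalize_height(
    spectrum: Spectrum1D, policy: NormalizationPolicy = NormalizationPolicy()
) -> tuple[Spectrum1D, float]:
    """Scale the spectrum so its maximum equals ``policy.target_height``.

    Returns the scaled spectrum and the scale factor applied (multiply by the
    factor to normalize; divide to undo).
    """
    peak = float(np.max(spectrum.values))
    if peak <= 0:
        raise ValueError("spectrum has no positive peak; cannot normalize height")
    scale = policy.target_height / peak
    return spectrum.with_values(spectrum.values * scale), scale


def denormalize_height(spectrum: Spectrum1D, scale_factor: float) -> Spectrum1D:
    """Undo :func:`normalize_height` by dividing by ``scale_factor``."""
    if not (scale_factor > 0):
        raise ValueError(f"scale_factor must be > 0, got {scale_factor}")
    return spectrum.with_values(spectrum.values / scale_factor)
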