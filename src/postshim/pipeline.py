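"""End-user correction path: resample, normalize, run the network, undo.

The checkpoint fixes the frequency step the network was trained at and the
peak-height normalization (tallest point scaled to 16).  ``correct`` hides
both from the user: the input spectrum is resampled to the model step,
scaled, passed through the network, unscaled, and resampled back onto the
exact input grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .extraction import ResponseFunction
from .network import ModelState, forward
from .spectrum import (
    NormalizationPolicy,
    Spectrum1D,
    denormalize_height,
    normalize_height,
    read_spectrum_text,
    resample,
    write_spectrum_text,
)

__all__ = ["CorrectionResult", "correct", "batch_correct", "attention_report"]

logger = logging.getLogger(__name__)

#: minimum network input length; below this the receptive fields cannot form
MIN_NETWORK_LENGTH = 64

#: tallest/smallest peak-height ratio covered by the training height ranges
DYNAMIC_RANGE_LIMIT = 220.0


@dataclass
class CorrectionResult:
    """Outcome of one correction run."""

    corrected: Spectrum1D           #: corrected spectrum on the original grid
    response_estimate: ResponseFunction  #: the network's distortion estimate
    attention_weights: np.ndarray   #: per-point weights on the original grid
    scale_factor: float             #: normalization factor that was applied


def _interp_to_grid(freqs_src: np.ndarray, values: np.ndarray, freqs_dst: np.ndarray) -> np.ndarray:
    spline = CubicSpline(freqs_src, values, extrapolate=False)
    out = spline(freqs_dst)
    # flat fill at the clipped edges
    out = np.where(freqs_dst < freqs_src[0], values[0], out)
    out = np.where(freqs_dst > freqs_src[-1], values[-1], out)
    return np.nan_to_num(out, nan=0.0)


def _dynamic_range_warning(values: np.ndarray) -> None:
    from scipy.signal import find_peaks

    peak_idx, _ = find_peaks(values, prominence=1e-3 * np.max(values))
    if peak_idx.size >= 2:
        heights = values[peak_idx]
        heights = heights[heights > 0]
        if heights.size >= 2 and heights.max() / heights.min() > DYNAMIC_RANGE_LIMIT:
            logger.warning(
                "peak-height dynamic range exceeds 1:%g (the training coverage); "
                "consider removing dominant solvent peaks before correction",
                DYNAMIC_RANGE_LIMIT,
            )


def correct(spectrum: Spectrum1D, state: ModelState) -> CorrectionResult:
    """Correct one spectrum with a trained model.

    The output spectrum sits on the identical grid as the input and keeps
    the input's tallest-peak height (up to resampling error).  Deterministic:
    repeated calls give identical results.
    """
    freq_step = float(state.meta.get("freq_step", spectrum.freq_step))
    target_height = float(state.meta.get("target_height", 16.0))
    if np.max(spectrum.values) <= 0:
        raise ValueError("spectrum has no positive peak; nothing to normalize")

    _dynamic_range_warning(spectrum.values)

    work = resample(spectrum, freq_step)
    if work.n_points < MIN_NETWORK_LENGTH:
        raise ValueError(
            f"resampled spectrum has {work.n_points} points, below the minimum "
            f"{MIN_NETWORK_LENGTH}; acquire a wider spectral window or use a "
            "model trained at finer resolution"
        )
    work, scale = normalize_height(work, NormalizationPolicy(target_height))

    corrected_vals, response_vals, weights = forward(work.values, state)
    corrected_model_grid = denormalize_height(work.with_values(corrected_vals), scale)

    freqs_model = corrected_model_grid.frequencies()
    freqs_out = spectrum.frequencies()
    out_values = _interp_to_grid(freqs_model, corrected_model_grid.values, freqs_out)
    weights_out = np.clip(_interp_to_grid(freqs_model, weights, freqs_out), 0.0, None)

    return CorrectionResult(
        corrected=Spectrum1D(spectrum.freq_start, spectrum.freq_step, out_values, dict(spectrum.meta)),
        response_estimate=ResponseFunction(values=response_vals, freq_step=freq_step),
        attention_weights=weights_out,
        scale_factor=scale,
    )


def batch_correct(paths, state: ModelState, out_dir) -> list[dict]:
    """Correct several spectrum files; failures are isolated per file.

    Returns one report row per input with the output path, scale factor and
    residual diagnostics, or the error message for failed files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: list[dict] = []
    for path in paths:
        path = Path(path)
        row: dict = {"input": str(path)}
        try:
            spec = read_spectrum_text(path)
            result = correct(spec, state)
            out_path = out_dir / f"{path.stem}_corrected{path.suffix or '.txt'}"
            write_spectrum_text(result.corrected, out_path)
            change = float(
                np.mean((result.corrected.values - spec.values) ** 2)
                / max(np.mean(spec.values**2), 1e-300)
            )
            row.update(
                output=str(out_path),
                scale_factor=result.scale_factor,
                relative_change_mse=change,
                status="ok",
            )
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            row.update(status="error", error=str(exc))
            logger.error("failed to correct %s: %s", path, exc)
        report.append(row)
    return report


def attention_report(
    result: CorrectionResult,
    regions: list[tuple[float, float]],
    spectrum: Spectrum1D | None = None,
) -> list[dict]:
    """Sum the attention weights inside frequency intervals, as percentages.

    ``regions`` are (low, high) frequency intervals in Hz on the corrected
    spectrum's grid.  Percentages are taken relative to the total attention
    mass, so disjoint intervals covering the whole span sum to 100.
    """
    spec = spectrum if spectrum is not None else result.corrected
    freqs = spec.frequencies()
    total = float(result.attention_weights.sum())
    if total <= 0:
        raise ValueError("attention weights have no mass")
    rows = []
    for lo, hi in regions:
        if hi < lo:
            lo, hi = hi, lo
        if hi < freqs[0] or lo > freqs[-1]:
            raise ValueError(f"region ({lo}, {hi}) Hz lies outside the spectrum span")
        mask = (freqs >= lo) & (freqs <= hi)
        rows.append(
            {
                "low_hz": float(lo),
                "high_hz": float(hi),
                "weight_percent": 100.0 * float(result.attention_weights[mask].sum()) / total,
            }
        )
    return rows
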