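"""Response-function extraction by least-squares deconvolution.

Magnetic-field inhomogeneity turns an ideal spectrum s into the observed
spectrum s * r, the discrete convolution with an N-point response function r
whose center index (N-1)/2 corresponds to zero frequency shift.  Given the
best-shimmed calibration spectrum and a mis-shimmed one on the same grid,
the response is recovered by solving

    argmin_r  || A r - d ||^2  +  ridge * || r ||^2

where A is the convolution-by-best operator restricted to a window around
the calibration peak and d is the distorted spectrum on that window.  No
sign or area constraint is imposed: measured responses are asymmetric and
irregular, which is precisely why they are extracted rather than modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import lstsq as _lstsq

from .spectrum import Spectrum1D, read_spectrum_text

__all__ = [
    "ResponseFunction",
    "ResponseLibrary",
    "ConditioningError",
    "conv_same",
    "convolve_spectrum",
    "extract_response",
    "build_library",
    "smoothness_map",
]

logger = logging.getLogger(__name__)

#: endpoint amplitudes above this fraction of the response maximum suggest
#: the window length N is too short for the distortion
ENDPOINT_TOL = 0.05

#: condition number beyond which the unregularized normal system is treated
#: as ill-conditioned and a ridge retry is attempted
COND_LIMIT = 1e12


class ConditioningError(RuntimeError):
    """Least-squares system is ill-conditioned; retry with ridge > 0."""


def conv_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-length convolution with an odd, centered kernel.

    ``kernel`` index j represents a frequency shift of (j - (N-1)/2) bins;
    edges are zero-padded.  Equivalent to ``np.convolve(x, kernel, 'same')``
    for odd kernels, kept as the single convention point for the package.
    """
    if kernel.size % 2 == 0:
        raise ValueError("kernel length must be odd")
    return np.convolve(x, kernel, mode="same")


@dataclass
class ResponseFunction:
    """N-point distortion kernel at a fixed frequency step.

    ``values[j]`` weights a shift of ``(j - center_index) * freq_step`` Hz.
    """

    values: np.ndarray
    freq_step: float
    setting: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size % 2 == 0:
            raise ValueError("response must be a 1D array of odd length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")
        if not self.freq_step > 0:
            raise ValueError("freq_step must be > 0")

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def center_index(self) -> int:
        return (self.n_points - 1) // 2

    def endpoints_ok(self, tol: float = ENDPOINT_TOL) -> bool:
        """True when both endpoint amplitudes are small relative to the peak,
        i.e. the response decayed to ~zero inside the window."""
        peak = np.max(np.abs(self.values))
        if peak == 0:
            return True
        return bool(
            abs(self.values[0]) < tol * peak and abs(self.values[-1]) < tol * peak
        )


@dataclass
class ResponseLibrary:
    """A set of response functions on a common (N, freq_step) grid."""

    responses: np.ndarray  # (n_responses, N)
    freq_step: float
    grid_shape: tuple[int, int] | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2 or self.responses.shape[1] % 2 == 0:
            raise ValueError("responses must be (n, N) with N odd")

    def __len__(self) -> int:
        return int(self.responses.shape[0])

    @property
    def n_response(self) -> int:
        return int(self.responses.shape[1])

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("responses", data=self.responses)
            h5.attrs["freq_step"] = self.freq_step
            if self.grid_shape is not None:
                h5.attrs["grid_shape"] = self.grid_shape
            if self.residuals is not None:
                h5.create_dataset("residuals", data=self.residuals)

    @classmethod
    def load(cls, path) -> "ResponseLibrary":
        import h5py

        with h5py.File(path, "r") as h5:
            responses = h5["responses"][...]
            freq_step = float(h5.attrs["freq_step"])
            grid_shape = tuple(h5.attrs["grid_shape"]) if "grid_shape" in h5.attrs else None
            residuals = h5["residuals"][...] if "residuals" in h5 else None
        return cls(responses, freq_step, grid_shape, residuals)


def convolve_spectrum(spectrum: Spectrum1D, response: ResponseFunction) -> Spectrum1D:
    """Distort a spectrum by a response function (same grid out as in)."""
    if abs(spectrum.freq_step - response.freq_step) > 1e-9 * response.freq_step:
        raise ValueError(
            f"frequency step mismatch: spectrum {spectrum.freq_step!r} Hz "
            f"vs response {response.freq_step!r} Hz"
        )
    return spectrum.with_values(conv_same(spectrum.values, response.values))


def _auto_window(best: np.ndarray, distorted: np.ndarray, n_response: int) -> tuple[int, int]:
    """Window centered on the distorted peak: the span of `best` above 0.1%
    of its maximum, widened by N points of margin on each side."""
    support = np.nonzero(best > 1e-3 * np.max(best))[0]
    lo = int(support[0]) - n_response
    hi = int(support[-1]) + 1 + n_response
    center_best = int(np.argmax(best))
    center_dist = int(np.argmax(distorted))
    shift = center_dist - center_best
    lo = max(0, min(lo, lo + shift))
    hi = min(best.size, max(hi, hi + shift))
    return lo, hi


def extract_response(
    best: Spectrum1D,
    distorted: Spectrum1D,
    n_response: int,
    window: tuple[int, int] | str = "auto",
    ridge: float = 0.0,
) -> ResponseFunction:
    """Deconvolve one calibration spectrum against the best-shimmed one.

    Parameters
    ----------
    best, distorted
        Calibration spectra on the identical frequency grid.
    n_response
        Odd number of response points to fit.
    window
        (start, stop) index range covering the calibration peak plus at
        least ``n_response`` points of margin on each side, or ``"auto"``.
    ridge
        Tikhonov penalty; 0 requests a plain least-squares fit, with one
        automatic ridge retry if the system is ill-conditioned.

    The relative root-mean-square fit residual is stored under
    ``meta["residual_rms"]``.
    """
    if n_response < 1 or n_response % 2 == 0:
        raise ValueError(f"n_response must be odd and >= 1, got {n_response}")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if not best.same_grid(distorted):
        raise ValueError("best and distorted spectra must share the frequency grid")

    b = best.values
    d_full = distorted.values
    if window == "auto":
        lo, hi = _auto_window(b, d_full, n_response)
    else:
        lo, hi = int(window[0]), int(window[1])
    if hi - lo < 2 * n_response:
        raise ValueError(
            f"window [{lo}, {hi}) too narrow for an {n_response}-point response"
        )

    half = (n_response - 1) // 2
    # A[i, j] = best[(lo + i) - (j - half)] : convolution-by-best operator
    rows = np.arange(lo, hi)[:, None] - (np.arange(n_response)[None, :] - half)
    valid = (rows >= 0) & (rows < b.size)
    A = np.where(valid, b[np.clip(rows, 0, b.size - 1)], 0.0)
    d = d_full[lo:hi]

    def solve(lam: float) -> tuple[np.ndarray, float]:
        if lam > 0:
            A_aug = np.vstack([A, np.sqrt(lam) * np.eye(n_response)])
            d_aug = np.concatenate([d, np.zeros(n_response)])
        else:
            A_aug, d_aug = A, d
        sol, _, rank, sv = _lstsq(A_aug, d_aug)
        cond = np.inf if sv[-1] == 0 else sv[0] / sv[-1]
        if rank < n_response or cond > COND_LIMIT:
            raise ConditioningError(
                f"normal system condition number {cond:.3g}; "
                "retry with ridge > 0"
            )
        return sol, cond

    try:
        sol, _ = solve(ridge)
    except ConditioningError:
        if ridge > 0:
            raise
        auto_ridge = 1e-8 * float(np.max(np.einsum("ij,ij->j", A, A)))
        logger.warning("ill-conditioned deconvolution; retrying with ridge=%.3g", auto_ridge)
        sol, _ = solve(auto_ridge)
        ridge = auto_ridge

    resid = A @ sol - d
    scale = float(np.max(np.abs(d))) or 1.0
    rms = float(np.sqrt(np.mean(resid**2))) / scale
    setting = None
    if "z1" in distorted.meta and "z2" in distorted.meta:
        setting = (float(distorted.meta["z1"]), float(distorted.meta["z2"]))
    return ResponseFunction(
        values=sol,
        freq_step=best.freq_step,
        setting=setting,
        meta={"residual_rms": rms, "ridge": ridge, "window": (lo, hi)},
    )


def build_library(
    best: Spectrum1D,
    calibration_dir,
    n_response: int,
    grid_shape: tuple[int, int] | None = None,
    ridge: float = 0.0,
    max_failure_fraction: float = 0.01,
) -> ResponseLibrary:
    """Extract one response per calibration file in ``calibration_dir``.

    Files are processed in sorted (grid) order.  Per-file failures are
    collected; the run only fails if more than ``max_failure_fraction`` of
    the files do.  Responses whose endpoints have not decayed to zero are
    kept but logged — they indicate an undersized window N.
    """
    calibration_dir = Path(calibration_dir)
    files = sorted(p for p in calibration_dir.glob("cal_*.txt"))
    if not files:
        files = sorted(
            p for p in calibration_dir.glob("*.txt") if p.name != "best.txt"
        )
    if not files:
        raise ValueError(f"no calibration spectra found in {calibration_dir}")

    responses = np.zeros((len(files), n_response))
    residuals = np.zeros(len(files))
    errors: list[tuple[str, Exception]] = []
    for i, path in enumerate(files):
        try:
            spec = read_spectrum_text(path)
            resp = extract_response(best, spec, n_response, ridge=ridge)
            responses[i] = resp.values
            residuals[i] = resp.meta["residual_rms"]
            if not resp.endpoints_ok():
                logger.warning(
                    "response from %s has non-zero endpoints (setting %s); "
                    "window N=%d may be too short",
                    path.name, resp.setting, n_response,
                )
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            errors.append((path.name, exc))
            logger.error("failed to extract response from %s: %s", path.name, exc)

    if len(errors) > max_failure_fraction * len(files):
        raise RuntimeError(
            f"{len(errors)}/{len(files)} calibration spectra failed extraction; "
            f"first error: {errors[0][0]}: {errors[0][1]}"
        )
    return ResponseLibrary(responses, best.freq_step, grid_shape, residuals)


def smoothness_map(library: ResponseLibrary) -> np.ndarray:
    """Mean Euclidean distance of each grid node's response to its 4-neighbors.

    Responses measured on a shim grid should vary smoothly with the shim
    currents; an isolated large value flags an outlier extraction.
    """
    if library.grid_shape is None:
        raise ValueError("library carries no grid shape metadata")
    n1, n2 = library.grid_shape
    if n1 * n2 != len(library):
        raise ValueError(
            f"grid shape {library.grid_shape} does not match {len(library)} responses"
        )
    grid = library.responses.reshape(n1, n2, -1)
    out = np.zeros((n1, n2))
    for i in range(n1):
        for j in range(n2):
            dists = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < n1 and 0 <= jj < n2:
                    dists.append(np.linalg.norm(grid[i, j] - grid[ii, jj]))
            out[i, j] = np.mean(dists)
    return out
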