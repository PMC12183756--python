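"""Frequency-resolution planning for network-compatible acquisition.

The convolutional correction network sees peaks through fixed receptive
fields, which constrains the frequency step Δf the spectra must be sampled
at.  With W the maximum expected response-function width (Hz) and
FWHM_min/FWHM_max the narrowest/broadest undistorted singlet widths (Hz),
the step must satisfy

    FWHM_min > 1 * Δf        (narrow singlets stay above one point wide)
    W + FWHM_max < 100 * Δf  (distorted peaks stay below 100 points wide)

and the response-function length N (points, odd) follows from W <= N * Δf.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ResolutionPlan",
    "PlanReport",
    "compute_frequency_step",
    "validate_plan",
    "response_length",
]


def compute_frequency_step(spectral_width: float, n_points: int) -> float:
    """Frequency step Δf = spectral width / number of points (Hz)."""
    if not spectral_width > 0:
        raise ValueError(f"spectral_width must be > 0, got {spectral_width}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    return spectral_width / n_points


@dataclass(frozen=True)
class PlanReport:
    """Outcome of the two step-size constraints with numeric margins."""

    narrow_ok: bool     #: FWHM_min > Δf
    broad_ok: bool      #: W + FWHM_max < 100 Δf
    narrow_margin: float  #: FWHM_min - Δf  (Hz; positive means pass)
    broad_margin: float   #: 100 Δf - (W + FWHM_max)  (Hz; positive means pass)

    @property
    def ok(self) -> bool:
        return self.narrow_ok and self.broad_ok


def validate_plan(freq_step: float, max_width: float, fwhm_min: float, fwhm_max: float) -> PlanReport:
    """Check both resolution constraints; failures are reported, not raised."""
    for name, v in [("freq_step", freq_step), ("max_width", max_width),
                    ("fwhm_min", fwhm_min), ("fwhm_max", fwhm_max)]:
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    narrow_margin = fwhm_min - freq_step
    broad_margin = 100.0 * freq_step - (max_width + fwhm_max)
    return PlanReport(
        narrow_ok=narrow_margin > 0,
        broad_ok=broad_margin > 0,
        narrow_margin=narrow_margin,
        broad_margin=broad_margin,
    )


def response_length(max_width: float, freq_step: float, n_override: int | None = None) -> int:
    """Smallest odd N with N * Δf >= W, or an explicit odd override.

    ``n_override`` lets a user pin N (e.g. to match an existing response
    library) as long as it is odd and positive; the constraint W <= N Δf is
    then the caller's responsibility.
    """
    if not max_width > 0:
        raise ValueError(f"max_width must be > 0, got {max_width}")
    if not freq_step > 0:
        raise ValueError(f"freq_step must be > 0, got {freq_step}")
    if n_override is not None:
        if n_override < 1 or n_override % 2 == 0:
            raise ValueError(f"n_override must be odd and >= 1, got {n_override}")
        return int(n_override)
    n = int(-(-max_width // freq_step))  # ceil(W / Δf)
    if n * freq_step < max_width:  # guard against float edge cases
        n += 1
    if n % 2 == 0:
        n += 1
    return max(n, 1)


@dataclass(frozen=True)
class ResolutionPlan:
    """Bundle of the resolution parameters shared across the pipeline.

    Attributes
    ----------
    freq_step
        Δf, the frequency increment of network-ready spectra (Hz).
    max_width
        W, the widest response function expected from the instrument (Hz).
    fwhm_min, fwhm_max
        Narrowest / broadest undistorted singlet FWHM expected (Hz).
        0.4 and 4 Hz are fairly universal for small molecules in solution.
    n_response
        Response-function length in points (odd).
    """

    freq_step: float
    max_width: float
    fwhm_min: float = 0.4
    fwhm_max: float = 4.0
    n_response: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fwhm_min <= self.fwhm_max):
            raise ValueError("need 0 < fwhm_min <= fwhm_max")
        if self.n_response == 0:
            object.__setattr__(
                self, "n_response", response_length(self.max_width, self.freq_step)
            )
        if self.n_response < 1 or self.n_response % 2 == 0:
            raise ValueError(f"n_response must be odd and >= 1, got {self.n_response}")
        report = validate_plan(self.freq_step, self.max_width, self.fwhm_min, self.fwhm_max)
        if not report.ok:
            raise ValueError(
                "resolution constraints violated: "
                f"narrow margin {report.narrow_margin:.4g} Hz, "
                f"broad margin {report.broad_margin:.4g} Hz"
            )

    def report(self) -> PlanReport:
        return validate_plan(self.freq_step, self.max_width, self.fwhm_min, self.fwhm_max)

    def to_dict(self) -> dict:
        return {
            "freq_step": self.freq_step,
            "max_width": self.max_width,
            "fwhm_min": self.fwhm_min,
            "fwhm_max": self.fwhm_max,
            "n_response": self.n_response,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResolutionPlan":
        return cls(**{k: d[k] for k in ("freq_step", "max_width", "fwhm_min", "fwhm_max", "n_response")})
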