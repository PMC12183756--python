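"""Synthetic training-data generation: Lorentzian-Gaussian multiplets,
library distortion and noise.

A clean spectrum is a sum of M multiplets.  Each line is the mixed
lineshape

    f(w) = (1 - g) * H * w0h^2 / (w0h^2 + (w - w0)^2)
           + g * H * exp(-(w - w0)^2 / (2 sigma^2))

with total height H, Gaussian fraction g, Lorentzian half-width at
half-maximum w0h and Gaussian dispersion sigma tied so both components share
the same FWHM: w0h = sigma * sqrt(2 ln 2).  A multiplet of multiplicity m is
a sum of m equidistant, equally wide lines spaced by the coupling j1 with
relative heights given by unit-sum binomial coefficients (weak-coupling
approximation); with probability one half a second coupling j2 splits each
line into a half-weight doublet.  The hybrid (network input) spectrum is the
clean one convolved with a randomly drawn measured response function plus
white Gaussian noise of random dispersion.

Parameter ranges (all drawn uniformly unless noted):

=====================  ========  =========  =========
parameter              min       max        scope
=====================  ========  =========  =========
number of multiplets M 2         5          spectrum
center frequency (Hz)  -279.02   279.02     multiplet
multiplicity m         1         7          multiplet (weighted)
couplings j1, j2 (Hz)  0         15         multiplet
component width (Hz)   1.0       2.0        multiplet
width factor w_s       0.2       1.0        spectrum
relative intensity h_i 1.0       3.0        multiplet
height factor h_m      0.5       4.0        multiplet
height factor h_s      0.5       2.0        spectrum
Gaussian fraction g    0         1          multiplet
noise sd               0         0.02       spectrum
=====================  ========  =========  =========
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .extraction import ResponseLibrary, conv_same

__all__ = [
    "LGComponent",
    "MultipletSpec",
    "SpectrumSamplingConfig",
    "TrainingExample",
    "WIDTH_SIGMA_RATIO",
    "MULTIPLICITY_WEIGHTS",
    "lg_peak",
    "multiplet_heights",
    "render_multiplet",
    "sample_spectrum",
    "make_training_example",
]

#: w = sigma * sqrt(2 ln 2): equal FWHM for the two mixture components
WIDTH_SIGMA_RATIO = math.sqrt(2.0 * math.log(2.0))

#: sampling weights for multiplicities 1..7, favouring low multiplicities as
#: found when harvesting multiplets from drug-like small molecules
MULTIPLICITY_WEIGHTS = (0.30, 0.30, 0.20, 0.10, 0.05, 0.03, 0.02)

#: probability that the second coupling splits each line into a doublet
SECONDARY_SPLIT_PROB = 0.5


@dataclass(frozen=True)
class LGComponent:
    """One Lorentzian-Gaussian line."""

    height: float          #: H, total peak height (a.u.)
    gaussian_fraction: float  #: g in [0, 1]
    center: float          #: w0, line frequency (Hz)
    width: float           #: Lorentzian half-width at half-maximum (Hz)

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("height must be > 0")
        if not self.width > 0:
            raise ValueError("width must be > 0")
        if not 0.0 <= self.gaussian_fraction <= 1.0:
            raise ValueError("gaussian_fraction must be in [0, 1]")

    @property
    def sigma(self) -> float:
        """Gaussian dispersion tied to the Lorentzian half-width."""
        return self.width / WIDTH_SIGMA_RATIO


def lg_peak(grid: np.ndarray, comp: LGComponent) -> np.ndarray:
    """Evaluate one Lorentzian-Gaussian line on a frequency grid (Hz)."""
    offs = np.asarray(grid, float) - comp.center
    w2 = comp.width**2
    lorentz = w2 / (w2 + offs**2)
    gauss = np.exp(-(offs**2) / (2.0 * comp.sigma**2))
    g = comp.gaussian_fraction
    return comp.height * ((1.0 - g) * lorentz + g * gauss)


def multiplet_heights(multiplicity: int) -> np.ndarray:
    """Unit-sum binomial line weights of an m-plet (1:1, 1:2:1, ...)."""
    if not 1 <= multiplicity <= 7:
        raise ValueError(f"multiplicity must be in 1..7, got {multiplicity}")
    row = np.array([math.comb(multiplicity - 1, k) for k in range(multiplicity)], float)
    return row / row.sum()


@dataclass(frozen=True)
class MultipletSpec:
    """All per-multiplet draws needed to render one multiplet."""

    multiplicity: int
    j1: float                #: primary coupling (Hz)
    j2: float                #: secondary coupling (Hz)
    width: float             #: per-multiplet width draw w_m (Hz)
    intensity: float         #: relative intensity h_i
    height_factor: float     #: per-multiplet height factor h_m
    gaussian_fraction: float
    center: float            #: multiplet center frequency (Hz)
    secondary_split: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.multiplicity <= 7:
            raise ValueError("multiplicity must be in 1..7")
        for name, v, lo, hi in [
            ("j1", self.j1, 0.0, 15.0),
            ("j2", self.j2, 0.0, 15.0),
            ("width", self.width, 1.0, 2.0),
            ("intensity", self.intensity, 1.0, 3.0),
            ("height_factor", self.height_factor, 0.5, 4.0),
            ("gaussian_fraction", self.gaussian_fraction, 0.0, 1.0),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def render_multiplet(
    grid: np.ndarray, spec: MultipletSpec, width_factor: float, height_factor: float
) -> np.ndarray:
    """Render one multiplet onto a frequency grid.

    ``width_factor`` (w_s) and ``height_factor`` (h_s) are the per-spectrum
    scale draws.  Line k of an m-plet sits at
    ``center + (k - (m - 1) / 2) * j1`` with height
    ``h_b[k] * h_i * h_m * h_s``; a secondary split replaces each line by a
    half-weight doublet separated by j2.
    """
    m = spec.multiplicity
    weights = multiplet_heights(m)
    width = spec.width * width_factor
    if not width > 0:
        raise ValueError("component width must be > 0")
    centers = spec.center + (np.arange(m) - (m - 1) / 2.0) * spec.j1
    heights = weights * spec.intensity * spec.height_factor * height_factor
    if spec.secondary_split:
        centers = np.concatenate([centers - spec.j2 / 2.0, centers + spec.j2 / 2.0])
        heights = np.concatenate([heights / 2.0, heights / 2.0])
    out = np.zeros_like(np.asarray(grid, float))
    for c, h in zip(centers, heights):
        out += lg_peak(
            grid,
            LGComponent(
                height=h, gaussian_fraction=spec.gaussian_fraction, center=c, width=width
            ),
        )
    return out


@dataclass(frozen=True)
class SpectrumSamplingConfig:
    """Ranges of the per-spectrum draws plus the output grid."""

    freq_step: float
    n_points: int = 2048
    n_multiplets_range: tuple[int, int] = (2, 5)
    center_half_range: float = 279.02
    width_factor_range: tuple[float, float] = (0.2, 1.0)
    height_factor_range: tuple[float, float] = (0.5, 2.0)
    noise_max: float = 0.02

    def __post_init__(self) -> None:
        if self.n_points < 128:
            raise ValueError("n_points must be >= 128")
        if not self.freq_step > 0:
            raise ValueError("freq_step must be > 0")
        if self.noise_max < 0:
            raise ValueError("noise_max must be >= 0")

    def grid(self) -> np.ndarray:
        """Frequency axis centered at 0 Hz."""
        half = self.n_points // 2
        return (np.arange(self.n_points) - half) * self.freq_step

    def effective_center_half_range(self) -> float:
        """The multiplet-center range, clipped to 90% of the grid half-span
        when the grid is narrower than the nominal +-279.02 Hz."""
        half_span = 0.5 * (self.n_points - 1) * self.freq_step
        return min(self.center_half_range, 0.9 * half_span)


def sample_spectrum(
    config: SpectrumSamplingConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Draw one clean synthetic spectrum.

    Returns the spectrum values and a record of every parameter drawn, so a
    spectrum can be re-rendered exactly.
    """
    grid = config.grid()
    m_lo, m_hi = config.n_multiplets_range
    n_mult = int(rng.integers(m_lo, m_hi + 1))
    width_factor = float(rng.uniform(*config.width_factor_range))
    height_factor = float(rng.uniform(*config.height_factor_range))
    omega_half = config.effective_center_half_range()

    values = np.zeros(config.n_points)
    multiplets = []
    for _ in range(n_mult):
        spec = MultipletSpec(
            multiplicity=1 + int(rng.choice(7, p=MULTIPLICITY_WEIGHTS)),
            j1=float(rng.uniform(0.0, 15.0)),
            j2=float(rng.uniform(0.0, 15.0)),
            width=float(rng.uniform(1.0, 2.0)),
            intensity=float(rng.uniform(1.0, 3.0)),
            height_factor=float(rng.uniform(0.5, 4.0)),
            gaussian_fraction=float(rng.uniform(0.0, 1.0)),
            center=float(rng.uniform(-omega_half, omega_half)),
            secondary_split=bool(rng.random() < SECONDARY_SPLIT_PROB),
        )
        values += render_multiplet(grid, spec, width_factor, height_factor)
        multiplets.append(spec)

    record = {
        "n_multiplets": n_mult,
        "width_factor": width_factor,
        "height_factor": height_factor,
        "multiplets": multiplets,
    }
    return values, record


@dataclass
class TrainingExample:
    """One (clean target, distorted noisy input, true response) triple."""

    clean: np.ndarray
    distorted: np.ndarray
    response: np.ndarray
    noise_sd: float = 0.0
    record: dict = field(default_factory=dict)


def make_training_example(
    clean: np.ndarray,
    library: ResponseLibrary,
    noise_max: float,
    rng: np.random.Generator,
) -> TrainingExample:
    """Distort a clean spectrum with a random library response plus noise."""
    if len(library) == 0:
        raise ValueError("response library is empty")
    idx = int(rng.integers(len(library)))
    response = library.responses[idx]
    distorted = conv_same(np.asarray(clean, float), response)
    noise_sd = float(rng.uniform(0.0, noise_max)) if noise_max > 0 else 0.0
    if noise_sd > 0:
        distorted = distorted + rng.normal(0.0, noise_sd, size=distorted.shape)
    return TrainingExample(
        clean=np.asarray(clean, float),
        distorted=distorted,
        response=response.copy(),
        noise_sd=noise_sd,
        record={"response_index": idx},
    )


def sample_batch(
    batch_size: int,
    config: SpectrumSamplingConfig,
    library: ResponseLibrary,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a training batch: (clean, distorted, responses) arrays.

    Shapes: (K, L), (K, L), (K, N).  Used by the online trainer, which never
    reuses a batch.
    """
    clean = np.zeros((batch_size, config.n_points))
    distorted = np.zeros_like(clean)
    responses = np.zeros((batch_size, library.n_response))
    for k in range(batch_size):
        s, _ = sample_spectrum(config, rng)
        ex = make_training_example(s, library, config.noise_max, rng)
        clean[k] = ex.clean
        distorted[k] = ex.distorted
        responses[k] = ex.response
    return clean, distorted, responses
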