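"""Online hybrid training: three-term loss, Adam, batch/learning-rate schedule.

Every batch is freshly generated (online learning): clean multiplet spectra
are drawn, distorted with random library responses and noise, and never
reused.  The loss over a batch of K spectra is

    L = (1/K) * ( |S_trg - S_out|^2 + |R_trg - R_out|^2
                  + |S_inp - S_out * R_out|^2 )

where * is centered same-length convolution; S_trg are the clean targets,
S_inp the distorted noisy inputs, S_out / R_out the network's corrected
spectra and response estimates, and R_trg the true responses.  Each |.|^2
is the per-element mean over its vector, which makes the loss (and hence the
learning rates) independent of the training spectrum length.

The reference schedule raises the batch size and lowers the learning rate in
three phases totalling 40 M spectra; a desk-scale smoke preset is provided
for CPU-only runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import ResponseLibrary, conv_same
from .generator import SpectrumSamplingConfig, sample_batch
from .network import ModelState, backward, forward, forward_training, save_state

__all__ = [
    "TrainingSchedule",
    "LossBreakdown",
    "loss",
    "loss_and_grads",
    "AdamOptimizer",
    "train",
    "evaluate",
    "REFERENCE_SCHEDULE",
    "smoke_schedule",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Ordered phases of (number of spectra, batch size, learning rate)."""

    phases: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        for n, k, lr in self.phases:
            if n % k != 0:
                raise ValueError(f"phase spectra {n} not divisible by batch size {k}")
            if lr <= 0:
                raise ValueError("learning rates must be > 0")

    @property
    def total_spectra(self) -> int:
        return sum(n for n, _, _ in self.phases)

    @property
    def total_batches(self) -> int:
        return sum(n // k for n, k, _ in self.phases)


#: the reference three-phase schedule: 40 M spectra in total
REFERENCE_SCHEDULE = TrainingSchedule(
    phases=(
        (1_600_000, 64, 0.0010),
        (25_600_000, 512, 0.0010),
        (12_800_000, 512, 0.0005),
    )
)


def smoke_schedule(n_spectra: int = 50_048, batch_size: int = 64, lr: float = 1e-3) -> TrainingSchedule:
    """Single-phase desk-scale preset (default ~50k spectra, CPU-friendly)."""
    n_spectra -= n_spectra % batch_size
    return TrainingSchedule(phases=((n_spectra, batch_size, lr),))


@dataclass(frozen=True)
class LossBreakdown:
    """The three loss terms and their sum."""

    reconstruction: float  #: |S_trg - S_out|^2
    distortion: float      #: |R_trg - R_out|^2
    consistency: float     #: |S_inp - S_out * R_out|^2
    total: float

    def __post_init__(self) -> None:
        assert abs(self.total - (self.reconstruction + self.distortion + self.consistency)) <= 1e-9 * max(1.0, self.total)


def _batched(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    return a[None, :] if a.ndim == 1 else a


def loss(
    s_trg: np.ndarray,
    s_inp: np.ndarray,
    s_out: np.ndarray,
    r_trg: np.ndarray,
    r_out: np.ndarray,
    batch_size: int | None = None,
) -> LossBreakdown:
    """Evaluate the three-term loss on a batch (no gradients)."""
    breakdown, _, _ = loss_and_grads(s_trg, s_inp, s_out, r_trg, r_out, batch_size)
    return breakdown


def loss_and_grads(
    s_trg: np.ndarray,
    s_inp: np.ndarray,
    s_out: np.ndarray,
    r_trg: np.ndarray,
    r_out: np.ndarray,
    batch_size: int | None = None,
) -> tuple[LossBreakdown, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. the network outputs (S_out, R_out)."""
    s_trg, s_inp, s_out = _batched(s_trg), _batched(s_inp), _batched(s_out)
    r_trg, r_out = _batched(r_trg), _batched(r_out)
    if s_trg.shape != s_out.shape or s_inp.shape != s_out.shape:
        raise ValueError("spectrum batch shapes do not match")
    if r_trg.shape != r_out.shape:
        raise ValueError("response batch shapes do not match")
    if r_out.shape[1] % 2 == 0:
        raise ValueError("response length must be odd")
    K_data, L = s_out.shape
    K = batch_size if batch_size is not None else K_data
    N = r_out.shape[1]
    c = (N - 1) // 2

    rec_resid = s_out - s_trg
    rec = float(np.sum(rec_resid**2)) / (K * L)
    dist_resid = r_out - r_trg
    dist = float(np.sum(dist_resid**2)) / (K * N)

    cons = 0.0
    d_s_out = 2.0 * rec_resid / (K * L)
    d_r_out = 2.0 * dist_resid / (K * N)
    for b in range(K_data):
        resid = conv_same(s_out[b], r_out[b]) - s_inp[b]
        cons += float(np.sum(resid**2)) / (K * L)
        d_s_out[b] += 2.0 / (K * L) * conv_same(resid, r_out[b][::-1])
        full = np.convolve(resid, s_out[b][::-1])
        d_r_out[b] += 2.0 / (K * L) * full[L - 1 - c : L - 1 - c + N]

    breakdown = LossBreakdown(
        reconstruction=rec, distortion=dist, consistency=cons,
        total=rec + dist + cons,
    )
    return breakdown, d_s_out, d_r_out


class AdamOptimizer:
    """Adam with the standard moment coefficients (0.9, 0.999), eps 1e-8."""

    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            params[k] -= lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)


def train(
    state: ModelState,
    library: ResponseLibrary,
    config: SpectrumSamplingConfig,
    schedule: TrainingSchedule,
    seed: int = 0,
    checkpoint_dir=None,
    checkpoint_every: int = 1000,
    progress: bool = False,
) -> tuple[ModelState, dict]:
    """Online training loop.

    Each batch is generated on the fly from ``config`` and ``library`` using
    a strictly advancing RNG, so no batch is ever reused.  Returns the
    trained state and a history dict with per-batch loss terms and the total
    number of spectra generated.
    """
    if len(library) == 0:
        raise ValueError("response library is empty")
    if library.n_response != state.config.n_response:
        raise ValueError(
            f"library response length {library.n_response} != model "
            f"n_response {state.config.n_response}"
        )
    rng = np.random.default_rng(seed)
    opt = AdamOptimizer(state.params)
    history = {"reconstruction": [], "distortion": [], "consistency": [], "total": []}
    n_generated = 0
    batch_iter = _schedule_batches(schedule)
    if progress:
        from tqdm import tqdm

        batch_iter = tqdm(list(batch_iter), desc="training")

    for batch_no, (batch_size, lr) in enumerate(batch_iter, start=1):
        s_trg, s_inp, r_trg = sample_batch(batch_size, config, library, rng)
        n_generated += batch_size
        s_out, r_out, cache = forward_training(s_inp, state)
        breakdown, d_s_out, d_r_out = loss_and_grads(s_trg, s_inp, s_out, r_trg, r_out)
        if not np.isfinite(breakdown.total):
            if checkpoint_dir is not None:
                save_state(state, f"{checkpoint_dir}/diagnostic_batch{batch_no}.npz")
            raise RuntimeError(
                f"non-finite loss {breakdown.total} at batch {batch_no}; aborted"
            )
        grads = backward(d_s_out, d_r_out, cache, state)
        grads.pop("_input", None)
        opt.step(state.params, grads, lr)
        for key in ("reconstruction", "distortion", "consistency", "total"):
            history[key].append(getattr(breakdown, key))
        if checkpoint_dir is not None and batch_no % checkpoint_every == 0:
            save_state(state, f"{checkpoint_dir}/checkpoint_batch{batch_no}.npz")

    history["n_generated"] = n_generated
    if checkpoint_dir is not None:
        save_state(state, f"{checkpoint_dir}/checkpoint_final.npz")
    return state, history


def _schedule_batches(schedule: TrainingSchedule):
    for n_spectra, batch_size, lr in schedule.phases:
        for _ in range(n_spectra // batch_size):
            yield batch_size, lr


def smooth_history(values: list[float], window: int = 1000) -> np.ndarray:
    """Moving average of a loss curve for reporting."""
    v = np.asarray(values, float)
    if v.size == 0:
        return v
    w = min(window, v.size)
    kernel = np.ones(w) / w
    return np.convolve(v, kernel, mode="valid")


def evaluate(
    state: ModelState,
    n_eval: int,
    library: ResponseLibrary,
    config: SpectrumSamplingConfig,
    seed: int = 0,
) -> dict:
    """Correction quality on freshly generated examples.

    Returns mean squared errors of the corrected and uncorrected spectra
    against the clean targets, their ratio, and the mean Pearson correlation
    between estimated and true response functions.
    """
    rng = np.random.default_rng(seed)
    s_trg, s_inp, r_trg = sample_batch(n_eval, config, library, rng)
    s_out, r_out, _ = forward(s_inp, state)
    corrected_mse = float(np.mean((s_out - s_trg) ** 2))
    baseline_mse = float(np.mean((s_inp - s_trg) ** 2))
    corrs = []
    for b in range(n_eval):
        ro, rt = r_out[b], r_trg[b]
        if np.std(ro) == 0 or np.std(rt) == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(ro, rt)[0, 1]))
    return {
        "corrected_mse": corrected_mse,
        "baseline_mse": baseline_mse,
        "mse_ratio": corrected_mse / baseline_mse if baseline_mse > 0 else np.nan,
        "response_correlation": float(np.mean(corrs)),
        "n_eval": n_eval,
    }
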