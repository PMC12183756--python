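"""The correction network: convolutional encoder, attention pooling,
convolutional decoder with global-feature concatenation, and an auxiliary
response decoder.

Architecture
------------
* Encoder: four stride-1 1D convolutions (kernel 7, 64 channels) with ReLU
  between them; receptive field depth*(kernel-1)+1 = 25 points, so every
  25-point neighbourhood of the input is encoded as 64 latent features.
* Attention pooling: scalar products of each latent column with a single
  learned query vector (64 parameters, no bias), softmax over positions,
  weighted average -> one global 64-vector describing the distortion.
* Decoder: the mirror of the encoder built from stride-1 transposed
  convolutions (which for stride 1 coincide with flipped-kernel
  convolutions); its input is each latent column concatenated with the
  broadcast global vector (128 channels).  Encoder+decoder receptive field:
  2*depth*(kernel-1)+1 = 49 points.
* Auxiliary decoder: two fully connected layers (64 -> 64 -> N) with one
  ReLU, mapping the global vector to a response-function estimate.  Used
  only by the training loss.

The network is fully convolutional: it processes spectra of any length with
the same parameters.  All layers are implemented on NumPy with explicit
backward passes (im2col convolutions backed by BLAS matrix products), which
keeps training and inference dependency-free on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelState",
    "init_state",
    "encode",
    "attend",
    "decode",
    "decode_response",
    "forward",
    "forward_training",
    "backward",
    "count_parameters",
    "save_state",
    "load_state",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the reference architecture: 64 channels, kernel 7,
    depth 4 per coder, giving receptive fields of 25 (encoder) and 49
    (encoder+decoder) points.
    """

    channels: int = 64
    kernel: int = 7
    depth: int = 4
    aux_hidden: int = 64
    n_response: int = 61
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and >= 1")
        if self.depth < 1 or self.channels < 1 or self.aux_hidden < 1:
            raise ValueError("depth, channels and aux_hidden must be >= 1")
        if self.n_response % 2 == 0 or self.n_response < 1:
            raise ValueError("n_response must be odd and >= 1")

    @property
    def encoder_receptive_field(self) -> int:
        return self.depth * (self.kernel - 1) + 1

    @property
    def autoencoder_receptive_field(self) -> int:
        return 2 * self.depth * (self.kernel - 1) + 1

    def to_dict(self) -> dict:
        return {
            "channels": self.channels,
            "kernel": self.kernel,
            "depth": self.depth,
            "aux_hidden": self.aux_hidden,
            "n_response": self.n_response,
            "seed": self.seed,
        }


@dataclass
class ModelState:
    """Trainable parameters plus the metadata a checkpoint must carry."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)  # freq_step, target_height, library fingerprint


# ---------------------------------------------------------------------------
# initialization


def _uniform_fan_in(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_state(config: ModelConfig, meta: dict | None = None) -> ModelState:
    """Fan-in-scaled uniform initialization of every layer, seeded."""
    rng = np.random.default_rng(config.seed)
    C, K, D = config.channels, config.kernel, config.depth
    p: dict[str, np.ndarray] = {}

    # encoder: 1 -> C, then C -> C
    ins = [1] + [C] * (D - 1)
    for i, cin in enumerate(ins):
        p[f"enc_W{i}"] = _uniform_fan_in(rng, (C, cin, K), cin * K)
        p[f"enc_b{i}"] = _uniform_fan_in(rng, (C,), cin * K)

    p["query"] = _uniform_fan_in(rng, (C,), C)

    # decoder: 2C -> C, C -> C, ..., C -> 1
    d_ins = [2 * C] + [C] * (D - 1)
    d_outs = [C] * (D - 1) + [1]
    for i, (cin, cout) in enumerate(zip(d_ins, d_outs)):
        p[f"dec_W{i}"] = _uniform_fan_in(rng, (cout, cin, K), cin * K)
        p[f"dec_b{i}"] = _uniform_fan_in(rng, (cout,), cin * K)

    p["aux_W0"] = _uniform_fan_in(rng, (config.aux_hidden, C), C)
    p["aux_b0"] = _uniform_fan_in(rng, (config.aux_hidden,), C)
    p["aux_W1"] = _uniform_fan_in(rng, (config.n_response, config.aux_hidden), config.aux_hidden)
    p["aux_b1"] = _uniform_fan_in(rng, (config.n_response,), config.aux_hidden)
    return ModelState(config=config, params=p, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# primitive layers (batched, with explicit backward passes)


def _conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 zero-padded 'same' convolution.

    x: (B, Cin, L); W: (Cout, Cin, K); returns (y, xp) where xp is the padded
    input reused by the backward pass.  Implemented as one matrix product per
    kernel tap so the hot loop stays inside BLAS.
    """
    B, Cin, L = x.shape
    Cout, _, K = W.shape
    P = (K - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (P, P)))
    xt = xp.transpose(1, 0, 2)  # (Cin, B, Lp) view
    acc = np.zeros((Cout, B, L), dtype=x.dtype)
    for k in range(K):
        seg = np.ascontiguousarray(xt[:, :, k : k + L]).reshape(Cin, B * L)
        acc += (W[:, :, k] @ seg).reshape(Cout, B, L)
    y = acc.transpose(1, 0, 2) + b[None, :, None]
    return np.ascontiguousarray(y), xp


def _conv1d_backward(
    dy: np.ndarray, xp: np.ndarray, W: np.ndarray, x_shape: tuple
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of _conv1d: returns (dx, dW, db)."""
    B, Cin, L = x_shape
    Cout, _, K = W.shape
    P = (K - 1) // 2
    xt = xp.transpose(1, 0, 2)
    dyt = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(Cout, B * L)
    dW = np.empty_like(W)
    dxp = np.zeros((Cin, B, L + 2 * P), dtype=dy.dtype)
    for k in range(K):
        seg = np.ascontiguousarray(xt[:, :, k : k + L]).reshape(Cin, B * L)
        dW[:, :, k] = dyt @ seg.T
        dxp[:, :, k : k + L] += (W[:, :, k].T @ dyt).reshape(Cin, B, L)
    db = dy.sum(axis=(0, 2))
    dx = np.ascontiguousarray(dxp[:, :, P : P + L].transpose(1, 0, 2))
    return dx, dW, db


def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# network stages


def encode(x: np.ndarray, state: ModelState, cache: list | None = None) -> np.ndarray:
    """Encoder: (B, L) spectra -> (B, C, L) latent features."""
    cfg = state.config
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] < cfg.autoencoder_receptive_field:
        raise ValueError(
            f"input length {x.shape[-1]} below the receptive field "
            f"{cfg.autoencoder_receptive_field}"
        )
    h = x[:, None, :]
    for i in range(cfg.depth):
        W, b = state.params[f"enc_W{i}"], state.params[f"enc_b{i}"]
        pre, xp_cache = _conv1d(h, W, b)
        if cache is not None:
            cache.append(("conv", xp_cache, W, h.shape))
        if i < cfg.depth - 1:
            h = np.maximum(pre, 0.0)
            if cache is not None:
                cache.append(("relu", pre > 0))
        else:
            h = pre
    return h


def attend(latents: np.ndarray, state: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """Attention pooling: (B, C, L) -> global (B, C) and weights (B, L)."""
    q = state.params["query"]
    scores = np.einsum("bcl,c->bl", latents, q)
    weights = _softmax(scores)
    pooled = np.einsum("bcl,bl->bc", latents, weights)
    return pooled, weights


def decode(
    latents: np.ndarray,
    pooled: np.ndarray,
    state: ModelState,
    cache: list | None = None,
) -> np.ndarray:
    """Decoder: latents (B, C, L) + global (B, C) -> corrected (B, L)."""
    cfg = state.config
    B, C, L = latents.shape
    h = np.concatenate([latents, np.broadcast_to(pooled[:, :, None], (B, C, L))], axis=1)
    for i in range(cfg.depth):
        W, b = state.params[f"dec_W{i}"], state.params[f"dec_b{i}"]
        # stride-1 transposed convolution == convolution with flipped kernel
        pre, xp_cache = _conv1d(h, W[:, :, ::-1], b)
        if cache is not None:
            cache.append(("conv", xp_cache, W[:, :, ::-1], h.shape))
        if i < cfg.depth - 1:
            h = np.maximum(pre, 0.0)
            if cache is not None:
                cache.append(("relu", pre > 0))
        else:
            h = pre
    return h[:, 0, :]


def decode_response(pooled: np.ndarray, state: ModelState) -> np.ndarray:
    """Auxiliary decoder: global vector (B, C) -> response estimate (B, N)."""
    p = state.params
    hidden = np.maximum(pooled @ p["aux_W0"].T + p["aux_b0"], 0.0)
    return hidden @ p["aux_W1"].T + p["aux_b1"]


def forward(
    x: np.ndarray, state: ModelState
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full forward pass.

    Parameters
    ----------
    x
        Spectra, shape (L,) or (B, L).

    Returns
    -------
    corrected, response_estimate, attention_weights
        Shapes (B, L), (B, N), (B, L); leading axis squeezed for 1D input.
    """
    squeeze = x.ndim == 1
    xb = x[None, :] if squeeze else x
    latents = encode(xb, state)
    pooled, weights = attend(latents, state)
    corrected = decode(latents, pooled, state)
    response = decode_response(pooled, state)
    if squeeze:
        return corrected[0], response[0], weights[0]
    return corrected, response, weights


def count_parameters(state: ModelState, include_auxiliary: bool = True) -> int:
    """Total number of trainable scalars.

    ``include_auxiliary=False`` counts only the correction path
    (encoder + attention + decoder), i.e. the parameters exercised at
    inference time.
    """
    total = 0
    for name, arr in state.params.items():
        if not include_auxiliary and name.startswith("aux_"):
            continue
        total += arr.size
    return total


# ---------------------------------------------------------------------------
# training-time forward/backward


def forward_training(x: np.ndarray, state: ModelState) -> tuple[np.ndarray, np.ndarray, dict]:
    """Forward pass retaining every intermediate needed for backprop."""
    cfg = state.config
    enc_cache: list = []
    latents = encode(x, state, cache=enc_cache)

    q = state.params["query"]
    scores = np.einsum("bcl,c->bl", latents, q)
    weights = _softmax(scores)
    pooled = np.einsum("bcl,bl->bc", latents, weights)

    dec_cache: list = []
    corrected = decode(latents, pooled, state, cache=dec_cache)

    p = state.params
    aux_pre = pooled @ p["aux_W0"].T + p["aux_b0"]
    aux_hidden = np.maximum(aux_pre, 0.0)
    response = aux_hidden @ p["aux_W1"].T + p["aux_b1"]

    cache = {
        "enc": enc_cache,
        "dec": dec_cache,
        "latents": latents,
        "weights": weights,
        "pooled": pooled,
        "aux_mask": aux_pre > 0,
        "aux_hidden": aux_hidden,
        "x_shape": x.shape,
    }
    return corrected, response, cache


def _coder_backward(
    dout: np.ndarray, cache: list, prefix: str, state: ModelState, grads: dict,
    flip_dec: bool,
) -> np.ndarray:
    """Backprop through one coder's cached (conv, relu) stack."""
    cfg = state.config
    d = dout
    layer = cfg.depth - 1
    for entry in reversed(cache):
        if entry[0] == "relu":
            d = d * entry[1]
        else:
            _, xp_cache, W_used, x_shape = entry
            d, dW, db = _conv1d_backward(d, xp_cache, W_used, x_shape)
            if flip_dec:
                dW = dW[:, :, ::-1]  # undo the kernel flip of the transposed conv
            grads[f"{prefix}_W{layer}"] = grads.get(f"{prefix}_W{layer}", 0) + dW
            grads[f"{prefix}_b{layer}"] = grads.get(f"{prefix}_b{layer}", 0) + db
            layer -= 1
    return d


def backward(
    d_corrected: np.ndarray, d_response: np.ndarray, cache: dict, state: ModelState
) -> dict[str, np.ndarray]:
    """Gradients of all parameters given output gradients.

    ``d_corrected``: (B, L) gradient w.r.t. the corrected spectra;
    ``d_response``: (B, N) gradient w.r.t. the response estimates.
    """
    cfg = state.config
    p = state.params
    grads: dict[str, np.ndarray] = {}
    latents = cache["latents"]
    weights = cache["weights"]
    pooled = cache["pooled"]
    B, C, L = latents.shape

    # auxiliary decoder
    aux_hidden = cache["aux_hidden"]
    grads["aux_W1"] = d_response.T @ aux_hidden
    grads["aux_b1"] = d_response.sum(axis=0)
    d_hidden = (d_response @ p["aux_W1"]) * cache["aux_mask"]
    grads["aux_W0"] = d_hidden.T @ pooled
    grads["aux_b0"] = d_hidden.sum(axis=0)
    d_pooled = d_hidden @ p["aux_W0"]

    # main decoder (input was concat(latents, broadcast pooled))
    d_cat = _coder_backward(d_corrected[:, None, :], cache["dec"], "dec", state, grads,
                            flip_dec=True)
    d_latents = d_cat[:, :C, :]
    d_pooled = d_pooled + d_cat[:, C:, :].sum(axis=2)

    # attention pooling
    q = p["query"]
    t = np.einsum("bc,bcl->bl", d_pooled, latents)      # d pooled . h_l
    d_scores = weights * (t - np.einsum("bl,bl->b", weights, t)[:, None])
    grads["query"] = np.einsum("bl,bcl->c", d_scores, latents)
    d_latents = d_latents + weights[:, None, :] * d_pooled[:, :, None] \
        + d_scores[:, None, :] * q[None, :, None]

    # encoder
    dx = _coder_backward(d_latents, cache["enc"], "enc", state, grads, flip_dec=False)
    grads["_input"] = dx[:, 0, :]
    return grads


# ---------------------------------------------------------------------------
# checkpoints


def save_state(state: ModelState, path) -> None:
    """Write a checkpoint: parameter arrays + config + metadata (npz)."""
    payload = {f"param_{k}": v for k, v in state.params.items()}
    payload["config_json"] = np.frombuffer(
        json.dumps(state.config.to_dict()).encode(), dtype=np.uint8
    )
    payload["meta_json"] = np.frombuffer(
        json.dumps(state.meta, default=float).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_state(path) -> ModelState:
    with np.load(path) as archive:
        config = ModelConfig(**json.loads(bytes(archive["config_json"])))
        meta = json.loads(bytes(archive["meta_json"]))
        params = {
            k[len("param_"):]: archive[k]
            for k in archive.files
            if k.startswith("param_")
        }
    return ModelState(config=config, params=params, meta=meta)
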