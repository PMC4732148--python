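"""Forward dynamics and parameter accounting for DeepConvLSTM.

Two architectures share a four-layer stack of valid (no-padding)
temporal convolutions applied independently to each sensor channel:

* DeepConvLSTM — ``C(64)-C(64)-C(64)-C(64)-R(128)-R(128)-Sm``: the
  feature maps are read out one time step at a time by two stacked
  peephole-LSTM layers, and the class distribution is taken from a
  softmax layer at the final time step only.
* baseline CNN — ``C(64)-C(64)-C(64)-C(64)-D(128)-D(128)-Sm``: the
  final feature-map tensor is flattened and passed through two ReLU
  dense layers and a softmax.

Everything is plain float64 NumPy. The private ``_forward_cached`` /
``_backward`` pair implements reverse-mode differentiation for the
training module; the public operations are the documented forward
contracts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ConvLayerParams",
    "LSTMLayerParams",
    "LSTMState",
    "DenseLayerParams",
    "ModelSpec",
    "ModelParameters",
    "feature_map_length",
    "conv_layer_forward",
    "lstm_step",
    "lstm_layer_forward",
    "dense_layer_forward",
    "softmax",
    "build_model",
    "count_parameters",
    "model_forward",
    "save_model",
    "load_model",
]

RECURRENT = "lstm"
BASELINE = "cnn"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ConvLayerParams:
    """1-D temporal convolution kernels, shared across sensor channels.

    ``kernels`` has shape ``(F_out, F_in, P)``; there is deliberately no
    channel axis: the same kernel slides over every sensor channel and
    channels are never mixed. ``bias`` has shape ``(F_out,)``. The layer
    nonlinearity is ReLU.
    """

    kernels: np.ndarray
    bias: np.ndarray

    def arrays(self, prefix: str):
        yield f"{prefix}.kernels", self.kernels
        yield f"{prefix}.bias", self.bias


@dataclass
class LSTMLayerParams:
    """Peephole LSTM layer weights.

    Input matrices ``W_a*`` are ``(n_in, n_cells)``, recurrent matrices
    ``W_h*`` are ``(n_cells, n_cells)``. The peephole weights ``w_c*``
    are vectors applied element-wise, letting each gate read its own
    cell state.
    """

    W_ai: np.ndarray
    W_af: np.ndarray
    W_ac: np.ndarray
    W_ao: np.ndarray
    W_hi: np.ndarray
    W_hf: np.ndarray
    W_hc: np.ndarray
    W_ho: np.ndarray
    w_ci: np.ndarray
    w_cf: np.ndarray
    w_co: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def n_in(self) -> int:
        return self.W_ai.shape[0]

    @property
    def n_cells(self) -> int:
        return self.W_ai.shape[1]

    def arrays(self, prefix: str):
        for name in (
            "W_ai", "W_af", "W_ac", "W_ao",
            "W_hi", "W_hf", "W_hc", "W_ho",
            "w_ci", "w_cf", "w_co",
            "b_i", "b_f", "b_c", "b_o",
        ):
            yield f"{prefix}.{name}", getattr(self, name)


@dataclass
class LSTMState:
    """Hidden value h and cell activation c of an LSTM layer.

    Both start at zero at the beginning of every sequence.
    """

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int, batch: int | None = None) -> "LSTMState":
        shape = (n_cells,) if batch is None else (batch, n_cells)
        return cls(h=np.zeros(shape), c=np.zeros(shape))


@dataclass
class DenseLayerParams:
    """Fully-connected layer: activation = sigma(W^T a + b).

    ``W`` is ``(n_in, n_out)``, ``b`` is ``(n_out,)``; ``activation`` is
    "relu" for hidden layers or "softmax" for the output layer.
    """

    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    def arrays(self, prefix: str):
        yield f"{prefix}.W", self.W
        yield f"{prefix}.b", self.b


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    Parameters
    ----------
    variant
        "lstm" for DeepConvLSTM (recurrent readout) or "cnn" for the
        flattened baseline.
    n_channels
        D, number of sensor channels.
    n_classes
        nc, number of output classes (including Null when present).
    window_len
        S1, input sequence length in samples.
    n_conv_layers, kernel_len, n_maps
        Convolutional stack: number of layers (default 4), kernel length
        P (default 5) and feature maps per layer F (default 64).
    n_hidden
        LSTM cells / dense units per readout layer (default 128).
    """

    variant: str = RECURRENT
    n_channels: int = 113
    n_classes: int = 18
    window_len: int = 24
    n_conv_layers: int = 4
    kernel_len: int = 5
    n_maps: int = 64
    n_hidden: int = 128

    def __post_init__(self) -> None:
        if self.variant not in (RECURRENT, BASELINE):
            raise ValueError(f"unknown variant {self.variant!r}")
        if min(self.n_channels, self.n_classes, self.n_hidden) < 1:
            raise ValueError("channels, classes and hidden size must be >= 1")
        if not 1 <= self.n_conv_layers:
            raise ValueError("need at least one convolutional layer")
        min_len = self.n_conv_layers * (self.kernel_len - 1) + 1
        if self.window_len < min_len:
            raise ValueError(
                f"window_len={self.window_len} too short: after "
                f"{self.n_conv_layers} valid convolutions of length "
                f"{self.kernel_len} the feature-map length S-{{l}}-P+1 "
                f"would be non-positive (need S1 >= {min_len})"
            )

    @property
    def final_map_len(self) -> int:
        """Feature-map length after the full convolutional stack."""
        s = self.window_len
        for _ in range(self.n_conv_layers):
            s = feature_map_length(s, self.kernel_len)
        return s

    @property
    def recurrent_input_width(self) -> int:
        """Per-time-step input width to the first LSTM layer (F * D)."""
        return self.n_maps * self.n_channels

    @property
    def flattened_width(self) -> int:
        """Flattened final feature-map size (F * D * S_final)."""
        return self.n_maps * self.n_channels * self.final_map_len

    @property
    def shorthand(self) -> str:
        conv = "-".join([f"C({self.n_maps})"] * self.n_conv_layers)
        tail = "R" if self.variant == RECURRENT else "D"
        return f"{conv}-{tail}({self.n_hidden})-{tail}({self.n_hidden})-Sm"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_channels": self.n_channels,
            "n_classes": self.n_classes,
            "window_len": self.window_len,
            "n_conv_layers": self.n_conv_layers,
            "kernel_len": self.kernel_len,
            "n_maps": self.n_maps,
            "n_hidden": self.n_hidden,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class ModelParameters:
    """All trainable arrays of one model, in layer order."""

    spec: ModelSpec
    conv_layers: list[ConvLayerParams]
    hidden_layers: list  # LSTMLayerParams x2 or DenseLayerParams x2
    output_layer: DenseLayerParams
    seed: int | None = None

    def arrays(self):
        """Yield ``(name, array)`` for every trainable tensor, in order."""
        for i, layer in enumerate(self.conv_layers):
            yield from layer.arrays(f"conv{i + 1}")
        for i, layer in enumerate(self.hidden_layers):
            yield from layer.arrays(f"hidden{i + 1}")
        yield from self.output_layer.arrays("softmax")


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------

def feature_map_length(s_l: int, p_l: int) -> int:
    """Length of a feature map after a valid convolution: S - P + 1.

    The convolution is computed only where kernel and input fully
    overlap, so every layer shrinks the time axis by P - 1.
    """
    if s_l < p_l:
        raise ValueError(
            f"kernel longer than input: S={s_l} < P={p_l}"
        )
    return s_l - p_l + 1


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


def _conv_preact(x: np.ndarray, p: ConvLayerParams) -> np.ndarray:
    """Valid 1-D convolution, batched: (B,F_in,D,S) -> (B,F_out,D,S-P+1).

    Computed as P shifted map-mixing matmuls,
    z[.., t] = sum_p K[:, :, p] @ x[.., t + p],
    which runs through BLAS on contiguous arrays instead of an im2col
    copy of the windowed input.
    """
    f_out, f_in, P = p.kernels.shape
    b, _, d, s = x.shape
    if x.shape[1] != f_in:
        raise ValueError(
            f"feature-map count mismatch: input has {x.shape[1]} maps, "
            f"kernels expect {f_in}"
        )
    if s < P:
        raise ValueError(f"kernel longer than input: S={s} < P={P}")
    s_out = s - P + 1
    # fold batch, channel and time into one long GEMM dimension
    xt = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(f_in, -1)
    zt = np.zeros((f_out, b, d, s_out))
    buf = np.empty((f_out, b * d * s))
    for sh in range(P):
        np.matmul(p.kernels[:, :, sh], xt, out=buf)
        zt += buf.reshape(f_out, b, d, s)[:, :, :, sh : sh + s_out]
    return zt.transpose(1, 0, 2, 3) + p.bias[None, :, None, None]


def conv_layer_forward(x: np.ndarray, p: ConvLayerParams) -> np.ndarray:
    """One convolutional layer: sliding dot product over time + ReLU.

    ``x`` is a feature-map tensor ``(F_in, D, S)`` or a batch
    ``(B, F_in, D, S)``. The kernel slides along the time axis only and
    is shared across all D sensor channels; there is no cross-channel
    mixing, so the channel axis is preserved. Output length follows
    :func:`feature_map_length`.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 3
    if single:
        x = x[None]
    out = _relu(_conv_preact(x, p))
    return out[0] if single else out


def lstm_step(
    a_t: np.ndarray, state: LSTMState, p: LSTMLayerParams
) -> LSTMState:
    """One peephole-LSTM update.

    Gates (logistic sigmoid) read the input, previous hidden value and
    — via element-wise peephole weights — the cell state: input and
    forget gates see c_{t-1}; the output gate sees the freshly updated
    c_t. The candidate cell input and the hidden readout use tanh.
    """
    a_t = np.asarray(a_t, dtype=np.float64)
    if a_t.shape[-1] != p.n_in:
        raise ValueError(
            f"input width {a_t.shape[-1]} does not match n_in={p.n_in}"
        )
    h_prev, c_prev = state.h, state.c
    i = _sigmoid(a_t @ p.W_ai + h_prev @ p.W_hi + p.w_ci * c_prev + p.b_i)
    f = _sigmoid(a_t @ p.W_af + h_prev @ p.W_hf + p.w_cf * c_prev + p.b_f)
    g = np.tanh(a_t @ p.W_ac + h_prev @ p.W_hc + p.b_c)
    c = f * c_prev + i * g
    o = _sigmoid(a_t @ p.W_ao + h_prev @ p.W_ho + p.w_co * c + p.b_o)
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


def lstm_layer_forward(seq: np.ndarray, p: LSTMLayerParams) -> np.ndarray:
    """Run an LSTM layer over a full sequence from a zero initial state.

    ``seq`` is ``(T, n_in)`` or batched ``(B, T, n_in)``; returns the
    hidden-value sequence ``(T, n_cells)`` / ``(B, T, n_cells)``.
    """
    seq = np.asarray(seq, dtype=np.float64)
    single = seq.ndim == 2
    if single:
        seq = seq[None]
    b, t_len, _ = seq.shape
    if t_len == 0:
        raise ValueError("empty input sequence")
    state = LSTMState.zeros(p.n_cells, batch=b)
    hs = np.empty((b, t_len, p.n_cells))
    for t in range(t_len):
        state = lstm_step(seq[:, t, :], state, p)
        hs[:, t, :] = state.h
    return hs[0] if single else hs


def softmax(z: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax along the last axis."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dense_layer_forward(a: np.ndarray, p: DenseLayerParams) -> np.ndarray:
    """Fully-connected layer with ReLU or softmax activation."""
    a = np.asarray(a, dtype=np.float64)
    if a.shape[-1] != p.W.shape[0]:
        raise ValueError(
            f"input width {a.shape[-1]} does not match W rows {p.W.shape[0]}"
        )
    z = a @ p.W + p.b
    if p.activation == "relu":
        return _relu(z)
    if p.activation == "softmax":
        return softmax(z)
    raise ValueError(f"unknown activation {p.activation!r}")


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Random matrix with orthonormal rows (wide) or columns (tall)."""
    rows, cols = shape
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix the sign ambiguity of QR
    if rows < cols:
        return q.T.copy()
    return q.copy()


def build_model(spec: ModelSpec, seed: int = 0) -> ModelParameters:
    """Allocate and initialise all layers implied by a spec.

    Every 2-D weight matrix (conv kernels reshaped to 2-D, the four
    LSTM input and four recurrent matrices separately, dense and softmax
    matrices) is orthogonally initialised; biases and peephole vectors
    start at zero. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    F, P = spec.n_maps, spec.kernel_len

    conv_layers = []
    f_in = 1
    for _ in range(spec.n_conv_layers):
        k2d = _orthogonal(rng, (F, f_in * P))
        conv_layers.append(
            ConvLayerParams(
                kernels=k2d.reshape(F, f_in, P),
                bias=np.zeros(F),
            )
        )
        f_in = F

    n = spec.n_hidden
    hidden_layers: list = []
    if spec.variant == RECURRENT:
        n_in = spec.recurrent_input_width
        for _ in range(2):
            hidden_layers.append(
                LSTMLayerParams(
                    W_ai=_orthogonal(rng, (n_in, n)),
                    W_af=_orthogonal(rng, (n_in, n)),
                    W_ac=_orthogonal(rng, (n_in, n)),
                    W_ao=_orthogonal(rng, (n_in, n)),
                    W_hi=_orthogonal(rng, (n, n)),
                    W_hf=_orthogonal(rng, (n, n)),
                    W_hc=_orthogonal(rng, (n, n)),
                    W_ho=_orthogonal(rng, (n, n)),
                    w_ci=np.zeros(n),
                    w_cf=np.zeros(n),
                    w_co=np.zeros(n),
                    b_i=np.zeros(n),
                    b_f=np.zeros(n),
                    b_c=np.zeros(n),
                    b_o=np.zeros(n),
                )
            )
            n_in = n
    else:
        n_in = spec.flattened_width
        for _ in range(2):
            hidden_layers.append(
                DenseLayerParams(
                    W=_orthogonal(rng, (n_in, n)),
                    b=np.zeros(n),
                    activation="relu",
                )
            )
            n_in = n

    output_layer = DenseLayerParams(
        W=_orthogonal(rng, (n, spec.n_classes)),
        b=np.zeros(spec.n_classes),
        activation="softmax",
    )
    return ModelParameters(
        spec=spec,
        conv_layers=conv_layers,
        hidden_layers=hidden_layers,
        output_layer=output_layer,
        seed=seed,
    )


def count_parameters(m: ModelParameters) -> dict:
    """Count every trainable scalar, per layer and in total.

    LSTM layers count all four input matrices, all four recurrent
    matrices, the four biases and the three peephole vectors:
    ``4*n*n_in + 4*n^2 + 4*n + 3*n``.

    Returns a dict with a ``layers`` list of
    ``{"name", "description", "count"}`` rows (layer numbering starts at
    2, layer 1 being the input) and a ``total``.
    """
    layers = []
    layer_no = 2
    for conv in m.conv_layers:
        f_out, f_in, P = conv.kernels.shape
        count = conv.kernels.size + conv.bias.size
        layers.append(
            {
                "name": f"layer{layer_no}",
                "description": f"conv K:{f_out}x{f_in}x{P} + b:{f_out}",
                "count": int(count),
            }
        )
        layer_no += 1
    for hid in m.hidden_layers:
        if isinstance(hid, LSTMLayerParams):
            n_in, n = hid.n_in, hid.n_cells
            count = 4 * n_in * n + 4 * n * n + 4 * n + 3 * n
            desc = (
                f"lstm Wa*:{n_in}x{n}(x4) + Wh*:{n}x{n}(x4) "
                f"+ b:{n}(x4) + peephole:{n}(x3)"
            )
        else:
            n_in, n = hid.W.shape
            count = n_in * n + n
            desc = f"dense W:{n_in}x{n} + b:{n}"
        layers.append(
            {"name": f"layer{layer_no}", "description": desc, "count": int(count)}
        )
        layer_no += 1
    n_in, nc = m.output_layer.W.shape
    layers.append(
        {
            "name": f"layer{layer_no}",
            "description": f"softmax W:{n_in}x{nc} + b:{nc}",
            "count": int(n_in * nc + nc),
        }
    )
    return {"layers": layers, "total": int(sum(r["count"] for r in layers))}


# ---------------------------------------------------------------------------
# full forward pass (+ cached version and backward pass for training)
# ---------------------------------------------------------------------------

def _maps_to_sequence(maps: np.ndarray) -> np.ndarray:
    """(B, F, D, S) feature maps -> (B, T=S, F*D) per-time-step vectors.

    Flattening is map-major: element ``f * D + d`` of the step vector is
    feature map f at channel d.
    """
    b, f, d, s = maps.shape
    return maps.transpose(0, 3, 1, 2).reshape(b, s, f * d)


def _forward_cached(
    m: ModelParameters,
    x: np.ndarray,
    dropout_masks: list[np.ndarray] | None = None,
):
    """Batched forward pass keeping every intermediate needed by backprop.

    ``x`` is ``(B, D, S1)``. ``dropout_masks`` — already scaled by
    1/(1-p) — multiply the inputs of hidden layer 1, hidden layer 2 and
    the softmax layer, in that order (None means no dropout).

    Returns ``(probs, cache)``.
    """
    spec = m.spec
    if x.ndim != 3 or x.shape[1] != spec.n_channels or x.shape[2] != spec.window_len:
        raise ValueError(
            f"input shape {x.shape} does not match spec "
            f"(B, {spec.n_channels}, {spec.window_len})"
        )
    cache: dict = {"conv": []}
    a = x[:, None, :, :]  # (B, 1, D, S1)
    for conv in m.conv_layers:
        z = _conv_preact(a, conv)
        out = _relu(z)
        cache["conv"].append({"input": a, "mask": z > 0})
        a = out
    cache["maps"] = a  # (B, F, D, S_final)

    masks = dropout_masks if dropout_masks is not None else [None, None, None]

    if spec.variant == RECURRENT:
        seq = _maps_to_sequence(a)  # (B, T, F*D)
        if masks[0] is not None:
            seq = seq * masks[0]
        cache["lstm"] = []
        h = seq
        for li, layer in enumerate(m.hidden_layers):
            if li == 1 and masks[1] is not None:
                h = h * masks[1]
            h = _lstm_forward_cached(h, layer, cache["lstm"])
        h_last = h[:, -1, :]
        if masks[2] is not None:
            h_last = h_last * masks[2]
        cache["softmax_in"] = h_last
        logits = h_last @ m.output_layer.W + m.output_layer.b
    else:
        flat = a.reshape(a.shape[0], -1)  # map-major, then channel, then time
        if masks[0] is not None:
            flat = flat * masks[0]
        cache["dense"] = []
        h = flat
        for li, layer in enumerate(m.hidden_layers):
            if li == 1 and masks[1] is not None:
                h = h * masks[1]
            z = h @ layer.W + layer.b
            out = _relu(z)
            cache["dense"].append({"input": h, "mask": z > 0})
            h = out
        if masks[2] is not None:
            h = h * masks[2]
        cache["softmax_in"] = h
        logits = h @ m.output_layer.W + m.output_layer.b

    probs = softmax(logits)
    cache["probs"] = probs
    cache["masks"] = masks
    return probs, cache


def _lstm_forward_cached(
    seq: np.ndarray, p: LSTMLayerParams, cache_list: list
) -> np.ndarray:
    """LSTM forward over (B, T, n_in), caching per-step gate activations.

    The input projections of all four gates are computed for the whole
    sequence in one matmul each; the time loop carries only the
    recurrent and peephole terms.
    """
    b, t_len, _ = seq.shape
    n = p.n_cells
    pa_i = seq @ p.W_ai + p.b_i  # (B, T, n)
    pa_f = seq @ p.W_af + p.b_f
    pa_g = seq @ p.W_ac + p.b_c
    pa_o = seq @ p.W_ao + p.b_o
    h = np.zeros((b, n))
    c = np.zeros((b, n))
    gates = {k: np.empty((b, t_len, n)) for k in ("i", "f", "g", "o", "c")}
    h_prev = np.empty((b, t_len, n))
    c_prev = np.empty((b, t_len, n))
    hs = np.empty((b, t_len, n))
    for t in range(t_len):
        h_prev[:, t], c_prev[:, t] = h, c
        i = _sigmoid(pa_i[:, t] + h @ p.W_hi + p.w_ci * c)
        f = _sigmoid(pa_f[:, t] + h @ p.W_hf + p.w_cf * c)
        g = np.tanh(pa_g[:, t] + h @ p.W_hc)
        c = f * c + i * g
        o = _sigmoid(pa_o[:, t] + h @ p.W_ho + p.w_co * c)
        h = o * np.tanh(c)
        gates["i"][:, t], gates["f"][:, t], gates["g"][:, t] = i, f, g
        gates["o"][:, t], gates["c"][:, t] = o, c
        hs[:, t] = h
    cache_list.append(
        {"params": p, "input": seq, "gates": gates,
         "h_prev": h_prev, "c_prev": c_prev}
    )
    return hs


def _lstm_backward(
    dh_seq: np.ndarray, layer_cache: dict
) -> tuple[np.ndarray, dict]:
    """Backpropagation through time for one peephole-LSTM layer.

    ``dh_seq`` is the gradient w.r.t. the hidden-value sequence
    ``(B, T, n)``. Returns the gradient w.r.t. the input sequence and a
    dict of parameter gradients keyed like the parameter field names.
    """
    p: LSTMLayerParams = layer_cache["params"]
    gates = layer_cache["gates"]
    h_prev_seq = layer_cache["h_prev"]
    c_prev_seq = layer_cache["c_prev"]
    seq = layer_cache["input"]
    b, t_len, n = dh_seq.shape

    # the time loop computes only the pre-activation gradients; all
    # parameter and input gradients follow from them in big matmuls
    dz = {k: np.empty((b, t_len, n)) for k in ("i", "f", "g", "o")}
    dh_next = np.zeros((b, n))
    dc_next = np.zeros((b, n))
    for t in range(t_len - 1, -1, -1):
        i, f, g = gates["i"][:, t], gates["f"][:, t], gates["g"][:, t]
        o, c = gates["o"][:, t], gates["c"][:, t]
        c_prev = c_prev_seq[:, t]
        dh = dh_seq[:, t, :] + dh_next
        tanh_c = np.tanh(c)
        dzo = dh * tanh_c * o * (1.0 - o)
        dc = dh * o * (1.0 - tanh_c**2) + dc_next + dzo * p.w_co
        dzi = dc * g * i * (1.0 - i)
        dzf = dc * c_prev * f * (1.0 - f)
        dzg = dc * i * (1.0 - g**2)
        dz["i"][:, t], dz["f"][:, t] = dzi, dzf
        dz["g"][:, t], dz["o"][:, t] = dzg, dzo
        dh_next = (
            dzi @ p.W_hi.T + dzf @ p.W_hf.T + dzg @ p.W_hc.T + dzo @ p.W_ho.T
        )
        dc_next = dc * f + dzi * p.w_ci + dzf * p.w_cf

    seq_f = seq.reshape(b * t_len, p.n_in)
    hp_f = h_prev_seq.reshape(b * t_len, n)
    cp_f = c_prev_seq.reshape(b * t_len, n)
    c_f = gates["c"].reshape(b * t_len, n)
    dz_f = {k: v.reshape(b * t_len, n) for k, v in dz.items()}
    grads = {
        "W_ai": seq_f.T @ dz_f["i"],
        "W_af": seq_f.T @ dz_f["f"],
        "W_ac": seq_f.T @ dz_f["g"],
        "W_ao": seq_f.T @ dz_f["o"],
        "W_hi": hp_f.T @ dz_f["i"],
        "W_hf": hp_f.T @ dz_f["f"],
        "W_hc": hp_f.T @ dz_f["g"],
        "W_ho": hp_f.T @ dz_f["o"],
        "w_ci": (dz_f["i"] * cp_f).sum(axis=0),
        "w_cf": (dz_f["f"] * cp_f).sum(axis=0),
        "w_co": (dz_f["o"] * c_f).sum(axis=0),
        "b_i": dz_f["i"].sum(axis=0),
        "b_f": dz_f["f"].sum(axis=0),
        "b_c": dz_f["g"].sum(axis=0),
        "b_o": dz_f["o"].sum(axis=0),
    }
    da_seq = (
        dz["i"] @ p.W_ai.T + dz["f"] @ p.W_af.T
        + dz["g"] @ p.W_ac.T + dz["o"] @ p.W_ao.T
    )
    return da_seq, grads


def _conv_backward(
    dz: np.ndarray, x: np.ndarray, p: ConvLayerParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward through a conv pre-activation.

    ``dz`` is ``(B, F_out, D, S_out)``, ``x`` the layer input
    ``(B, F_in, D, S)``. Returns (dx, dK, db), using the same shifted
    matmul decomposition as the forward pass.
    """
    f_out, f_in, P = p.kernels.shape
    b, _, d, s = x.shape
    s_out = s - P + 1
    db = dz.sum(axis=(0, 2, 3))
    dzt = np.ascontiguousarray(dz.transpose(1, 0, 2, 3)).reshape(f_out, -1)
    xt = x.transpose(1, 0, 2, 3)
    dK = np.empty_like(p.kernels)
    dxt = np.zeros((f_in, b, d, s))
    for sh in range(P):
        xs = np.ascontiguousarray(xt[:, :, :, sh : sh + s_out]).reshape(
            f_in, -1
        )
        # contraction of dz and the shifted input over batch, channel, time
        dK[:, :, sh] = dzt @ xs.T
        dxt[:, :, :, sh : sh + s_out] += np.matmul(
            p.kernels[:, :, sh].T, dzt
        ).reshape(f_in, b, d, s_out)
    return dxt.transpose(1, 0, 2, 3), dK, db


def _backward(
    m: ModelParameters, cache: dict, labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradient of the mean cross-entropy loss w.r.t. every parameter.

    The loss attaches to the softmax output at the final time step (the
    only readout of the recurrent variant). Returns ``{name: grad}``
    with names matching :meth:`ModelParameters.arrays`.
    """
    spec = m.spec
    probs = cache["probs"]
    b = probs.shape[0]
    masks = cache["masks"]

    dlogits = probs.copy()
    dlogits[np.arange(b), labels] -= 1.0
    dlogits /= b

    grads: dict[str, np.ndarray] = {}
    sm_in = cache["softmax_in"]
    grads["softmax.W"] = sm_in.T @ dlogits
    grads["softmax.b"] = dlogits.sum(axis=0)
    d_sm_in = dlogits @ m.output_layer.W.T
    if masks[2] is not None:
        d_sm_in = d_sm_in * masks[2]

    if spec.variant == RECURRENT:
        lstm2_cache = cache["lstm"][1]
        t_len = lstm2_cache["input"].shape[1]
        n = m.hidden_layers[1].n_cells
        dh2 = np.zeros((b, t_len, n))
        dh2[:, -1, :] = d_sm_in
        dseq2, g2 = _lstm_backward(dh2, lstm2_cache)
        for k, v in g2.items():
            grads[f"hidden2.{k}"] = v
        if masks[1] is not None:
            dseq2 = dseq2 * masks[1]
        dseq1, g1 = _lstm_backward(dseq2, cache["lstm"][0])
        for k, v in g1.items():
            grads[f"hidden1.{k}"] = v
        if masks[0] is not None:
            dseq1 = dseq1 * masks[0]
        # (B, T, F*D) -> (B, F, D, S)
        maps = cache["maps"]
        bb, f, d, s = maps.shape
        da = dseq1.reshape(bb, s, f, d).transpose(0, 2, 3, 1)
    else:
        d_h = d_sm_in
        for li in (1, 0):
            layer = m.hidden_layers[li]
            lc = cache["dense"][li]
            dz = d_h * lc["mask"]
            grads[f"hidden{li + 1}.W"] = lc["input"].T @ dz
            grads[f"hidden{li + 1}.b"] = dz.sum(axis=0)
            d_h = dz @ layer.W.T
            if li == 1 and masks[1] is not None:
                d_h = d_h * masks[1]
        if masks[0] is not None:
            d_h = d_h * masks[0]
        da = d_h.reshape(cache["maps"].shape)

    for ci in range(len(m.conv_layers) - 1, -1, -1):
        conv = m.conv_layers[ci]
        lc = cache["conv"][ci]
        dz = da * lc["mask"]
        da, dK, db = _conv_backward(dz, lc["input"], conv)
        grads[f"conv{ci + 1}.kernels"] = dK
        grads[f"conv{ci + 1}.bias"] = db
    return grads


def model_forward(window: np.ndarray, m: ModelParameters) -> np.ndarray:
    """Class probability distribution for one window or a batch.

    ``window`` is ``(D, S1)`` or ``(B, D, S1)``. The convolutional stack
    runs first; the recurrent variant then reads the feature maps one
    time step at a time through both LSTM layers and applies the softmax
    to the hidden value at the final time step only, once the whole
    sequence has been observed. The baseline flattens the feature maps
    and applies two ReLU dense layers. Dropout is inactive at inference.
    """
    window = np.asarray(window, dtype=np.float64)
    single = window.ndim == 2
    if single:
        window = window[None]
    probs, _ = _forward_cached(m, window)
    return probs[0] if single else probs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(m: ModelParameters, path) -> None:
    """Write all parameters plus spec and seed to one ``.npz`` archive.

    Arrays are stored under their :meth:`ModelParameters.arrays` names;
    the spec is stored as a JSON string. Round-trips bit-exactly.
    """
    payload = {name: arr for name, arr in m.arrays()}
    payload["__spec__"] = np.frombuffer(
        json.dumps(m.spec.to_dict()).encode(), dtype=np.uint8
    )
    payload["__seed__"] = np.array(-1 if m.seed is None else m.seed)
    np.savez(path, **payload)


def load_model(path) -> ModelParameters:
    """Inverse of :func:`save_model`."""
    with np.load(path) as npz:
        spec = ModelSpec.from_dict(
            json.loads(bytes(npz["__spec__"]).decode())
        )
        seed = int(npz["__seed__"])
        m = build_model(spec, seed=max(seed, 0))
        m.seed = None if seed < 0 else seed
        for name, arr in m.arrays():
            arr[...] = npz[name]
    return m
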