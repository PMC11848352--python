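"""The conditional noise-prediction network and its embedding machinery.

The network ``Diff`` maps a two-channel image — the noisy target stacked
with the clean structural condition — plus a time step and a modality class
to a single-channel noise estimate.  Conditioning enters through one
*final embedding*: a sin-cos time-step embedding, deepened by a two-layer
fully connected stack, plus a learnable per-modality class vector.  The
class vector is the "output prompt": the same trained network denoises
toward the structural (MRI-like) or functional (PET-like) modality
depending on which vector is added.

The backbone is a small U-Net: a contracting path of double-conv blocks
with 2x average pooling, a bottleneck, and an expanding path that upsamples
and merges the lower-level but higher-resolution skip features.  The final
embedding is broadcast-added inside every block through a per-block linear
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import AvgPool, Conv, Linear, Param, SiLU, Upsample

__all__ = [
    "MODALITIES",
    "EmbeddingConfig",
    "ClassEmbeddingTable",
    "DeepEmbed",
    "NoisePredictor",
    "timestep_embedding",
    "predict_noise",
]

#: Modality classes the conditioning distinguishes: the structural (MRI-like)
#: channel and the functional (PET-like) channel.
MODALITIES = ("MRI", "PET")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Sin-cos time-step embedding geometry.

    ``dim`` must be even: the first ``dim/2`` entries are sine terms, the
    rest cosine terms.  ``mp`` is the maximum period of the slowest
    frequency (default 10,000).
    """

    dim: int = 512
    mp: float = 10_000.0

    def __post_init__(self) -> None:
        if self.dim % 2:
            raise ValueError(f"embedding dim must be even, got {self.dim}")
        if self.mp <= 1.0:
            raise ValueError("maximum period must exceed 1")

    @property
    def n_freq(self) -> int:
        return self.dim // 2


def timestep_embedding(t, config: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Sin-cos embedding of one or more non-negative time steps.

    For frequency index ``i = 0..n_freq-1``,
    ``seq_i = exp(-log(mp) * i / n_freq) * t`` and the embedding is
    ``concat(sin(seq), cos(seq))``.  Scalar ``t`` gives a ``(dim,)`` vector;
    an array of steps gives ``(len(t), dim)``.
    """
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValueError("time step must be non-negative")
    i = np.arange(config.n_freq, dtype=np.float64)
    freqs = np.exp(-np.log(config.mp) * i / config.n_freq)
    seq = t_arr[..., None] * freqs
    return np.concatenate([np.sin(seq), np.cos(seq)], axis=-1)


class ClassEmbeddingTable:
    """One learnable vector per modality class, same length as the
    time-step embedding."""

    def __init__(self, dim: int, rng: np.random.Generator, init_sd: float = 0.02):
        self.dim = dim
        self.table = {m: Param(rng.standard_normal(dim) * init_sd) for m in MODALITIES}

    def __getitem__(self, modality: str) -> np.ndarray:
        if modality not in self.table:
            raise KeyError(
                f"unknown modality {modality!r}; allowed: {sorted(self.table)}"
            )
        return self.table[modality].value

    def params(self) -> list[Param]:
        return [self.table[m] for m in MODALITIES]


class DeepEmbed:
    """Two affine maps with a SiLU between: the ``fc`` stack that deepens
    the raw sin-cos embedding."""

    def __init__(self, dim: int, rng: np.random.Generator) -> None:
        self.lin1 = Linear(dim, dim, rng)
        self.act = SiLU()
        self.lin2 = Linear(dim, dim, rng)

    def forward(self, emb: np.ndarray) -> np.ndarray:
        emb = np.atleast_2d(np.asarray(emb, dtype=np.float32))
        if emb.shape[-1] != self.lin1.W.value.shape[1]:
            raise ValueError(
                f"embedding length {emb.shape[-1]} != expected "
                f"{self.lin1.W.value.shape[1]}"
            )
        return self.lin2.forward(self.act.forward(self.lin1.forward(emb)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.lin1.backward(self.act.backward(self.lin2.backward(dy)))

    def params(self) -> list[Param]:
        return self.lin1.params() + self.lin2.params()


class _ConvBlock:
    """conv -> +emb -> SiLU -> conv -> SiLU, with a per-block linear
    projection of the final embedding broadcast-added to the feature maps."""

    def __init__(self, c_in, c_out, emb_dim, ndim, rng):
        self.ndim = ndim
        self.conv1 = Conv(c_in, c_out, ndim, rng=rng)
        self.proj = Linear(emb_dim, c_out, rng)
        self.act1 = SiLU()
        self.conv2 = Conv(c_out, c_out, ndim, rng=rng)
        self.act2 = SiLU()

    def forward(self, x, emb):
        h = self.conv1.forward(x)
        h = h + self.proj.forward(emb).reshape(emb.shape[0], -1, *(1,) * self.ndim)
        h = self.act1.forward(h)
        return self.act2.forward(self.conv2.forward(h))

    def backward(self, dy):
        dh = self.act1.backward(self.conv2.backward(self.act2.backward(dy)))
        spatial_axes = tuple(range(2, 2 + self.ndim))
        demb = self.proj.backward(dh.sum(axis=spatial_axes))
        return self.conv1.backward(dh), demb

    def params(self):
        return self.conv1.params() + self.proj.params() + self.conv2.params()


class NoisePredictor:
    """U-Net style conditional noise predictor.

    Parameters
    ----------
    depth : number of pooling levels (spatial sizes must divide 2**depth).
    base_width : channel count at full resolution; doubles per level.
    ndim : spatial dimensionality of the volumes (2 or 3).
    parametrization : what the convolutional head regresses.  With ``"eps"``
        the head output is the noise estimate directly.  With ``"x0"`` (the
        default) the head regresses the clean-image estimate and the noise
        estimate is derived algebraically,

            eps_hat = (x_t - sqrt(alpha_bar_t) * x0_hat) / sqrt(1 - alpha_bar_t),

        so the predictor still *outputs* noise and trains under the same
        masked noise-MSE — but the regressed function is nearly independent
        of ``t`` for a strongly conditioned task, which conditions training
        far better at small compute.  ``"x0"`` needs the noise schedule:
        bind one with :meth:`bind_schedule` (training and synthesis do this
        automatically).
    """

    def __init__(
        self,
        depth: int = 3,
        base_width: int = 32,
        ndim: int = 2,
        emb_config: EmbeddingConfig | None = None,
        seed: int = 0,
        parametrization: str = "x0",
    ) -> None:
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if parametrization not in ("eps", "x0"):
            raise ValueError("parametrization must be 'eps' or 'x0'")
        self.depth = depth
        self.base_width = base_width
        self.ndim = ndim
        self.emb_config = emb_config or EmbeddingConfig()
        self.seed = seed
        self.parametrization = parametrization
        self._alpha_bars: np.ndarray | None = None
        rng = np.random.default_rng(seed)
        dim = self.emb_config.dim

        self.class_table = ClassEmbeddingTable(dim, rng)
        self.deep_embed = DeepEmbed(dim, rng)

        chs = [base_width * 2**d for d in range(depth + 1)]
        self.stem = Conv(2, chs[0], ndim, rng=rng)
        self.stem_act = SiLU()
        self.down = []
        self.pools = []
        for d in range(depth):
            c_in = chs[0] if d == 0 else chs[d - 1]
            self.down.append(_ConvBlock(c_in, chs[d], dim, ndim, rng))
            self.pools.append(AvgPool())
        mid_in = chs[0] if depth == 0 else chs[depth - 1]
        self.mid = _ConvBlock(mid_in, chs[depth], dim, ndim, rng)
        self.up = []
        self.upsamples = []
        for d in reversed(range(depth)):
            c_above = chs[d + 1]
            self.up.append(_ConvBlock(c_above + chs[d], chs[d], dim, ndim, rng))
            self.upsamples.append(Upsample())
        head_in = chs[0] if depth else chs[depth]
        self.head = Conv(head_in, 1, ndim, rng=rng, zero_init=True)

    # -- parameters -------------------------------------------------------
    def params(self) -> list[Param]:
        ps = self.class_table.params() + self.deep_embed.params()
        ps += self.stem.params()
        for blk in self.down:
            ps += blk.params()
        ps += self.mid.params()
        for blk in self.up:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def hyperparams(self) -> dict:
        return {
            "depth": self.depth,
            "base_width": self.base_width,
            "ndim": self.ndim,
            "emb_dim": self.emb_config.dim,
            "emb_mp": self.emb_config.mp,
            "seed": self.seed,
            "parametrization": self.parametrization,
        }

    def bind_schedule(self, schedule) -> None:
        """Give the model access to the alpha-bar sequence (needed by the
        ``"x0"`` parametrization to convert its head output into a noise
        estimate)."""
        self._alpha_bars = np.asarray(schedule.alpha_bars, dtype=np.float64)

    def _alpha_bar_of(self, t_arr: np.ndarray) -> np.ndarray:
        if self._alpha_bars is None:
            raise ValueError(
                "the 'x0' parametrization needs a bound noise schedule; "
                "call model.bind_schedule(schedule) first"
            )
        padded = np.concatenate([[1.0], self._alpha_bars])
        if np.any(t_arr < 0) or np.any(t_arr >= padded.size):
            raise ValueError(f"t out of range 0..{padded.size - 1}")
        return padded[t_arr]

    # -- embedding path ---------------------------------------------------
    def final_embedding(self, t, modality) -> np.ndarray:
        """Deep time embedding plus the modality's class vector.

        ``t`` may be a scalar with a single modality string, or an array of
        steps with a matching sequence of modality strings; returns
        ``(N, dim)`` float32.
        """
        t_arr = np.atleast_1d(np.asarray(t))
        mods = [modality] * t_arr.size if isinstance(modality, str) else list(modality)
        if len(mods) != t_arr.size:
            raise ValueError("modality list length must match t")
        for m in mods:
            if m not in MODALITIES:
                raise ValueError(
                    f"unknown modality {m!r}; allowed: {sorted(MODALITIES)}"
                )
        raw = timestep_embedding(t_arr, self.emb_config)
        deep = self.deep_embed.forward(raw.astype(np.float32))
        cls = np.stack([self.class_table[m] for m in mods])
        self._emb_mods = mods
        return deep + cls

    def _embedding_backward(self, demb: np.ndarray) -> None:
        for i, m in enumerate(self._emb_mods):
            self.class_table.table[m].grad += demb[i]
        self.deep_embed.backward(demb)

    # -- network ----------------------------------------------------------
    def forward_batch(self, x2: np.ndarray, t, modality, raw: bool = False) -> np.ndarray:
        """Predict noise for a batch ``x2`` of shape ``(N, 2, *spatial)``
        (channel 0: noisy target, channel 1: clean condition).

        With ``raw=True`` (and the ``"x0"`` parametrization) the head's
        clean-image estimate is returned without conversion to a noise
        estimate — the quantity the training loop regresses directly.
        """
        x2 = np.ascontiguousarray(x2, dtype=np.float32)
        if x2.ndim != 2 + self.ndim or x2.shape[1] != 2:
            raise ValueError(
                f"expected batch of shape (N, 2, *spatial{self.ndim}d), got {x2.shape}"
            )
        for s in x2.shape[2:]:
            if s % (2**self.depth):
                raise ValueError(
                    f"spatial size {s} not divisible by 2**depth={2**self.depth}"
                )
        emb = self.final_embedding(t, modality)
        h = self.stem_act.forward(self.stem.forward(x2))
        skips = []
        for blk, pool in zip(self.down, self.pools):
            h = blk.forward(h, emb)
            skips.append(h)
            h = pool.forward(h)
        h = self.mid.forward(h, emb)
        self._skip_channels = [s.shape[1] for s in skips]
        for blk, ups in zip(self.up, self.upsamples):
            h = ups.forward(h)
            h = np.concatenate([h, skips.pop()], axis=1)
            h = blk.forward(h, emb)
        out = self.head.forward(h)
        self._last_raw = raw or self.parametrization == "eps"
        if self._last_raw:
            return out
        # x0 head -> algebraic noise estimate; at t = 0 the state is clean
        # and the noise is zero by definition
        t_arr = np.atleast_1d(np.asarray(t, dtype=np.int64))
        if t_arr.size == 1 and x2.shape[0] > 1:
            t_arr = np.full(x2.shape[0], int(t_arr[0]), dtype=np.int64)
        ab = self._alpha_bar_of(t_arr)
        shape = (-1, 1) + (1,) * self.ndim
        sq_ab = np.sqrt(ab).reshape(shape).astype(np.float32)
        sq_1mab = np.sqrt(1.0 - ab).reshape(shape).astype(np.float32)
        coef = np.where(sq_1mab > 0.0, sq_ab / np.maximum(sq_1mab, 1e-12), 0.0)
        inv = np.where(sq_1mab > 0.0, 1.0 / np.maximum(sq_1mab, 1e-12), 0.0)
        self._x0_coef = coef.astype(np.float32)
        eps_hat = inv * x2[:, :1] - coef * out
        return eps_hat.astype(np.float32)

    def backward_batch(self, d_eps: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the predicted noise, accumulating
        into every parameter's ``.grad`` (including the embedding path)."""
        d_eps = np.ascontiguousarray(d_eps, dtype=np.float32)
        if not self._last_raw:
            d_eps = -self._x0_coef * d_eps
        demb_total = 0.0
        dh = self.head.backward(d_eps)
        d_skips = []
        # self.up[j] consumed skip level depth-1-j in forward, so walking
        # reversed(self.up) yields skip-gradients for levels 0, 1, ... in order
        for blk, ups in zip(reversed(self.up), reversed(self.upsamples)):
            dcat, demb = blk.backward(dh)
            demb_total = demb_total + demb
            c_up = dcat.shape[1] - self._skip_channels[len(d_skips)]
            d_up, d_skip = dcat[:, :c_up], dcat[:, c_up:]
            d_skips.append(d_skip)
            dh = ups.backward(d_up)
        dh, demb = self.mid.backward(dh)
        demb_total = demb_total + demb
        for i, (blk, pool) in enumerate(zip(reversed(self.down), reversed(self.pools))):
            dh = pool.backward(dh)
            dh = dh + d_skips[self.depth - 1 - i]
            dh, demb = blk.backward(dh)
            demb_total = demb_total + demb
        self.stem.backward(self.stem_act.backward(dh))
        self._embedding_backward(np.asarray(demb_total, dtype=np.float32))

    def predict(
        self, x_noisy: np.ndarray, condition: np.ndarray, t: int, modality: str
    ) -> np.ndarray:
        """Single-volume convenience wrapper around :meth:`forward_batch`."""
        x_noisy = np.asarray(x_noisy)
        condition = np.asarray(condition)
        if x_noisy.shape != condition.shape:
            raise ValueError(
                f"shape mismatch: noisy {x_noisy.shape} vs condition {condition.shape}"
            )
        x2 = np.stack([x_noisy, condition])[None]
        return self.forward_batch(x2, t, modality)[0, 0].astype(np.float64)


def predict_noise(
    model: NoisePredictor,
    x_noisy: np.ndarray,
    condition: np.ndarray,
    t: int,
    modality: str,
) -> np.ndarray:
    """Functional form of :meth:`NoisePredictor.predict`."""
    return model.predict(x_noisy, condition, t, modality)
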