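"""Variance schedule for the forward/reverse diffusion processes.

The forward process corrupts an image over ``T`` discrete steps with
per-step variances ``beta_1 .. beta_T``.  Everything downstream only needs
the cumulative products ``alpha_bar_t = prod_{s<=t} (1 - beta_s)``, plus a
strided subsequence of steps used for accelerated (DDIM-style) sampling.

Indexing convention: mathematically ``t`` runs ``1..T``; arrays are stored
0-based, and ``alpha_bar(0) == 1`` is defined so boundary formulas (a clean
image at ``t = 0``) need no special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "make_schedule"]

DEFAULT_BETA_START = 1e-4
DEFAULT_BETA_END = 0.02


@dataclass(frozen=True)
class NoiseSchedule:
    """Immutable container of the beta/alpha/alpha-bar sequences.

    Attributes
    ----------
    betas : (T,) array, ``betas[k]`` is beta_{k+1}.
    sample_steps : strictly increasing integer array, a subsequence of
        ``1..T`` ending at ``T``; the time steps visited during accelerated
        sampling (and, mirrored, during deterministic inversion).
    """

    betas: np.ndarray
    sample_steps: np.ndarray
    alphas: np.ndarray = field(init=False, repr=False)
    alpha_bars: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=np.float64)
        if betas.ndim != 1 or betas.size == 0:
            raise ValueError("betas must be a non-empty 1-D sequence")
        if np.any(betas <= 0.0) or np.any(betas >= 1.0):
            raise ValueError("betas must satisfy 0 < beta_t < 1")
        if np.any(np.diff(betas) < 0):
            raise ValueError("betas must be non-decreasing")
        steps = np.asarray(self.sample_steps, dtype=np.int64)
        if steps.ndim != 1 or steps.size == 0:
            raise ValueError("sample_steps must be a non-empty 1-D sequence")
        if np.any(np.diff(steps) <= 0):
            raise ValueError("sample_steps must be strictly increasing")
        if steps[0] < 1 or steps[-1] != betas.size:
            raise ValueError("sample_steps must lie in 1..T and include T")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "sample_steps", steps)
        object.__setattr__(self, "alphas", 1.0 - betas)
        object.__setattr__(self, "alpha_bars", np.cumprod(1.0 - betas))

    @property
    def T(self) -> int:
        return int(self.betas.size)

    def alpha_bar(self, t):
        """``alpha_bar_t`` for integer ``t`` in ``0..T`` (scalar or array)."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValueError(f"t must lie in 0..{self.T}")
        padded = np.concatenate([[1.0], self.alpha_bars])
        out = padded[t]
        return float(out) if out.ndim == 0 else out

    def step_pairs(self):
        """(t, t_prev) pairs in sampling (descending) order.

        The last pair ends at ``t_prev = 0``, i.e. the clean image.
        """
        prev = np.concatenate([[0], self.sample_steps[:-1]])
        return list(zip(self.sample_steps[::-1].tolist(), prev[::-1].tolist()))

    def inversion_pairs(self):
        """(t, t_next) pairs in inversion (ascending) order, from 0 up to T."""
        return [(p, t) for t, p in reversed(self.step_pairs())]


def make_schedule(
    T: int,
    beta_start: float = DEFAULT_BETA_START,
    beta_end: float = DEFAULT_BETA_END,
    n_sample_steps: int | None = None,
) -> NoiseSchedule:
    """Linear beta schedule with an evenly strided sampling subsequence.

    Defaults follow the common DDPM convention (beta linear from 1e-4 to
    0.02).  ``n_sample_steps`` selects how many of the ``T`` steps the
    accelerated sampler visits; the stride is chosen so the subsequence ends
    exactly at ``T`` and its first element's predecessor is 0.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got beta_start={beta_start}, "
            f"beta_end={beta_end}"
        )
    if n_sample_steps is None:
        n_sample_steps = T
    if not (1 <= n_sample_steps <= T):
        raise ValueError(
            f"n_sample_steps must lie in 1..T={T}, got {n_sample_steps}"
        )
    betas = np.linspace(beta_start, beta_end, T)
    # even stride T/n; increments >= 1 so rounding keeps it strictly increasing
    steps = np.round(np.arange(1, n_sample_steps + 1) * (T / n_sample_steps))
    return NoiseSchedule(betas=betas, sample_steps=steps.astype(np.int64))
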