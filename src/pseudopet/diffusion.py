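"""Forward diffusion, brain-masked training loss, generalized reverse step,
deterministic inversion, and the training loop.

The target channel (the functional image during synthesis training, or the
structural image for structural-class examples) is corrupted by

    x_t = sqrt(alpha_bar_t) * x_0 + sqrt(1 - alpha_bar_t) * eps,

while the condition channel stays clean.  Training minimizes a mean squared
error between true and predicted noise, restricted to brain tissue by a
binary mask.  Sampling uses the generalized (DDIM-family) update with a
stochasticity multiplier ``eta``; ``eta = 0`` makes the chain fully
deterministic, which also permits a strided (accelerated) step schedule.
Deterministic inversion runs the same update in the increasing-noise
direction using the model's own noise predictions, encoding an image into
its latent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MODALITIES, NoisePredictor
from .nn import Adam
from .phantoms import VolumePair
from .schedule import NoiseSchedule

__all__ = [
    "TrainConfig",
    "TrainResult",
    "DiffusionStep",
    "normalize_pm1",
    "forward_diffuse",
    "masked_loss",
    "sigma_t",
    "reverse_step",
    "inversion_step",
    "train",
]


def normalize_pm1(x: np.ndarray) -> np.ndarray:
    """Affinely map a volume to the range [-1, 1] using its own min/max."""
    x = np.asarray(x, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("cannot normalize a constant volume (max == min)")
    return (x - lo) / (hi - lo) * 2.0 - 1.0


def forward_diffuse(
    x0: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule
) -> np.ndarray:
    """One-shot corruption of a clean volume to noise level ``t``."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError(f"shape mismatch: x0 {x0.shape} vs eps {eps.shape}")
    if not (1 <= t <= schedule.T):
        raise ValueError(f"t must lie in 1..{schedule.T}, got {t}")
    ab = schedule.alpha_bar(t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def masked_loss(
    eps_pred: np.ndarray,
    eps: np.ndarray,
    mask: np.ndarray,
    within_mask_only: bool = False,
) -> float:
    """Brain-masked mean squared error between true and predicted noise.

    The mask zeroes out-of-brain residuals *before* an unrestricted mean
    over all voxels (the printed formula); ``within_mask_only`` divides by
    the in-mask voxel count instead.
    """
    eps_pred = np.asarray(eps_pred, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    mask = np.asarray(mask)
    if not (eps_pred.shape == eps.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: pred {eps_pred.shape}, eps {eps.shape}, "
            f"mask {mask.shape}"
        )
    n_in = int(np.count_nonzero(mask))
    if n_in == 0:
        raise ValueError("mask selects no voxels")
    sq = (mask != 0) * (eps - eps_pred) ** 2
    denom = n_in if within_mask_only else sq.size
    return float(sq.sum() / denom)


@dataclass(frozen=True)
class DiffusionStep:
    """One reverse transition ``t -> t_prev`` with stochasticity ``eta``."""

    t: int
    t_prev: int
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.t_prev >= self.t:
            raise ValueError(f"t_prev ({self.t_prev}) must be < t ({self.t})")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


def sigma_t(step: DiffusionStep, schedule: NoiseSchedule) -> float:
    """Per-step noise scale of the generalized update, scaled by ``eta``."""
    ab_t = schedule.alpha_bar(step.t)
    ab_prev = schedule.alpha_bar(step.t_prev)
    base = np.sqrt((1.0 - ab_prev) / (1.0 - ab_t)) * np.sqrt(1.0 - ab_t / ab_prev)
    return float(step.eta * base)


def _x0_from_eps(x_t, eps_pred, alpha_bar):
    return (x_t - np.sqrt(1.0 - alpha_bar) * eps_pred) / np.sqrt(alpha_bar)


def reverse_step(
    x_t: np.ndarray,
    eps_pred: np.ndarray,
    step: DiffusionStep,
    schedule: NoiseSchedule,
    rng: np.random.Generator | None = None,
    clip_x0: bool = False,
) -> np.ndarray:
    """Generalized reverse transition from ``x_t`` to ``x_{t_prev}``.

    With ``eta = 0`` (the deterministic setting) no random numbers are
    consumed and ``rng`` may be omitted.  ``clip_x0`` clamps the implied
    clean-image estimate to the model's [-1, 1] data range before
    re-noising — the usual stabilization when sampling with an imperfect
    predictor (out-of-brain voxels carry no training signal under the
    masked loss, and the 1/sqrt(alpha_bar) amplification at high ``t``
    would otherwise blow them up).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    eps_pred = np.asarray(eps_pred, dtype=np.float64)
    if x_t.shape != eps_pred.shape:
        raise ValueError(f"shape mismatch: x_t {x_t.shape} vs eps {eps_pred.shape}")
    if not (1 <= step.t <= schedule.T):
        raise ValueError(f"step.t must lie in 1..{schedule.T}")
    ab_t = schedule.alpha_bar(step.t)
    ab_prev = schedule.alpha_bar(step.t_prev)
    sig = sigma_t(step, schedule)
    resid_var = 1.0 - ab_prev - sig**2
    if resid_var < -1e-12:
        raise ValueError(
            f"sigma_t^2 = {sig**2:.3g} exceeds 1 - alpha_bar_prev = "
            f"{1.0 - ab_prev:.3g}; eta too large for this schedule"
        )
    x0_hat = _x0_from_eps(x_t, eps_pred, ab_t)
    if clip_x0:
        x0_hat = np.clip(x0_hat, -1.0, 1.0)
    out = np.sqrt(ab_prev) * x0_hat + np.sqrt(max(resid_var, 0.0)) * eps_pred
    if sig > 0.0:
        if rng is None:
            raise ValueError("eta > 0 requires an rng")
        out = out + sig * rng.standard_normal(x_t.shape)
    return out


def inversion_step(
    x_t: np.ndarray,
    eps_pred: np.ndarray,
    t: int,
    t_next: int,
    schedule: NoiseSchedule,
    clip_x0: bool = False,
) -> np.ndarray:
    """Deterministic transition in the increasing-noise direction.

    The exact mirror of the ``eta = 0`` reverse step: re-estimate the clean
    image from the current state and the predicted noise, then re-noise it
    to level ``t_next``.  ``t = 0`` means the clean image itself.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    eps_pred = np.asarray(eps_pred, dtype=np.float64)
    if x_t.shape != eps_pred.shape:
        raise ValueError(f"shape mismatch: x_t {x_t.shape} vs eps {eps_pred.shape}")
    if t_next <= t:
        raise ValueError(f"t_next ({t_next}) must exceed t ({t})")
    ab_t = schedule.alpha_bar(t)
    ab_next = schedule.alpha_bar(t_next)
    x0_hat = _x0_from_eps(x_t, eps_pred, ab_t)
    if clip_x0:
        x0_hat = np.clip(x0_hat, -1.0, 1.0)
    return np.sqrt(ab_next) * x0_hat + np.sqrt(1.0 - ab_next) * eps_pred


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyperparameters of the noise-prediction training loop.

    ``modality_mix`` is the probability that a drawn example targets the
    functional (PET-like) channel rather than the structural one; training
    on both classes is what gives the class embedding its steering role.
    """

    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 2e-4
    modality_mix: float = 0.5
    seed: int = 0
    within_mask_only: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.modality_mix <= 1.0):
            raise ValueError("modality_mix must lie in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainResult:
    model: NoisePredictor
    loss_trace: list[float] = field(default_factory=list)


def train(
    dataset: list[VolumePair],
    model: NoisePredictor,
    schedule: NoiseSchedule,
    config: TrainConfig,
) -> TrainResult:
    """Train the noise predictor on paired volumes.

    Per example: both channels are normalized to [-1, 1]; a modality class
    is drawn (functional with probability ``modality_mix``); the drawn
    modality's volume becomes the noised target while the structural volume
    is always the clean condition; a uniform time step and Gaussian noise
    build ``x_t``; a brain-masked MSE is minimized with Adam.  Fully
    deterministic given ``config.seed``.

    With the ``"eps"`` parametrization the regressed quantity is the noise
    itself; with ``"x0"`` (the default) it is the clean target, i.e. the
    same masked-MSE objective with the signal-to-noise weight across time
    steps dropped — the standard "simple loss" reweighting, which keeps the
    per-step gradient scale flat and training stable.  The reported loss
    trace is the masked MSE of the regressed quantity.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    model.bind_schedule(schedule)
    rng = np.random.default_rng(config.seed)
    T = schedule.T

    norm_s = [normalize_pm1(p.structural) for p in dataset]
    norm_f = [normalize_pm1(p.functional) for p in dataset]
    masks = [np.asarray(p.brain_mask != 0) for p in dataset]

    opt = Adam(model.params(), lr=config.learning_rate)
    trace: list[float] = []
    n = len(dataset)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, eps_true, x0s, mods, ts, ms = [], [], [], [], [], []
            for j in idx:
                pet_target = rng.random() < config.modality_mix
                target = norm_f[j] if pet_target else norm_s[j]
                t = int(rng.integers(1, T + 1))
                eps = rng.standard_normal(target.shape)
                x_t = forward_diffuse(target, t, eps, schedule)
                xs.append(np.stack([x_t, norm_s[j]]))
                eps_true.append(eps)
                x0s.append(target)
                mods.append("PET" if pet_target else "MRI")
                ts.append(t)
                ms.append(masks[j])
            x2 = np.stack(xs).astype(np.float32)
            use_x0 = model.parametrization == "x0"
            target_arr = np.stack(x0s if use_x0 else eps_true)[:, None]
            mask_arr = np.stack(ms)[:, None]
            pred = model.forward_batch(x2, np.array(ts), mods, raw=use_x0)
            resid = (pred.astype(np.float64) - target_arr) * mask_arr
            denom = mask_arr.sum() if config.within_mask_only else resid.size
            loss = float((resid**2).sum() / denom)
            model.backward_batch((2.0 * resid / denom).astype(np.float32))
            opt.step()
            trace.append(loss)
    return TrainResult(model=model, loss_trace=trace)
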