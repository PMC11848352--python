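"""End-to-end synthesis strategies: one-way and two-way.

One-way synthesis denoises fresh Gaussian noise down the strided step
schedule with the functional (PET) class embedding, conditioned on the
structural image; its output depends on the initial noise, so a seed is
always recorded.  Two-way synthesis first *encodes* the structural image
into latent noise by running the deterministic update in the
increasing-noise direction with the structural (MRI) class embedding, then
decodes that latent with the functional class embedding — no random numbers
are consumed anywhere, so repeated invocations are bit-identical.

Both strategies operate in the [-1, 1] model space and denormalize the
result to a nonnegative [0, 1] activity scale; downstream similarity
criteria renormalize to [0, 1] anyway, so the choice of output affine does
not affect evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import DiffusionStep, inversion_step, normalize_pm1, reverse_step
from .model import NoisePredictor
from .schedule import NoiseSchedule

__all__ = [
    "SynthesisResult",
    "one_way_synthesize",
    "two_way_synthesize",
    "invert_and_resample",
]


@dataclass(frozen=True)
class SynthesisResult:
    """A synthesized functional volume plus its provenance."""

    functional_hat: np.ndarray
    strategy: str  # "one_way" | "two_way"
    n_steps: int
    seed: int | None  # None iff the strategy consumed no randomness
    schedule_T: int

    def __post_init__(self) -> None:
        if self.strategy == "two_way" and self.seed is not None:
            raise ValueError("two_way synthesis is deterministic; seed must be None")

    def provenance(self) -> dict:
        return {
            "strategy": self.strategy,
            "n_steps": self.n_steps,
            "seed": self.seed,
            "schedule_T": self.schedule_T,
        }


def _denormalize(x: np.ndarray) -> np.ndarray:
    return np.clip((x + 1.0) / 2.0, 0.0, None)


def _apply_mask(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    return x if mask is None else x * (np.asarray(mask) != 0)


def one_way_synthesize(
    model: NoisePredictor,
    structural: np.ndarray,
    schedule: NoiseSchedule,
    seed: int | None = None,
    brain_mask: np.ndarray | None = None,
) -> SynthesisResult:
    """Sample a functional volume from seeded Gaussian noise.

    A missing seed is never silent: a fresh one is drawn and recorded in
    the result so the run can be reproduced.  With ``brain_mask``, voxels
    outside the mask are zeroed in the output — they carry no training
    signal under the brain-masked loss, so their content is meaningless.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    model.bind_schedule(schedule)
    cond = normalize_pm1(structural)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(cond.shape)
    for t, t_prev in schedule.step_pairs():
        eps = model.predict(x, cond, t, "PET")
        x = reverse_step(
            x, eps, DiffusionStep(t=t, t_prev=t_prev, eta=0.0), schedule,
            clip_x0=True,
        )
    return SynthesisResult(
        functional_hat=_apply_mask(_denormalize(x), brain_mask),
        strategy="one_way",
        n_steps=len(schedule.sample_steps),
        seed=seed,
        schedule_T=schedule.T,
    )


def two_way_synthesize(
    model: NoisePredictor,
    structural: np.ndarray,
    schedule: NoiseSchedule,
    brain_mask: np.ndarray | None = None,
) -> SynthesisResult:
    """Encode the structural image to latent noise, decode as functional.

    Phase 1 chains deterministic inversion steps from t = 0 up to T with
    the structural class embedding; phase 2 chains eta = 0 reverse steps
    back down with the functional class embedding.  Deterministic end to
    end; the inversion visits the same strided steps as sampling, keeping
    the two trajectories symmetric.
    """
    model.bind_schedule(schedule)
    cond = normalize_pm1(structural)
    x = cond.copy()
    for t, t_next in schedule.inversion_pairs():
        eps = model.predict(x, cond, t, "MRI")
        x = inversion_step(x, eps, t, t_next, schedule, clip_x0=True)
    for t, t_prev in schedule.step_pairs():
        eps = model.predict(x, cond, t, "PET")
        x = reverse_step(
            x, eps, DiffusionStep(t=t, t_prev=t_prev, eta=0.0), schedule,
            clip_x0=True,
        )
    return SynthesisResult(
        functional_hat=_apply_mask(_denormalize(x), brain_mask),
        strategy="two_way",
        n_steps=len(schedule.sample_steps),
        seed=None,
        schedule_T=schedule.T,
    )


def invert_and_resample(
    model: NoisePredictor,
    volume: np.ndarray,
    schedule: NoiseSchedule,
    modality: str = "MRI",
) -> np.ndarray:
    """Round-trip identity check: encode a volume to latent noise and decode
    it with the *same* class embedding.  Returns the reconstruction in
    [-1, 1] model space alongside-comparable with ``normalize_pm1(volume)``.
    """
    model.bind_schedule(schedule)
    cond = normalize_pm1(volume)
    x = cond.copy()
    for t, t_next in schedule.inversion_pairs():
        eps = model.predict(x, cond, t, modality)
        x = inversion_step(x, eps, t, t_next, schedule, clip_x0=True)
    for t, t_prev in schedule.step_pairs():
        eps = model.predict(x, cond, t, modality)
        x = reverse_step(
            x, eps, DiffusionStep(t=t, t_prev=t_prev, eta=0.0), schedule,
            clip_x0=True,
        )
    return x
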