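"""Synthetic paired structural/functional brain phantoms.

Each phantom emulates an already-preprocessed, skull-stripped, co-registered
scan pair: a smooth multi-region "brain" (elliptical outline, three
concentric tissue shells standing in for CSF/GM/WM, wedge-shaped atlas
parcels) plus a functional image coupled to the structural one through a
fixed monotone nonlinearity.  Disease stage (NC/MCI/AD) multiplicatively
suppresses the functional signal in designated disease regions,
emulating progressive regional hypometabolism, and additive Gaussian noise
models acquisition noise on the functional channel.

The per-subject geometry (ellipse radii, centre, parcel rotation, tissue
texture) is jittered with a subject-specific seed shared across classes, so
pairs for the same subject differ across classes only through the disease
modulation and noise — and both channels share one geometry, keeping pairs
co-registered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["CLASSES", "PhantomConfig", "VolumePair", "generate_pair", "generate_dataset"]

#: Disease-stage labels in progression order.
CLASSES = ("NC", "MCI", "AD")

#: Mean structural intensities of the three tissue shells (arbitrary
#: [0, 255]-like units): CSF-like, GM-like, WM-like.
_SHELL_INTENSITY = {"CSF": 60.0, "GM": 160.0, "WM": 230.0}

#: Monotone structural->functional coupling: a scaled logistic, steep enough
#: that the intensity contrast of the functional channel differs markedly
#: from the structural one (deep-tissue signal saturates, CSF-like signal
#: stays near zero), as it does between real structural and metabolic scans.
_G_CENTER = 190.0
_G_WIDTH = 12.0
_G_SMOOTH_SIGMA = 1.5


def _g(structural: np.ndarray) -> np.ndarray:
    sm = gaussian_filter(structural, _G_SMOOTH_SIGMA)
    return 1.0 / (1.0 + np.exp(-(sm - _G_CENTER) / _G_WIDTH))


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic cohort.

    ``class_effect`` maps each stage to the multiplicative functional-signal
    retention inside the disease regions (1.0 = no hypometabolism); it must
    be non-increasing along NC >= MCI >= AD.  ``noise_sd`` is the standard
    deviation of additive Gaussian noise on the functional image, whose
    tissue signal lives in [0, 1].
    """

    image_shape: tuple[int, ...] = (64, 64)
    n_subjects: int = 30
    n_regions: int = 12
    class_effect: dict = field(
        default_factory=lambda: {"NC": 1.0, "MCI": 0.85, "AD": 0.7}
    )
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be 2-D or 3-D")
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        if set(self.class_effect) != set(CLASSES):
            raise ValueError(f"class_effect must map exactly {CLASSES}")
        vals = [self.class_effect[c] for c in CLASSES]
        if any(not (0.0 < v <= 1.0) for v in vals):
            raise ValueError("class_effect values must lie in (0, 1]")
        if not (vals[0] >= vals[1] >= vals[2]):
            raise ValueError("class_effect must satisfy NC >= MCI >= AD")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def disease_regions(self) -> tuple[int, int]:
        """The two atlas parcels with highest label index."""
        return (self.n_regions - 1, self.n_regions)


@dataclass
class VolumePair:
    """One co-registered structural/functional pair with its masks."""

    structural: np.ndarray
    functional: np.ndarray
    brain_mask: np.ndarray
    segment_masks: dict  # {"GM": ..., "WM": ..., "CSF": ...}
    atlas: np.ndarray
    subject_id: str
    class_label: str

    def validate(self) -> None:
        shape = self.structural.shape
        vols = [self.functional, self.brain_mask, self.atlas] + list(
            self.segment_masks.values()
        )
        if any(v.shape != shape for v in vols):
            raise ValueError("all volumes must share one shape")
        if self.class_label not in CLASSES:
            raise ValueError(
                f"unknown class {self.class_label!r}; allowed: {CLASSES}"
            )
        segs = [np.asarray(self.segment_masks[k] != 0) for k in ("GM", "WM", "CSF")]
        union = segs[0] | segs[1] | segs[2]
        if not np.array_equal(union, self.brain_mask != 0):
            raise ValueError("brain_mask must equal the union of segment masks")
        for a in range(3):
            for b in range(a + 1, 3):
                if np.any(segs[a] & segs[b]):
                    raise ValueError("segment masks must be pairwise disjoint")
        if np.any((self.atlas != 0) & (self.brain_mask == 0)):
            raise ValueError("atlas labels must lie inside brain_mask")
        if np.any(self.functional[self.brain_mask == 0] != 0):
            raise ValueError("functional must be zero outside brain_mask")


def _geometry(config: PhantomConfig, subject_index: int):
    """Per-subject brain geometry: masks, shells, atlas, structural texture."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_index])
    )
    shape = config.image_shape
    center = [s / 2.0 + rng.uniform(-1.0, 1.0) for s in shape]
    radii = [0.42 * s + rng.uniform(-2.0, 2.0) for s in shape]
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    brain = r2 <= 1.0
    seg = {
        "WM": brain & (r2 <= 0.35),
        "GM": brain & (r2 > 0.35) & (r2 <= 0.75),
        "CSF": brain & (r2 > 0.75),
    }
    # wedge parcels on the first two axes, rotated per subject
    rot = rng.uniform(0.0, 2.0 * np.pi)
    theta = np.arctan2(grids[1] - center[1], grids[0] - center[0])
    frac = ((theta + rot) / (2.0 * np.pi)) % 1.0
    atlas = np.where(brain, (frac * config.n_regions).astype(np.int64) + 1, 0)
    atlas = np.clip(atlas, 0, config.n_regions)

    structural = np.zeros(shape)
    for name, mask in seg.items():
        structural[mask] = _SHELL_INTENSITY[name]
    # per-parcel intensity offsets + a smooth bias field + fine texture
    offsets = rng.uniform(-12.0, 12.0, size=config.n_regions + 1)
    offsets[0] = 0.0
    structural += offsets[atlas]
    bias = sum(
        rng.uniform(-15.0, 15.0) * (g - c) / s
        for g, c, s in zip(grids, center, shape)
    )
    texture = gaussian_filter(rng.standard_normal(shape), 1.0) * 8.0
    structural = np.clip((structural + bias + texture) * brain, 0.0, 255.0)
    return structural, brain, seg, atlas


def generate_pair(
    config: PhantomConfig, subject_index: int, class_label: str
) -> VolumePair:
    """Generate one co-registered pair, deterministic given
    ``(config.seed, subject_index, class_label)``."""
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}; allowed: {CLASSES}")
    if not (0 <= subject_index < config.n_subjects):
        raise ValueError(
            f"subject_index must lie in 0..{config.n_subjects - 1}"
        )
    structural, brain, seg, atlas = _geometry(config, subject_index)

    modulation = np.ones(config.image_shape)
    for r in config.disease_regions:
        modulation[atlas == r] = config.class_effect[class_label]
    functional = _g(structural) * modulation

    noise_rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, subject_index, 1 + CLASSES.index(class_label)]
        )
    )
    if config.noise_sd > 0:
        functional = functional + config.noise_sd * noise_rng.standard_normal(
            config.image_shape
        )
    functional = np.clip(functional, 0.0, None) * brain

    pair = VolumePair(
        structural=structural,
        functional=functional,
        brain_mask=brain.astype(np.uint8),
        segment_masks={k: v.astype(np.uint8) for k, v in seg.items()},
        atlas=atlas,
        subject_id=f"sub-{subject_index:04d}",
        class_label=class_label,
    )
    pair.validate()
    return pair


def generate_dataset(
    config: PhantomConfig, out_dir: str | Path | None = None
) -> list[VolumePair]:
    """Generate ``n_subjects`` pairs with classes balanced round-robin
    (NC, MCI, AD, NC, ...).  With ``out_dir``, volumes are written as NIfTI
    and a ``manifest.csv`` records ids, classes, disease regions and paths.
    """
    pairs = [
        generate_pair(config, i, CLASSES[i % len(CLASSES)])
        for i in range(config.n_subjects)
    ]
    if out_dir is not None:
        from .io import write_volume

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for pair in pairs:
            paths = {}
            for key, vol in [
                ("structural", pair.structural),
                ("functional", pair.functional),
                ("mask", pair.brain_mask),
                ("atlas", pair.atlas),
                ("gm", pair.segment_masks["GM"]),
                ("wm", pair.segment_masks["WM"]),
                ("csf", pair.segment_masks["CSF"]),
            ]:
                p = out / f"{pair.subject_id}_{key}.nii"
                write_volume(p, vol)
                paths[key] = str(p)
            rows.append(
                {
                    "subject_id": pair.subject_id,
                    "class": pair.class_label,
                    "structural_path": paths["structural"],
                    "functional_path": paths["functional"],
                    "mask_path": paths["mask"],
                    "atlas_path": paths["atlas"],
                    "gm_path": paths["gm"],
                    "wm_path": paths["wm"],
                    "csf_path": paths["csf"],
                    "disease_regions": " ".join(map(str, config.disease_regions)),
                }
            )
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    return pairs
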