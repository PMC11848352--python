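"""Image-similarity criteria for synthesized-vs-true functional volumes.

Five criteria — MAE, MSE, zero-normalized cross correlation (ZNCC), the
structural similarity index (SSIM), and peak signal-to-noise ratio (PSNR) —
computed after both images are affinely normalized to [0, 1] so comparisons
share one scale.  SSIM here is the single global-statistics form

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)),

with c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03 and L = 1 after
normalization (population moments, matching the 1/n convention of the ZNCC
formula).  A locally windowed SSIM (scikit-image) is available behind a
flag for users who prefer the conventional sliding-window variant.  A third
stabilizer c3 = c2/2 exists in the usual three-term SSIM decomposition but
is not used by the combined formula; it is kept as a documented constant.

PSNR at MSE = 0 is reported as ``math.inf`` (a documented sentinel, not an
error); ZNCC on a constant image is undefined and flagged rather than
raised so the remaining criteria still come back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["K1", "K2", "MetricsReport", "normalize01", "compare"]

K1 = 0.01
K2 = 0.03


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    mse: float
    zncc: float  # nan when undefined (see zncc_defined)
    ssim: float
    psnr: float  # math.inf when mse == 0
    n_voxels: int
    L: float = 1.0
    zncc_defined: bool = True

    @property
    def c1(self) -> float:
        return (K1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (K2 * self.L) ** 2

    @property
    def c3(self) -> float:
        # defined alongside c1/c2 in the three-term SSIM decomposition;
        # unused by the combined formula computed here
        return self.c2 / 2.0

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mse": self.mse,
            "zncc": self.zncc,
            "ssim": self.ssim,
            "psnr": self.psnr,
            "n_voxels": self.n_voxels,
        }


def normalize01(x: np.ndarray) -> np.ndarray:
    """Affinely map a volume to [0, 1] using its own min/max."""
    x = np.asarray(x, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("cannot normalize a constant volume (max == min)")
    return (x - lo) / (hi - lo)


def _global_ssim(x: np.ndarray, y: np.ndarray, L: float = 1.0) -> float:
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    c1, c2 = (K1 * L) ** 2, (K2 * L) ** 2
    return float(
        (2 * mu_x * mu_y + c1)
        * (2 * cov + c2)
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def compare(
    x: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    normalize: bool = True,
    windowed_ssim: bool = False,
) -> MetricsReport:
    """All five criteria between a reference ``x`` and a comparison ``y``.

    With ``mask``, the normalization and every moment range over in-mask
    voxels only.  ``windowed_ssim`` swaps the global-statistics SSIM for
    scikit-image's sliding-window SSIM (whole-grid; ignores the mask).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    windowed = None
    if windowed_ssim:
        from skimage.metrics import structural_similarity

        xs, ys = (normalize01(x), normalize01(y)) if normalize else (x, y)
        windowed = float(structural_similarity(xs, ys, data_range=1.0))
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != x.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {x.shape}")
        x, y = x[mask != 0], y[mask != 0]
    x, y = x.ravel(), y.ravel()
    if normalize:
        x, y = normalize01(x), normalize01(y)

    n = x.size
    diff = y - x
    mae = float(np.abs(diff).mean())
    mse = float((diff**2).mean())
    sd_x, sd_y = float(x.std()), float(y.std())
    if sd_x > 0 and sd_y > 0:
        zncc = float(((x - x.mean()) * (y - y.mean())).mean() / (sd_x * sd_y))
        zncc_defined = True
    else:
        zncc, zncc_defined = math.nan, False
    ssim = windowed if windowed is not None else _global_ssim(x, y)
    psnr = math.inf if mse == 0.0 else float(10.0 * np.log10(1.0 / mse))
    return MetricsReport(
        mae=mae,
        mse=mse,
        zncc=zncc,
        ssim=ssim,
        psnr=psnr,
        n_voxels=n,
        zncc_defined=zncc_defined,
    )
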