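"""Volume and checkpoint I/O.

Volumes travel as NIfTI (via nibabel), with the affine preserved for
round-trips; model checkpoints are a single ``.npz`` holding every
parameter array plus a JSON header of architecture hyperparameters and the
noise schedule, so a checkpoint is self-describing for sampling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .model import EmbeddingConfig, NoisePredictor
from .schedule import NoiseSchedule

__all__ = [
    "read_volume",
    "write_volume",
    "save_checkpoint",
    "load_checkpoint",
]


def read_volume(path, expected_ndim: int | None = None):
    """Read a NIfTI volume; returns ``(data, affine)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unparseable file
        raise ValueError(f"cannot read volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data) if data.ndim > 3 and 1 in data.shape else data
    if expected_ndim is not None and data.ndim != expected_ndim:
        raise ValueError(
            f"{path}: expected a {expected_ndim}-D volume, got {data.ndim}-D "
            f"shape {data.shape}"
        )
    return data, np.asarray(img.affine)


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    data = np.asarray(data)
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    nib.save(img, str(path))


def save_checkpoint(
    path, model: NoisePredictor, schedule: NoiseSchedule
) -> None:
    params = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    header = {
        "model": model.hyperparams(),
        "schedule": {
            "betas": schedule.betas.tolist(),
            "sample_steps": schedule.sample_steps.tolist(),
        },
    }
    np.savez(path, header=np.array(json.dumps(header)), **params)


def load_checkpoint(path):
    """Rebuild ``(model, schedule)`` from a checkpoint file."""
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        hp = header["model"]
        model = NoisePredictor(
            depth=hp["depth"],
            base_width=hp["base_width"],
            ndim=hp["ndim"],
            emb_config=EmbeddingConfig(dim=hp["emb_dim"], mp=hp["emb_mp"]),
            seed=hp["seed"],
            parametrization=hp.get("parametrization", "x0"),
        )
        for i, p in enumerate(model.params()):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p.value[...] = stored
        schedule = NoiseSchedule(
            betas=np.array(header["schedule"]["betas"]),
            sample_steps=np.array(header["schedule"]["sample_steps"]),
        )
        model.bind_schedule(schedule)
    return model, schedule
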