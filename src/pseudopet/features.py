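"""Atlas-region feature extraction.

Scalar features per atlas parcel, restricted to one tissue segment:
structural volumes use a ``count_nonzero`` mode (non-zero voxels per
region, a proxy for remaining tissue / atrophy), functional volumes use a
``sum`` mode (total regional signal, a proxy for metabolic activity).  Any
integer-labelled parcellation works — the phantom wedge atlas at desk
scale, or a real atlas volume (e.g. AAL3) supplied by the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MODES", "FeatureVector", "extract_features", "pair_feature_table"]

MODES = ("count_nonzero", "sum")

#: Extraction mode conventional for each modality kind.
MODE_FOR_MODALITY = {
    "structural": "count_nonzero",
    "functional": "sum",
    "functional_synth": "sum",
}


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray  # one entry per region, region-label order
    regions: tuple  # the atlas labels the entries correspond to
    modality: str
    segment: str
    subject_id: str
    extraction_mode: str


def extract_features(
    volume: np.ndarray,
    atlas: np.ndarray,
    segment_mask: np.ndarray,
    mode: str,
    regions: tuple | None = None,
    modality: str = "",
    segment: str = "",
    subject_id: str = "",
) -> FeatureVector:
    """Per-region scalar features of ``volume`` within one tissue segment.

    ``regions`` fixes the region list (features of regions absent from the
    atlas are 0, with a warning); by default the distinct nonzero atlas
    labels are used.
    """
    volume = np.asarray(volume)
    atlas = np.asarray(atlas)
    segment_mask = np.asarray(segment_mask)
    if not (volume.shape == atlas.shape == segment_mask.shape):
        raise ValueError(
            f"shape mismatch: volume {volume.shape}, atlas {atlas.shape}, "
            f"segment {segment_mask.shape}"
        )
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    present = np.unique(atlas[atlas != 0])
    if regions is None:
        regions = tuple(int(r) for r in present)
    else:
        missing = sorted(set(regions) - set(int(r) for r in present))
        if missing:
            warnings.warn(
                f"atlas regions {missing} absent; their features are 0",
                stacklevel=2,
            )
    sel = segment_mask != 0
    labels = atlas[sel].ravel()
    n_bins = (max(regions) if regions else 0) + 1
    if mode == "count_nonzero":
        weights = (volume[sel].ravel() != 0).astype(np.float64)
    else:
        weights = volume[sel].ravel().astype(np.float64)
    binned = np.bincount(labels, weights=weights, minlength=n_bins)
    values = np.array([binned[r] for r in regions])
    return FeatureVector(
        values=values,
        regions=tuple(regions),
        modality=modality,
        segment=segment,
        subject_id=subject_id,
        extraction_mode=mode,
    )


def pair_feature_table(
    volumes: dict,
    atlas: np.ndarray,
    segment_masks: dict,
    subject_id: str = "",
    regions: tuple | None = None,
) -> dict:
    """Features for every (modality, segment) branch of one subject.

    ``volumes`` maps modality name -> volume; the extraction mode follows
    the modality kind (structural counts, functional-like sums).  Synthetic
    functional views reuse the structural image's segment masks — the
    synthesized volume has no segmentation of its own.
    """
    out = {}
    for modality, vol in volumes.items():
        kind = "structural" if modality.startswith("structural") else "functional"
        mode = MODE_FOR_MODALITY[kind]
        for segment, seg_mask in segment_masks.items():
            out[(modality, segment)] = extract_features(
                vol,
                atlas,
                seg_mask,
                mode,
                regions=regions,
                modality=modality,
                segment=segment,
                subject_id=subject_id,
            )
    return out
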