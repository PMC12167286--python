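"""Paired cube/mask augmentation and OoD-mask preprocessing.

The diffusion model generalizes from a small labeled set with a geometric
augmentation pipeline: rescaling, rotation, random crop, random flipping and
label dropout. The same transform is applied to the cube (linear
interpolation) and the mask (nearest-neighbour). Pixels with no source
(rotation/rescale voids) are set to a fresh *fill label* — max legend id + 1,
guaranteed absent from the legend — in the mask, and 0 (black) in the cube.

For cross-modality conditioning, masks whose labels the synthesis model was
never trained on are preprocessed by reassigning all unknown labels to the
background class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from .errors import ConfigError
from .hsi_io import HsiCube, LabelLegend, SemanticMask, check_paired

__all__ = ["AugmentConfig", "augment_pair", "label_dropout", "reassign_ood_labels",
           "fill_label_for"]

_VOID = -1  # sentinel for unmapped pixels during resampling


@dataclass
class AugmentConfig:
    rescale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range: float = 15.0           # degrees, symmetric
    crop_size: tuple[int, int] | None = None
    flip_horizontal_p: float = 0.5
    flip_vertical_p: float = 0.0
    label_dropout_p: float = 0.0

    def __post_init__(self):
        lo, hi = self.rescale_range
        if not (0 < lo <= hi):
            raise ConfigError("rescale_range must satisfy 0 < lo <= hi")
        for p in (self.flip_horizontal_p, self.flip_vertical_p, self.label_dropout_p):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("probabilities must be in [0, 1]")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(rescale_range=(1.0, 1.0), rotation_range=0.0, crop_size=None,
                   flip_horizontal_p=0.0, flip_vertical_p=0.0, label_dropout_p=0.0)


def fill_label_for(legend: LabelLegend) -> int:
    """A label guaranteed not to collide with any legend id."""
    return max(legend.ids) + 1


def augment_pair(cube: HsiCube, mask: SemanticMask, config: AugmentConfig,
                 seed: int) -> tuple[HsiCube, SemanticMask]:
    """Apply one random geometric transform identically to a cube/mask pair."""
    check_paired(cube, mask)
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    fill = fill_label_for(mask.legend)

    scale = float(rng.uniform(*config.rescale_range))
    angle = float(rng.uniform(-config.rotation_range, config.rotation_range))
    flip_h = rng.random() < config.flip_horizontal_p
    flip_v = rng.random() < config.flip_vertical_p

    data = cube.data
    labels = mask.labels
    if flip_h:
        data, labels = data[:, ::-1], labels[:, ::-1]
    if flip_v:
        data, labels = data[::-1, :], labels[::-1, :]

    if scale != 1.0 or angle != 0.0:
        theta = np.deg2rad(angle)
        # output->input mapping: rotate by -theta and divide by scale, about center
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]]) / scale
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - rot @ center
        mat3 = np.eye(3)
        mat3[:2, :2] = rot
        off3 = np.array([offset[0], offset[1], 0.0])
        data = affine_transform(data, mat3, offset=off3, order=1, cval=0.0,
                                mode="constant")
        labels = affine_transform(labels, rot, offset=offset, order=0,
                                  cval=_VOID, mode="constant")
        data = np.clip(data, 0.0, None)

    if config.crop_size is not None:
        ch, cw = config.crop_size
        if ch > labels.shape[0] or cw > labels.shape[1]:
            raise ConfigError("crop_size exceeds image dims")
        y0 = int(rng.integers(0, labels.shape[0] - ch + 1))
        x0 = int(rng.integers(0, labels.shape[1] - cw + 1))
        data = data[y0 : y0 + ch, x0 : x0 + cw]
        labels = labels[y0 : y0 + ch, x0 : x0 + cw]

    labels = np.where(labels == _VOID, fill, labels).astype(np.int64)

    if config.label_dropout_p > 0:
        labels = _dropout_labels(labels, mask.legend, config.label_dropout_p,
                                 fill, rng)

    out_cube = HsiCube(data=np.ascontiguousarray(data, dtype=np.float32),
                       wavelengths=cube.wavelengths,
                       subject_id=cube.subject_id, camera_id=cube.camera_id)
    out_mask = SemanticMask(labels=np.ascontiguousarray(labels),
                            legend=mask.legend, fill_label=fill)
    return out_cube, out_mask


def _dropout_labels(labels: np.ndarray, legend: LabelLegend, p: float,
                    fill: int, rng: np.random.Generator) -> np.ndarray:
    out = labels.copy()
    present = [int(c) for c in np.unique(labels)
               if c != legend.background_id and c != fill and c in legend]
    for cls in present:
        if rng.random() < p:
            out[out == cls] = fill
    return out


def label_dropout(mask: SemanticMask, p: float, seed: int) -> SemanticMask:
    """Drop whole non-background class regions independently with prob ``p``.

    The cited technique operates on semantic classes; dropping regions (not
    random pixels) keeps the mask a plausible segmentation. Dropped regions
    take the fill label.
    """
    if not (0.0 <= p <= 1.0):
        raise ConfigError("p must be in [0, 1]")
    fill = mask.fill_label if mask.fill_label is not None else fill_label_for(mask.legend)
    rng = np.random.default_rng(seed)
    labels = _dropout_labels(mask.labels, mask.legend, p, fill, rng)
    return SemanticMask(labels=labels, legend=mask.legend, fill_label=fill)


def reassign_ood_labels(mask: SemanticMask, known_legend: LabelLegend) -> SemanticMask:
    """Map every label absent from ``known_legend`` to its background id.

    This is how segmentation masks from other modalities (or with classes
    unseen in training) are made usable as conditioning; the operation is
    idempotent.
    """
    labels = mask.labels.copy()
    known = set(known_legend.ids)
    unknown = ~np.isin(labels, sorted(known))
    labels[unknown] = known_legend.background_id
    return SemanticMask(labels=labels, legend=known_legend, fill_label=None)
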