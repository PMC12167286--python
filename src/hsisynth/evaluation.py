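"""Validation metrics for synthesis and segmentation.

Covers the quantitative validation pillars: spectral consistency of
generated images (l1-normalized class spectra, hierarchically aggregated),
segmentation quality (Dice similarity coefficient, normalized surface
distance), hierarchical per-subject aggregation, subject-level bootstrap
confidence intervals on model differences, and an RGB reconstruction of
hyperspectral cubes for visual inspection.

Conventions fixed here (metric values are meaningless across differing
conventions, so they are spelled out):

* NSD boundary: a region pixel with at least one 8-connected neighbour
  outside the region; image-border pixels of a region count as boundary.
  Distances are Euclidean in pixels.
* Undefined metric records (class absent from both masks / empty spectra)
  are marked NaN and *excluded* from aggregation, never zero-filled.
* Bootstrap CIs are percentile intervals over subject resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .errors import ConfigError, ValidationError
from .hsi_io import HsiCube, SemanticMask

__all__ = [
    "MetricRecord", "EvalConfig", "ClassSpectrum",
    "l1_normalize", "class_spectrum", "spectral_agreement",
    "dsc", "nsd", "segmentation_records",
    "hierarchical_aggregate", "bootstrap_ci_difference", "rgb_reconstruction",
]

RECORD_COLUMNS = ["image_id", "subject_id", "class_id", "metric", "value"]


@dataclass
class MetricRecord:
    image_id: str
    subject_id: str
    class_id: int
    metric: str  # "DSC" or "NSD"
    value: float  # NaN marks an undefined record

    def __post_init__(self):
        if np.isfinite(self.value) and not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"metric value {self.value} outside [0, 1]")


@dataclass
class EvalConfig:
    nsd_tolerance: float = 2.0   # pixels, at phantom scale
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.nsd_tolerance < 0:
            raise ConfigError("nsd_tolerance must be >= 0")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level must be in (0, 1)")


def records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

def l1_normalize(spectrum: np.ndarray) -> np.ndarray | None:
    """Divide by the sum of absolute band values; None for all-zero input."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    total = np.sum(np.abs(spectrum))
    if total == 0:
        return None
    return spectrum / total


@dataclass
class ClassSpectrum:
    """Hierarchically aggregated l1-normalized class spectrum.

    Per image: median over the class pixels of their l1-normalized spectra.
    Per subject: mean of its image spectra. Across subjects: mean and std
    (std is zero by convention when only one subject contributes).
    """

    mean: np.ndarray
    std: np.ndarray
    per_subject: dict[str, np.ndarray]


def _image_median_spectrum(cube: HsiCube, mask: SemanticMask,
                           class_id: int) -> np.ndarray | None:
    sel = mask.labels == class_id
    if not sel.any():
        return None
    pixels = cube.data[sel].astype(np.float64)      # (n, C)
    sums = np.abs(pixels).sum(axis=1)
    ok = sums > 0
    if not ok.any():
        return None
    norm = pixels[ok] / sums[ok, None]
    return np.median(norm, axis=0)


def class_spectrum(dataset, class_id: int) -> ClassSpectrum | None:
    """Aggregate a class's normalized spectrum over a (cube, mask[, subject]) list."""
    per_subject: dict[str, list[np.ndarray]] = {}
    for item in dataset:
        cube, mask = item[0], item[1]
        subject = item[2] if len(item) > 2 else cube.subject_id
        spec = _image_median_spectrum(cube, mask, class_id)
        if spec is not None:
            per_subject.setdefault(subject, []).append(spec)
    if not per_subject:
        return None
    subj_means = {s: np.mean(np.stack(v), axis=0) for s, v in per_subject.items()}
    stack = np.stack(list(subj_means.values()))
    std = stack.std(axis=0) if len(stack) > 1 else np.zeros(stack.shape[1])
    return ClassSpectrum(mean=stack.mean(axis=0), std=std, per_subject=subj_means)


def spectral_agreement(real_dataset, synth_dataset, class_id: int) -> float | None:
    """l1 distance between the aggregated class spectra of two datasets."""
    a = class_spectrum(real_dataset, class_id)
    b = class_spectrum(synth_dataset, class_id)
    if a is None or b is None:
        return None
    return float(np.abs(a.mean - b.mean).sum())


# --------------------------------------------------------------------------
# segmentation metrics
# --------------------------------------------------------------------------

def _as_labels(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, SemanticMask) else np.asarray(mask)


def dsc(pred_mask, gt_mask, class_id: int) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P|+|G|); NaN if both empty."""
    p = _as_labels(pred_mask) == class_id
    g = _as_labels(gt_mask) == class_id
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = p.sum() + g.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def _boundary(region: np.ndarray) -> np.ndarray:
    """8-connectivity boundary; pixels touching the image border count."""
    padded = np.pad(region, 1, constant_values=False)
    interior = np.ones_like(region, dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            interior &= padded[1 + dy : 1 + dy + region.shape[0],
                               1 + dx : 1 + dx + region.shape[1]]
    return region & ~interior


def nsd(pred_mask, gt_mask, class_id: int, tolerance: float) -> float:
    """Normalized surface distance at Euclidean pixel tolerance ``tolerance``.

    Fraction of boundary pixels of prediction and ground truth lying within
    ``tolerance`` of the other boundary. NaN when both boundaries are empty.
    """
    if tolerance < 0:
        raise ConfigError("tolerance must be >= 0")
    p = _as_labels(pred_mask) == class_id
    g = _as_labels(gt_mask) == class_id
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {g.shape}")
    bp, bg = _boundary(p), _boundary(g)
    np_, ng = int(bp.sum()), int(bg.sum())
    if np_ + ng == 0:
        return float("nan")
    hits = 0
    if ng:
        dist_to_g = distance_transform_edt(~bg)
        hits += int((dist_to_g[bp] <= tolerance).sum())
    if np_:
        dist_to_p = distance_transform_edt(~bp)
        hits += int((dist_to_p[bg] <= tolerance).sum())
    # one empty boundary: all pixels of the other are misses (distance inf)
    return float(hits / (np_ + ng))


def segmentation_records(image_id: str, subject_id: str, pred_mask, gt_mask,
                         class_ids, config: EvalConfig) -> list[MetricRecord]:
    """DSC + NSD records for one image over the given classes."""
    out = []
    for cls in class_ids:
        out.append(MetricRecord(image_id, subject_id, int(cls), "DSC",
                                dsc(pred_mask, gt_mask, cls)))
        out.append(MetricRecord(image_id, subject_id, int(cls), "NSD",
                                nsd(pred_mask, gt_mask, cls, config.nsd_tolerance)))
    return out


# --------------------------------------------------------------------------
# hierarchical aggregation & bootstrap
# --------------------------------------------------------------------------

def hierarchical_aggregate(records) -> pd.DataFrame:
    """Mean over subjects of per-subject means, per (class, metric).

    Undefined (NaN) records are excluded before any averaging, so a subject
    without a defined value for a class simply does not contribute to that
    class's subject-level average.
    """
    df = records_frame(records).dropna(subset=["value"])
    if df.empty:
        return pd.DataFrame(columns=["class_id", "metric", "value"])
    subj = (df.groupby(["class_id", "metric", "subject_id"])["value"]
              .mean().reset_index())
    agg = subj.groupby(["class_id", "metric"])["value"].mean().reset_index()
    return agg


def _subject_cell_matrix(df: pd.DataFrame, subjects: list[str]) -> np.ndarray:
    """(n_subjects, n_cells) matrix of per-subject means; NaN where missing.

    Cells are (class_id, metric) pairs, ordered consistently for both inputs
    by the caller.
    """
    subj = (df.dropna(subset=["value"])
              .groupby(["class_id", "metric", "subject_id"])["value"]
              .mean().reset_index())
    pivot = subj.pivot_table(index="subject_id", columns=["class_id", "metric"],
                             values="value", dropna=False)
    pivot = pivot.reindex(subjects)
    return pivot.to_numpy(dtype=float), list(pivot.columns)


def bootstrap_ci_difference(records_a, records_b,
                            config: EvalConfig) -> tuple[float, float] | None:
    """Percentile CI on the pooled hierarchical-aggregate difference A - B.

    Subjects are resampled with replacement; per replicate the difference of
    the pooled (mean over class/metric cells) hierarchical aggregates is
    computed. Requires the same subjects in both record sets; returns None
    with a warning when fewer than two subjects are available.
    """
    df_a, df_b = records_frame(records_a), records_frame(records_b)
    subjects = sorted(set(df_a["subject_id"]) & set(df_b["subject_id"]))
    if len(subjects) < 2:
        warnings.warn("bootstrap CI undefined with fewer than 2 subjects")
        return None
    mat_a, _ = _subject_cell_matrix(df_a, subjects)
    mat_b, _ = _subject_cell_matrix(df_b, subjects)
    rng = np.random.default_rng(config.seed)
    n = len(subjects)
    idx = rng.integers(0, n, size=(config.n_bootstrap, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN resamples
        # mean over resampled subjects, then over cells -> pooled aggregate
        agg_a = np.nanmean(np.nanmean(mat_a[idx], axis=1), axis=1)
        agg_b = np.nanmean(np.nanmean(mat_b[idx], axis=1), axis=1)
    diffs = agg_a - agg_b
    alpha = 1.0 - config.ci_level
    low, high = np.nanquantile(diffs, [alpha / 2, 1.0 - alpha / 2])
    return float(low), float(high)


# --------------------------------------------------------------------------
# RGB reconstruction
# --------------------------------------------------------------------------

DEFAULT_RGB_WINDOWS = {"R": (620.0, 650.0), "G": (540.0, 570.0), "B": (500.0, 520.0)}


def rgb_reconstruction(cube: HsiCube,
                       windows: dict[str, tuple[float, float]] | None = None,
                       gamma: float = 1.0 / 2.2) -> np.ndarray:
    """Band-integration RGB rendering of a cube, values in [0, 1].

    Each channel is the mean reflectance over a wavelength window, jointly
    max-normalized, then gamma-encoded. The sensor axis starts at 500 nm, so
    the 'blue' window is a documented non-colorimetric stand-in.
    """
    windows = windows or DEFAULT_RGB_WINDOWS
    wl = cube.wavelengths
    chans = []
    for name in ("R", "G", "B"):
        lo, hi = windows[name]
        sel = (wl >= lo) & (wl <= hi)
        if not sel.any():
            raise ConfigError(
                f"window {name}=({lo}, {hi}) nm outside wavelength axis "
                f"[{wl[0]}, {wl[-1]}]"
            )
        chans.append(cube.data[:, :, sel].mean(axis=2))
    rgb = np.stack(chans, axis=-1)
    peak = rgb.max()
    if peak > 0:
        rgb = rgb / peak
    return np.power(rgb, gamma, dtype=np.float64)
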