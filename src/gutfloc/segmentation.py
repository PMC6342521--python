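"""Depth-calibrated segmentation of 3D confocal z-stacks into aggregate sizes.

Fluorescence collected deep in a scattering sample is dimmer than at the
surface, so a single global threshold cannot be applied to a raw stack.  The
procedure here (a faithful re-implementation of a FIJI/ImageJ macro workflow)
is:

1. **Anchor-slice calibration** — pick two anchor slices (the 10th and the
   10th-from-last by default), Otsu-threshold each, and record the median
   foreground intensity (per-slice "max") and a background statistic
   (1/3 mean background + 2/3 max background, the per-slice "min").  The
   depth drop-off is assumed approximately linear, so both statistics are
   interpolated (and extrapolated) linearly across all slices.
2. **Rescaling** — clip each slice to its [min, max] band and stretch it to
   the full 16-bit range.  Clipping is deliberate: aggregates are measured
   by total volume, not by resolving individual particles.
3. **3D object labeling** — a single Otsu threshold on the rescaled stack,
   connected components at 6/18/26-connectivity, voxel counts converted to
   metric volumes (µm³).
4. **Singlet normalization** — divide object volumes by the volume of a
   single particle (configured, or estimated automatically as the modal
   low-volume cluster), giving particles per aggregate N_i.  Sub-singlet
   debris is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .aggstats import AggregateTable
from .errors import CalibrationError, EstimationError, SegmentationError

__all__ = [
    "ImageStack",
    "CalibrationProfile",
    "SegmentationConfig",
    "SegmentationResult",
    "calibrate_anchor_slices",
    "rescale_stack",
    "connected_component_volumes",
    "label_aggregates",
    "singlet_volume_estimate",
    "segment_stack",
    "aggregate_table_from_stack",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ImageStack:
    """A 3D intensity volume with voxel dimensions.

    ``voxels`` is indexed (slice, row, col); ``voxel_size`` is (dz, dy, dx)
    in µm.  At least 20 slices are required so that the two anchor slices
    exist and are distinct.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if self.n_slices < 20:
            raise ValueError(f"need at least 20 slices, got {self.n_slices}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class CalibrationProfile:
    """Per-slice (max, min) intensity pair from linear anchor interpolation."""

    slice_max: np.ndarray
    slice_min: np.ndarray
    anchor_indices: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if np.any(self.slice_min >= self.slice_max):
            raise CalibrationError(
                "calibration requires min_intensity < max_intensity on every slice"
            )


@dataclass
class SegmentationConfig:
    """Free parameters of the segmentation chain.

    anchor_offset: 1-based position of the anchor slices from either end
    (10 -> the 10th slice and the 10th-from-last).  connectivity: 6, 18 or 26
    neighbours for 3D labeling.  singlet_volume: µm³, or "auto" to estimate
    from the low-volume mode.  Objects smaller than
    ``min_volume_fraction_of_singlet`` times the singlet volume are dropped
    as debris.  rounding: "nearest" (integer N_i, floored at 1) or "none"
    (keep fractional volume ratios, still floored at 1).
    """

    anchor_offset: int = 10
    connectivity: int = 26
    singlet_volume: float | str = "auto"
    min_volume_fraction_of_singlet: float = 0.25
    rounding: str = "nearest"
    exclude_border: bool = False
    min_anchor_contrast: float = 1.5

    def __post_init__(self) -> None:
        if self.anchor_offset < 1:
            raise ValueError("anchor_offset must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
        if self.rounding not in ("nearest", "none"):
            raise ValueError("rounding must be 'nearest' or 'none'")
        if isinstance(self.singlet_volume, str) and self.singlet_volume != "auto":
            raise ValueError("singlet_volume must be a volume in µm³ or 'auto'")


@dataclass
class SegmentationResult:
    """Everything the chain measured, for QC reporting."""

    table: AggregateTable
    volumes: np.ndarray
    singlet_volume: float
    threshold: float
    calibration: CalibrationProfile
    n_debris: int = 0


def _anchor_statistics(slice_: np.ndarray) -> tuple[float, float]:
    """(median foreground, 1/3 mean background + 2/3 max background) of a slice."""
    if slice_.max() == slice_.min():
        raise CalibrationError("anchor slice is uniform; Otsu thresholding impossible")
    thr = threshold_otsu(slice_)
    fg = slice_ > thr
    if not fg.any() or fg.all():
        raise CalibrationError(
            "anchor slice has no foreground/background split after Otsu"
        )
    fg_median = float(np.median(slice_[fg]))
    bg = slice_[~fg]
    bg_stat = float(np.mean(bg)) / 3.0 + 2.0 * float(np.max(bg)) / 3.0
    return fg_median, bg_stat


class NoUsableAnchorError(CalibrationError):
    """No slice near either anchor position contains usable foreground."""


def _find_anchor(stack: ImageStack, indices, min_contrast: float):
    """First anchor candidate with a genuine foreground/background split.

    An Otsu split of pure background noise yields a "foreground" median
    barely above the background statistic; such slices are skipped.
    """
    for i in indices:
        try:
            fg_median, bg_stat = _anchor_statistics(np.asarray(stack.voxels[i], dtype=float))
        except CalibrationError:
            continue
        if bg_stat <= 0 or fg_median >= min_contrast * bg_stat:
            return i, fg_median, bg_stat
    raise NoUsableAnchorError(
        f"no usable anchor among slices {indices[0]}..{indices[-1]}; "
        "the stack may contain no fluorescent objects"
    )


def calibrate_anchor_slices(stack: ImageStack, cfg: SegmentationConfig) -> CalibrationProfile:
    """Linear depth-calibration lines from two Otsu-thresholded anchor slices.

    Anchor positions are 1-based ("10th slice", "10th-from-last slice"), i.e.
    0-based indices ``offset-1`` and ``n-offset``.  If a nominal anchor slice
    happens to contain no aggregates it cannot define the calibration line,
    so the nearest usable slice towards the stack centre is used instead.
    Per-slice values outside the anchors are linear extrapolations.
    """
    n = stack.n_slices
    i0 = cfg.anchor_offset - 1
    i1 = n - cfg.anchor_offset
    if not (0 <= i0 < i1 < n):
        raise CalibrationError(
            f"anchor_offset={cfg.anchor_offset} does not give two distinct "
            f"anchor slices in a {n}-slice stack"
        )
    mid = (i0 + i1) // 2
    i0, max0, min0 = _find_anchor(stack, range(i0, mid), cfg.min_anchor_contrast)
    i1, max1, min1 = _find_anchor(stack, range(i1, mid, -1), cfg.min_anchor_contrast)
    s = np.arange(n, dtype=float)
    t = (s - i0) / (i1 - i0)
    return CalibrationProfile(
        slice_max=max0 + t * (max1 - max0),
        slice_min=min0 + t * (min1 - min0),
        anchor_indices=(i0, i1),
    )


def rescale_stack(stack: ImageStack, cal: CalibrationProfile) -> ImageStack:
    """Clip each slice to its calibration band and stretch to 16-bit range.

    Pixels at or below the per-slice min map to 0, at or above the max to
    65535.  The mapping is monotone within the band, so pixel rank order is
    preserved; out-of-band values are deliberately clipped.
    """
    if cal.slice_max.shape[0] != stack.n_slices:
        raise SegmentationError("rescale: calibration does not cover every slice")
    v = np.asarray(stack.voxels, dtype=float)
    lo = cal.slice_min[:, None, None]
    hi = cal.slice_max[:, None, None]
    out = (np.clip(v, lo, hi) - lo) / (hi - lo) * 65535.0
    return ImageStack(np.round(out).astype(np.uint16), stack.voxel_size)


def connected_component_volumes(binary: np.ndarray, connectivity: int = 26):
    """Voxel counts of 3D connected components of a boolean array.

    Returns (labels, counts) where ``labels`` is the labeled array and
    ``counts[k]`` the voxel count of component k+1.
    """
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels, np.empty(0, dtype=np.int64)
    counts = np.bincount(labels.ravel())[1:]
    return labels, counts


def label_aggregates(stack: ImageStack, cfg: SegmentationConfig) -> np.ndarray:
    """Object volumes (µm³) of a rescaled stack.

    Applies one global Otsu threshold to the whole stack, labels connected
    components at the configured connectivity, and converts voxel counts to
    metric volumes.  Returns an empty array when nothing is above threshold.
    """
    v = stack.voxels
    if v.max() == v.min():
        return np.empty(0)
    thr = threshold_otsu(np.asarray(v))
    binary = v > thr
    labels, counts = connected_component_volumes(binary, cfg.connectivity)
    if cfg.exclude_border and counts.size:
        border_labels = np.unique(np.concatenate([
            labels[0].ravel(), labels[-1].ravel(),
            labels[:, 0].ravel(), labels[:, -1].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
        ]))
        keep = np.ones(counts.size + 1, dtype=bool)
        keep[border_labels] = False
        counts = counts[keep[1:]]
    return counts * stack.voxel_volume


def singlet_volume_estimate(volumes: np.ndarray, cfg: SegmentationConfig) -> float:
    """Volume of a single particle, in µm³.

    An explicitly configured value is returned unchanged.  In "auto" mode the
    estimate automates the manual identify-ten-singlets step: object volumes
    are binned on a log axis, the leftmost well-populated local maximum is
    taken as the singlet mode, and the estimate is the median volume within
    that mode and its neighbouring bins.
    """
    if not isinstance(cfg.singlet_volume, str):
        if cfg.singlet_volume <= 0:
            raise ValueError("singlet_volume must be > 0")
        return float(cfg.singlet_volume)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size < 10:
        raise EstimationError(
            f"only {volumes.size} objects; automatic singlet estimation needs "
            ">= 10 — set singlet_volume explicitly"
        )
    logv = np.log(volumes)
    width = 0.2  # ~22% volume bins
    lo = logv.min() - width / 2
    nbins = max(1, int(np.ceil((logv.max() - lo) / width)))
    edges = lo + width * np.arange(nbins + 1)
    counts, _ = np.histogram(logv, bins=edges)
    floor = max(3, int(0.03 * volumes.size))
    padded = np.concatenate(([0], counts, [0]))
    peak = None
    for i in range(counts.size):
        if counts[i] >= floor and padded[i] <= counts[i] >= padded[i + 2]:
            peak = i
            break
    if peak is None:
        peak = int(np.argmax(counts))
    sel = (logv >= edges[max(peak - 1, 0)]) & (logv < edges[min(peak + 2, nbins)])
    return float(np.median(volumes[sel]))


def segment_stack(stack: ImageStack, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Full chain: calibrate -> rescale -> label -> singlet-normalize.

    Returns a SegmentationResult whose table holds N_i = volume_i / singlet
    volume (rounded per config, floored at 1); objects below the debris cut
    are excluded.  A background-only stack yields an empty table and a
    warning.
    """
    cfg = cfg or SegmentationConfig()
    try:
        cal = calibrate_anchor_slices(stack, cfg)
    except NoUsableAnchorError as exc:
        # nothing fluorescent near either anchor: background-only stack
        warnings.warn(f"{exc}; returning an empty table", stacklevel=2)
        n = stack.n_slices
        cal = CalibrationProfile(np.ones(n), np.zeros(n), (0, 0))
        return SegmentationResult(
            table=AggregateTable(np.empty(0)), volumes=np.empty(0),
            singlet_volume=float("nan"), threshold=float("nan"), calibration=cal,
        )
    except CalibrationError as exc:
        raise SegmentationError(f"calibration: {exc}") from exc
    rescaled = rescale_stack(stack, cal)
    volumes = label_aggregates(rescaled, cfg)
    thr = float(threshold_otsu(np.asarray(rescaled.voxels))) if volumes.size else float("nan")
    if volumes.size == 0:
        warnings.warn("no objects found above threshold; returning an empty table",
                      stacklevel=2)
        return SegmentationResult(
            table=AggregateTable(np.empty(0)), volumes=volumes,
            singlet_volume=float("nan"), threshold=thr, calibration=cal,
        )
    try:
        singlet = singlet_volume_estimate(volumes, cfg)
    except EstimationError as exc:
        raise SegmentationError(f"singlet estimation: {exc}") from exc
    keep = volumes >= cfg.min_volume_fraction_of_singlet * singlet
    n_debris = int((~keep).sum())
    sizes = volumes[keep] / singlet
    if cfg.rounding == "nearest":
        sizes = np.round(sizes)
    sizes = np.maximum(sizes, 1.0)
    return SegmentationResult(
        table=AggregateTable(sizes), volumes=volumes, singlet_volume=singlet,
        threshold=thr, calibration=cal, n_debris=n_debris,
    )


def aggregate_table_from_stack(stack: ImageStack,
                               cfg: SegmentationConfig | None = None) -> AggregateTable:
    """Convenience wrapper returning only the AggregateTable."""
    return segment_stack(stack, cfg).table
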