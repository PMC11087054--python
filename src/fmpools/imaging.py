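"""Minimal image-to-trace extraction: punctum detection and ROI averaging.

A deliberately simple stand-in for automated ROI detection on fluorescence
time-lapse stacks of presynaptic punctae: blob detection (Laplacian of
Gaussian) on the mean image with an intensity threshold, square ROIs, and a
designated background region whose mean feeds trace normalization.  Synthetic
stacks are drift-free, so no registration is performed (a real pipeline would
align frames first).

Pixel coordinates are 0-based; ROI windows are half-open in both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import blob_log

from .destain import ROITrace

__all__ = ["ROIDefinition", "detect_punctae", "extract_traces",
           "background_region_trace"]


@dataclass(frozen=True)
class ROIDefinition:
    """Square region of interest centered on a punctum.

    ``center`` is (row, col) in 0-based pixels; the ROI spans
    ``[c - half_width, c + half_width + 1)`` in each axis.  ``background``
    is a rectangle ``(row0, col0, row1, col1)`` (half-open) whose mean
    intensity serves as the background signal.
    """

    center: tuple[float, float]
    half_width: int = 3
    background: tuple[int, int, int, int] | None = None

    def slices(self) -> tuple[slice, slice]:
        r, c = (int(round(v)) for v in self.center)
        h = self.half_width
        return slice(r - h, r + h + 1), slice(c - h, c + h + 1)

    def inside(self, shape: tuple[int, int]) -> bool:
        sr, sc = self.slices()
        return sr.start >= 0 and sc.start >= 0 \
            and sr.stop <= shape[0] and sc.stop <= shape[1]


def detect_punctae(
    mean_image: np.ndarray,
    min_sigma: float = 1.0,
    max_sigma: float = 4.0,
    threshold_rel: float = 0.1,
    half_width: int = 3,
    max_size_px: float | None = None,
    background: tuple[int, int, int, int] | None = None,
) -> list[ROIDefinition]:
    """Detect fluorescent punctae on a 2-D mean image.

    Laplacian-of-Gaussian blob detection after background flattening; the
    threshold is relative to the image's dynamic range, so detection is
    insensitive to overall brightness.  ``max_size_px`` drops blobs whose
    estimated diameter exceeds it (the low-density single-synapse mode,
    e.g. 1.5 um at a configured um/px scale).  Deterministic.
    """
    img = np.asarray(mean_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("mean_image must be 2-D")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return []
    norm = (img - lo) / (hi - lo)
    blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=8, threshold=threshold_rel)
    rois = []
    for r, c, sigma in blobs:
        if max_size_px is not None and 2 * sigma * np.sqrt(2) > max_size_px:
            continue
        roi = ROIDefinition(center=(float(r), float(c)),
                            half_width=half_width, background=background)
        if roi.inside(img.shape):
            rois.append(roi)
    return rois


def background_region_trace(stack: np.ndarray,
                            region: tuple[int, int, int, int]) -> np.ndarray:
    """Per-frame mean intensity of the designated background rectangle."""
    r0, c0, r1, c1 = region
    return stack[:, r0:r1, c0:c1].mean(axis=(1, 2))


def extract_traces(
    stack: np.ndarray,
    rois: list[ROIDefinition],
    times: np.ndarray | None = None,
    frame_period_s: float = 4.0,
    background: tuple[int, int, int, int] | None = None,
    prep_id: str = "prep0",
) -> list[ROITrace]:
    """Per-frame mean ROI intensities as raw traces.

    Extraction is linear in the stack.  The background comes from each ROI's
    own region or the shared ``background`` rectangle; without either, the
    per-frame image median is used.  Output feeds ``normalize_trace``.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    t = np.asarray(times, dtype=float) if times is not None \
        else np.arange(n) * frame_period_s
    traces = []
    shared_bg = background_region_trace(stack, background) \
        if background is not None else None
    for i, roi in enumerate(rois):
        if not roi.inside(stack.shape[1:]):
            raise ValueError(f"ROI {i} outside frame")
        sr, sc = roi.slices()
        F = stack[:, sr, sc].mean(axis=(1, 2))
        if roi.background is not None:
            bg = background_region_trace(stack, roi.background)
        elif shared_bg is not None:
            bg = shared_bg
        else:
            bg = np.median(stack, axis=(1, 2))
        traces.append(ROITrace(times=t, F_raw=F, background=bg,
                               prep_id=prep_id, roi_id=f"roi{i}"))
    return traces
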