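"""Per-frame cell detection from fluorescence and transmitted-light channels.

The pipeline mirrors a denoise → threshold → intersect design:

1. ``denoise``: a 3×3 median filter removes shot noise and a Gaussian
   low-pass (kernel 10% of the image side) estimates the slow-varying
   background, which is subtracted.
2. ``segment_fluorescence``: per-frame Otsu threshold on the pixelwise max of
   the two FUCCI channels (so cells stay detectable through the red↔green
   handoff), then 8-connected components with a minimum-size filter.
3. ``segment_phase``: transmitted-light foreground = pixels more than one
   standard deviation from the frame median, unioned with an Otsu-thresholded
   Sobel gradient image, holes filled.
4. ``combine``: fluorescence components intersected with the phase mask;
   components losing more than half their area are dropped.  Mean channel
   intensities are measured on the *raw* fluorescence frames so downstream
   classification is not distorted by background subtraction.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .errors import InputError

DETECTION_COLUMNS = ["frame", "label_id", "x_px", "y_px", "area_px",
                     "radius_px", "mean_red", "mean_green"]


def denoise(image: np.ndarray, kernel_frac: float = 0.10) -> np.ndarray:
    """Median-filter then subtract a Gaussian background estimate, clip at 0."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 10:
        raise InputError("denoise expects a single-channel 2D image, >= 10x10 px")
    kernel = kernel_frac * min(img.shape)
    sigma = kernel / 4.0  # Gaussian sd chosen so ±2σ spans the stated kernel
    med = ndimage.median_filter(img, size=3)
    background = ndimage.gaussian_filter(img, sigma=sigma)
    return np.clip(med - background, 0.0, None)


def segment_fluorescence(red_denoised: np.ndarray, green_denoised: np.ndarray,
                         min_size: int = 30) -> np.ndarray:
    """Label mask from the two denoised FUCCI channels (Otsu on their max)."""
    if red_denoised.shape != green_denoised.shape:
        raise InputError("channel shapes differ")
    combined = np.maximum(red_denoised, green_denoised)
    if not np.any(combined > 0):
        return np.zeros(combined.shape, dtype=np.int32)
    thr = filters.threshold_otsu(combined)
    fg = combined > thr
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_size)
        fg &= ~np.isin(labels, small[small > 0])
        labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    return labels.astype(np.int32)


def intensity_foreground(trans: np.ndarray) -> np.ndarray:
    """Pixels more than one frame-sd away from the frame median."""
    img = np.asarray(trans, dtype=float)
    sd = img.std()
    if sd == 0:
        return np.zeros(img.shape, dtype=bool)
    return np.abs(img - np.median(img)) > sd


def segment_phase(trans: np.ndarray) -> np.ndarray:
    """Foreground mask from a transmitted-light frame.

    Union of the intensity rule (> 1 sd from the median background level) and
    an Otsu threshold on the Sobel gradient magnitude, with holes filled.
    Returns an all-false mask for a constant frame.
    """
    img = np.asarray(trans, dtype=float)
    fg1 = intensity_foreground(img)
    if img.std() == 0:
        return fg1
    grad = filters.sobel(img)
    thr = filters.threshold_otsu(grad)
    fg2 = grad > thr
    return ndimage.binary_fill_holes(fg1 | fg2)


def combine(fluor_labels: np.ndarray, phase_mask: Optional[np.ndarray],
            raw_red: np.ndarray, raw_green: np.ndarray,
            frame_index: int = 0, min_size: int = 30,
            max_loss: float = 0.5) -> Tuple[np.ndarray, pd.DataFrame]:
    """Intersect fluorescence components with the phase mask; measure cells.

    A fluorescence component keeps only its pixels inside ``phase_mask`` and
    is dropped entirely if that removes more than ``max_loss`` of its area
    (or shrinks it below ``min_size``).  Passing ``phase_mask=None`` skips the
    intersection (fluorescence-only data).  Returns the final label mask and
    a detections table with centroids, areas, equivalent radii and mean raw
    channel intensities.
    """
    if phase_mask is not None and phase_mask.shape != fluor_labels.shape:
        raise InputError("mask shapes differ")
    labels = fluor_labels.copy()
    if phase_mask is not None:
        for region in measure.regionprops(fluor_labels):
            inside = phase_mask[tuple(region.coords.T)]
            kept = int(inside.sum())
            if kept < (1.0 - max_loss) * region.area or kept < min_size:
                labels[fluor_labels == region.label] = 0
            else:
                drop = region.coords[~inside]
                labels[drop[:, 0], drop[:, 1]] = 0
    # relabel to contiguous positive integers; the intersection can split a
    # component, so re-apply the minimum size to the fragments
    relabeled, n = ndimage.label(labels > 0, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = np.bincount(relabeled.ravel())
        small = np.flatnonzero(sizes < min_size)
        keep = relabeled > 0
        keep &= ~np.isin(relabeled, small[small > 0])
        relabeled, _ = ndimage.label(keep, structure=np.ones((3, 3), dtype=int))
    rows = []
    for region in measure.regionprops(relabeled):
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        rows.append({
            "frame": frame_index,
            "label_id": region.label,
            "x_px": region.centroid[1],
            "y_px": region.centroid[0],
            "area_px": float(region.area),
            "radius_px": float(np.sqrt(region.area / np.pi)),
            "mean_red": float(np.mean(raw_red[rr, cc])),
            "mean_green": float(np.mean(raw_green[rr, cc])),
        })
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    return relabeled.astype(np.int32), df


def segment_frame(raw_red: np.ndarray, raw_green: np.ndarray,
                  raw_trans: Optional[np.ndarray] = None,
                  frame_index: int = 0, min_size: int = 30):
    """Full single-frame pipeline: denoise → threshold → intersect → measure."""
    red_d = denoise(raw_red)
    green_d = denoise(raw_green)
    fluor = segment_fluorescence(red_d, green_d, min_size=min_size)
    phase = segment_phase(raw_trans) if raw_trans is not None else None
    return combine(fluor, phase, raw_red, raw_green,
                   frame_index=frame_index, min_size=min_size)


def segment_movie(movie, use_phase_channel: bool = True, min_size: int = 30):
    """Segment every frame of a MovieStack.

    Returns (label_stack, detections DataFrame across frames).
    """
    masks = np.zeros(movie.red.shape, dtype=np.int32)
    tables = []
    for t in range(movie.n_frames):
        trans = movie.trans[t] if use_phase_channel else None
        labels, df = segment_frame(movie.red[t], movie.green[t], trans,
                                   frame_index=t, min_size=min_size)
        masks[t] = labels
        tables.append(df)
    detections = pd.concat(tables, ignore_index=True)
    return masks, detections
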