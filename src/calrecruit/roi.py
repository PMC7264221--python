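"""ROI detection on the time-averaged movie and trace extraction.

Cell bodies are detected on the pixelwise time average of the recording
(transients are brief, so somata stand out as bright blobs), thresholded
with Otsu's criterion, and split into 8-connected components filtered by
area. Traces are the spatial mean over each ROI's pixels, frame by frame.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import clear_border

from .core import RAW, FluorescenceMovie, RoiMask, Trace
from .errors import EmptyInputError, ParameterError, RoiBoundsError


def time_average(movie: FluorescenceMovie) -> np.ndarray:
    """Pixelwise arithmetic mean over all frames."""
    if movie.n_frames < 1:
        raise EmptyInputError("cannot average an empty movie")
    return movie.frames.mean(axis=0)


def detect_rois(
    avg_image: np.ndarray,
    min_area_px: int = 20,
    max_area_px: int = 600,
    remove_border: bool = False,
) -> list[RoiMask]:
    """Detect cell bodies as bright connected components of the average image.

    Foreground is ``avg_image > Otsu threshold``; 8-connected components with
    area in ``[min_area_px, max_area_px]`` become ROIs, ids assigned in raster
    order of their centroids. A uniform image yields no ROIs (with a warning).
    """
    if min_area_px > max_area_px:
        raise ParameterError(f"min_area_px {min_area_px} > max_area_px {max_area_px}")
    avg = np.asarray(avg_image, dtype=float)
    if avg.ndim != 2:
        raise ParameterError("avg_image must be 2-D")
    if np.ptp(avg) == 0:
        warnings.warn("uniform image: no threshold separates foreground; 0 ROIs")
        return []
    thr = threshold_otsu(avg)
    fg = avg > thr
    if remove_border:
        fg = clear_border(fg)
    lbl = cc_label(fg, connectivity=2)
    regions = [r for r in regionprops(lbl) if min_area_px <= r.area <= max_area_px]
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    return [RoiMask(i, np.asarray(r.coords)) for i, r in enumerate(regions)]


def extract_traces(movie: FluorescenceMovie, rois: Sequence[RoiMask]) -> list[Trace]:
    """Per-ROI raw traces: spatial mean over the ROI's pixels in every frame."""
    h, w = movie.frame_shape
    traces = []
    for roi in rois:
        px = roi.pixels
        if (px[:, 0].min() < 0 or px[:, 1].min() < 0
                or px[:, 0].max() >= h or px[:, 1].max() >= w):
            raise RoiBoundsError(f"ROI {roi.id} has pixels outside the {h}x{w} frame")
        vals = movie.frames[:, px[:, 0], px[:, 1]].mean(axis=1)
        traces.append(Trace(vals, movie.frame_rate_hz, RAW, roi.id))
    return traces


def label_image(rois: Sequence[RoiMask], frame_shape: tuple[int, int]) -> np.ndarray:
    """Label image with ROI id + 1 at each ROI pixel (0 = background)."""
    out = np.zeros(frame_shape, dtype=np.int32)
    for roi in rois:
        out[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.id + 1
    return out


def match_rois_to_centroids(
    rois: Sequence[RoiMask],
    true_centroids: np.ndarray,
    max_dist_px: float,
) -> dict[int, int]:
    """Greedy nearest-centroid matching of detected ROIs to ground truth.

    Returns a mapping ``true index -> roi id`` for pairs closer than
    ``max_dist_px``; each ROI and each truth centroid is used at most once.
    """
    true_centroids = np.asarray(true_centroids, dtype=float)
    if not len(rois) or not len(true_centroids):
        return {}
    det = np.asarray([r.centroid for r in rois])
    d = np.linalg.norm(det[:, None, :] - true_centroids[None, :, :], axis=2)
    matches: dict[int, int] = {}
    used_rois: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ri, ti in order:
        if d[ri, ti] > max_dist_px:
            break
        if ti in matches or ri in used_rois:
            continue
        matches[int(ti)] = rois[ri].id
        used_rois.add(int(ri))
    return matches
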