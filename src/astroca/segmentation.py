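"""Activity-based ROI segmentation and soma/process classification.

Active regions are found from a temporal-activity map: each pixel is
detrended by its temporal median, its standard deviation over time is
computed, the SD map is smoothed and thresholded at mean + k*SD, and the
surviving connected components become ROIs. Components are classified as
somata (large, roundish) or processes (small or elongated) and processes
are grouped with their nearest soma into cells — an automated proxy for
morphology-based manual identification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Movie",
    "ROISet",
    "SegmentationParams",
    "CompartmentParams",
    "segment_active_rois",
    "classify_compartments",
    "extract_traces",
]


@dataclass
class Movie:
    """A T x H x W fluorescence stack with frame-interval metadata."""

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValidationError("movie must be T x H x W with T >= 2")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("movie contains non-finite pixels")
        if np.any(self.data < 0):
            raise ValidationError("movie intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class ROISet:
    """Labelled ROI pixels with compartment tags and cell grouping.

    label_image holds contiguous positive integer labels (0 = background);
    ``compartments`` maps label -> "soma"/"process"; ``cell_id`` maps
    label -> cell index (each soma is its own cell; processes join the
    nearest soma).
    """

    label_image: np.ndarray
    compartments: dict[int, str] = field(default_factory=dict)
    cell_id: dict[int, int] = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.label_image) if v != 0]

    @property
    def n_rois(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma_px: float = 0.5
    threshold_k: float = 2.0
    min_area_px: int = 20
    grow_px: int = 1  # dilation to recover thresholded-away ROI edges


@dataclass(frozen=True)
class CompartmentParams:
    soma_min_area_px: int = 100
    ecc_max: float = 0.95
    max_link_dist_px: float = 45.0


def segment_active_rois(
    movie: Movie, params: SegmentationParams = SegmentationParams()
) -> ROISet:
    """Segment temporally active regions of a movie into labelled ROIs.

    Invariant to adding a constant to every frame (median detrending) and
    to multiplying the movie by a positive constant (the threshold scales
    with the map). An all-constant movie yields an empty ROISet.
    """
    data = movie.data.astype(np.float64, copy=False)
    detrended = data - np.median(data, axis=0)
    sd_map = detrended.std(axis=0)
    if params.smooth_sigma_px > 0:
        sd_map = ndimage.gaussian_filter(sd_map, params.smooth_sigma_px)
    thr = sd_map.mean() + params.threshold_k * sd_map.std()
    active = sd_map > thr
    if params.grow_px > 0:
        active = ndimage.binary_closing(active)
        active = ndimage.binary_dilation(active, iterations=params.grow_px)
    labels, n = ndimage.label(active)
    if n == 0:
        return ROISet(label_image=labels.astype(np.int32))
    # drop small components, relabel contiguously
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= params.min_area_px) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return ROISet(label_image=remap[labels])


def classify_compartments(
    roiset: ROISet, params: CompartmentParams = CompartmentParams()
) -> ROISet:
    """Tag each ROI as soma or process and group compartments into cells.

    A component is a soma when its area is >= soma_min_area_px and its
    eccentricity is <= ecc_max; anything smaller or more elongated is a
    process. Each process joins the cell of the nearest soma centroid
    within max_link_dist_px, otherwise it forms its own cell.
    """
    if roiset.n_rois == 0:
        raise ValidationError("cannot classify an empty ROISet")
    props = {p.label: p for p in regionprops(roiset.label_image)}
    compartments: dict[int, str] = {}
    for label, p in props.items():
        is_soma = p.area >= params.soma_min_area_px and p.eccentricity <= params.ecc_max
        compartments[label] = "soma" if is_soma else "process"

    cell_id: dict[int, int] = {}
    soma_labels = [lb for lb, c in compartments.items() if c == "soma"]
    for idx, lb in enumerate(sorted(soma_labels)):
        cell_id[lb] = idx
    next_cell = len(soma_labels)
    soma_centroids = np.array([props[lb].centroid for lb in sorted(soma_labels)])
    for lb, c in compartments.items():
        if c == "soma":
            continue
        if len(soma_centroids):
            d = np.linalg.norm(soma_centroids - np.array(props[lb].centroid), axis=1)
            j = int(np.argmin(d))
            if d[j] <= params.max_link_dist_px:
                cell_id[lb] = cell_id[sorted(soma_labels)[j]]
                continue
        cell_id[lb] = next_cell
        next_cell += 1
    return ROISet(
        label_image=roiset.label_image, compartments=compartments, cell_id=cell_id
    )


def extract_traces(movie: Movie, roiset: ROISet) -> pd.DataFrame:
    """Mean intensity over each ROI's pixels per frame.

    Returns a DataFrame with a ``time_s`` column followed by one raw-trace
    column per label (named ``roi_<label>``). Trace extraction is linear:
    traces(a*movie + b) = a*traces(movie) + b. Empty labels are skipped
    with a warning.
    """
    if roiset.label_image.shape != movie.shape_hw:
        raise ValidationError("label image and movie shapes disagree")
    t = np.arange(movie.n_frames) * movie.frame_interval_s
    out = {"time_s": t}
    flat_labels = roiset.label_image.ravel()
    T = movie.n_frames
    flat = movie.data.reshape(T, -1)
    for label in roiset.labels:
        idx = np.flatnonzero(flat_labels == label)
        if idx.size == 0:
            logger.warning("label %d has no pixels; excluded", label)
            continue
        out[f"roi_{label}"] = flat[:, idx].mean(axis=1)
    return pd.DataFrame(out)
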