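"""Nuclear segmentation and cycle-aligned trace extraction.

Recovers, from a two-channel movie (histone channel for the nuclear
reference, reporter channel for the tagged construct):

* per-frame nuclear label masks (Gaussian smoothing + Otsu/percentile
  threshold, optional distance-transform watershed for touching nuclei),
* a field-averaged, background-corrected nuclear reporter trace,
* NEF/NEB cycle annotations from the nucleus-count time series (counts
  collapse when chromatin disperses at nuclear envelope breakdown), and
* per-cycle plateau ("peak") values taken 4 min after NEF, where the nuclear
  concentration is stable for 1-2 min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops_table
from skimage.morphology import disk
from skimage.segmentation import watershed

from .simulate import ImagingMovie

__all__ = [
    "SegmentationParams",
    "CycleDetectionParams",
    "LabelMask",
    "CycleAnnotation",
    "CycleEntry",
    "NuclearTrace",
    "PeakSeries",
    "segment_nuclei",
    "segment_movie",
    "measure_trace",
    "detect_cycles",
    "extract_peaks",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Histone-channel segmentation parameters.

    ``smooth_sigma`` defaults to about half the nuclear radius in pixels.
    ``threshold_method`` is "otsu" or "percentile" (with ``percentile``).
    ``contrast_ratio_min`` guards against thresholding featureless frames
    (mitosis, blank fields): a frame whose (p99 - median)/(median - p1)
    spread ratio falls below it yields an empty mask.
    """

    smooth_sigma: float = 2.0
    threshold_method: str = "otsu"
    percentile: float = 99.0
    min_area: int = 20
    max_area: int = 10_000
    split_touching: bool = True
    contrast_ratio_min: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "percentile"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.min_area < 1 or self.max_area < self.min_area:
            raise ValueError("need 1 <= min_area <= max_area")


@dataclass
class LabelMask:
    """Integer label image (0 = background) plus a region table."""

    labels: np.ndarray
    regions: pd.DataFrame  # columns: label, centroid_row, centroid_col, area

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def centroids(self) -> np.ndarray:
        return self.regions[["centroid_row", "centroid_col"]].to_numpy()


def _region_table(labels: np.ndarray) -> pd.DataFrame:
    if labels.max() == 0:
        return pd.DataFrame(columns=["label", "centroid_row", "centroid_col", "area"])
    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    return pd.DataFrame({
        "label": props["label"],
        "centroid_row": props["centroid-0"],
        "centroid_col": props["centroid-1"],
        "area": props["area"],
    })


def segment_nuclei(histone_frame: np.ndarray,
                   params: SegmentationParams = SegmentationParams()) -> LabelMask:
    """Segment nuclei in a single histone-channel frame.

    Deterministic given the frame and parameters.  A blank or featureless
    frame yields an empty mask rather than an error.
    """
    img = np.asarray(histone_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite pixels in histone frame")
    if np.any(img < 0):
        raise ValueError("negative intensities in histone frame")

    empty = LabelMask(np.zeros(img.shape, dtype=np.int32), _region_table(np.zeros(img.shape, int)))
    if img.max() == img.min():
        return empty
    smoothed = ndi.gaussian_filter(img, params.smooth_sigma)

    p1, med, p_hi = np.percentile(smoothed, [1, 50, 99.9])
    spread_lo = med - p1
    spread_hi = p_hi - med
    if spread_hi <= 0:  # no bright features at all
        return empty
    if spread_lo > 0 and spread_hi / spread_lo < params.contrast_ratio_min:
        return empty  # featureless (e.g. mitotic dispersal): spread is just noise

    if params.threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        thr = np.percentile(smoothed, params.percentile)
    binary = smoothed > thr
    if not binary.any():
        return empty

    if params.split_touching:
        # seeds: intensity maxima of the smoothed frame (nuclei have a
        # peaked chromatin profile), at least ~1 nuclear radius apart
        min_dist = max(3, int(round(2 * params.smooth_sigma)))
        peaks = peak_local_max(smoothed, min_distance=min_dist, labels=binary,
                               exclude_border=False)
        maxima = np.zeros(binary.shape, dtype=bool)
        maxima[tuple(peaks.T)] = True
        markers, _ = ndi.label(maxima)
        labels = watershed(-smoothed, markers, mask=binary)
    else:
        labels = sk_label(binary)

    # area filter
    table = _region_table(labels)
    bad = table[(table["area"] < params.min_area) | (table["area"] > params.max_area)]["label"]
    if len(bad):
        labels = np.where(np.isin(labels, bad.to_numpy()), 0, labels)
    labels, _, _ = _relabel(labels)
    return LabelMask(labels.astype(np.int32), _region_table(labels))


def _relabel(labels: np.ndarray):
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels], ids, lut


def segment_movie(movie: ImagingMovie,
                  params: SegmentationParams = SegmentationParams()) -> list[LabelMask]:
    """Segment every frame's histone channel."""
    return [segment_nuclei(movie.frames[i, 0], params) for i in range(movie.n_frames)]


# ---------------------------------------------------------------------------
# traces


@dataclass
class NuclearTrace:
    """Field-averaged, background-corrected nuclear reporter intensity.

    ``mean_corrected`` is NaN on frames with no segmented nuclei (missing,
    not zero).  Background is the median reporter intensity over a
    morphologically safeguarded cytoplasmic region (complement of the dilated
    mask union, eroded to stay clear of nuclear rims).
    """

    time_min: np.ndarray
    mean_corrected: np.ndarray
    n_nuclei: np.ndarray
    background: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time_min,
            "mean_corrected": self.mean_corrected,
            "n_nuclei": self.n_nuclei,
            "background": self.background,
        })

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "NuclearTrace":
        return NuclearTrace(
            time_min=df["time_min"].to_numpy(float),
            mean_corrected=df["mean_corrected"].to_numpy(float),
            n_nuclei=df["n_nuclei"].to_numpy(int),
            background=df["background"].to_numpy(float),
        )

    def value_near(self, t: float, side: str) -> float:
        """Trace value at the last frame before t (side='before') or the
        first frame at/after t (side='after'); NaN frames are skipped."""
        if side == "before":
            idx = np.nonzero(self.time_min < t - 1e-9)[0]
            order = idx[::-1]
        elif side == "after":
            idx = np.nonzero(self.time_min >= t - 1e-9)[0]
            order = idx
        else:
            raise ValueError("side must be 'before' or 'after'")
        for i in order:
            if np.isfinite(self.mean_corrected[i]):
                return float(self.mean_corrected[i])
        raise ValueError(f"no usable trace frame {side} t={t}")


def measure_trace(movie: ImagingMovie, masks: Sequence[LabelMask],
                  *, dilate_px: int = 3, erode_px: int = 5) -> NuclearTrace:
    """Measure the nuclear reporter trace through per-frame label masks.

    Per frame: nuclear mean = mean reporter intensity over all labelled
    pixels; background = median reporter intensity over the eroded complement
    of the dilated mask union; corrected = max(nuclear - background, 0).
    """
    if len(masks) != movie.n_frames:
        raise ValueError("mask count does not match movie frame count")
    T = movie.n_frames
    mean_c = np.full(T, np.nan)
    nn = np.zeros(T, dtype=int)
    bg = np.zeros(T, dtype=float)
    selem_d = disk(dilate_px)
    selem_e = disk(erode_px)
    for i in range(T):
        rep = movie.frames[i, 1]
        lab = masks[i].labels
        fg = lab > 0
        cyto = ~ndi.binary_dilation(fg, structure=selem_d)
        cyto = ndi.binary_erosion(cyto, structure=selem_e, border_value=1)
        if not cyto.any():
            cyto = ~fg
        bg[i] = float(np.median(rep[cyto])) if cyto.any() else 0.0
        nn[i] = masks[i].n_regions
        if fg.any():
            mean_c[i] = max(float(rep[fg].mean()) - bg[i], 0.0)
    return NuclearTrace(time_min=movie.times_min.copy(), mean_corrected=mean_c,
                        n_nuclei=nn, background=bg)


# ---------------------------------------------------------------------------
# cycle detection


@dataclass(frozen=True)
class CycleDetectionParams:
    """NEB = sustained (>= m frames) drop of the nucleus count below fraction
    f of the preceding interphase plateau; NEF = first frame of the sustained
    recovery that follows.  Cycle indices count back from the final cycle."""

    drop_fraction: float = 0.5  # f
    min_run: int = 3  # m, frames
    last_cycle_index: int = 14


@dataclass(frozen=True)
class CycleEntry:
    cycle_index: int
    nef_frame: int
    neb_frame: int | None


@dataclass
class CycleAnnotation:
    entries: list[CycleEntry]
    frame_interval_min: float
    start_time_min: float = 0.0
    warning: str | None = None

    def frame_time(self, frame: int) -> float:
        return self.start_time_min + frame * self.frame_interval_min

    def nef_times(self) -> list[float]:
        return [self.frame_time(e.nef_frame) for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle_index": [e.cycle_index for e in self.entries],
            "nef_frame": [e.nef_frame for e in self.entries],
            "neb_frame": [e.neb_frame if e.neb_frame is not None else -1
                          for e in self.entries],
            "nef_time_min": [self.frame_time(e.nef_frame) for e in self.entries],
            "neb_time_min": [self.frame_time(e.neb_frame) if e.neb_frame is not None
                             else np.nan for e in self.entries],
        })

    def cycle(self, index: int) -> CycleEntry:
        for e in self.entries:
            if e.cycle_index == index:
                return e
        raise KeyError(index)


def _sustained_run_start(cond: np.ndarray, start: int, m: int) -> int | None:
    """First index >= start opening a run of >= m consecutive True values."""
    n = len(cond)
    i = start
    while i < n:
        if cond[i]:
            j = i
            while j < n and cond[j]:
                j += 1
            if j - i >= m or j == n:  # a run truncated by the movie end counts
                return i
            i = j
        else:
            i += 1
    return None


def detect_cycles(movie: ImagingMovie, masks: Sequence[LabelMask],
                  params: CycleDetectionParams = CycleDetectionParams()) -> CycleAnnotation:
    """Annotate NEF/NEB frames from the per-frame nucleus count."""
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames")
    counts = np.array([m.n_regions for m in masks], dtype=float)
    f, m = params.drop_fraction, params.min_run
    dt = movie.frame_interval_s / 60.0

    boundaries: list[tuple[int, int | None]] = []  # (nef_frame, neb_frame)
    nef = 0
    pos = 0
    while True:
        # plateau of the current interphase: median count from nef up to the
        # next sustained drop; estimate provisionally from the next m frames
        window = counts[nef:nef + max(m, 3)]
        plateau = np.median(window[window > 0]) if np.any(window > 0) else 0.0
        if plateau <= 0:
            break
        below = counts < f * plateau
        neb = _sustained_run_start(below, nef + 1, m)
        if neb is None:
            boundaries.append((nef, None))
            break
        # refine plateau over the full interphase, re-check the drop frame
        plateau = np.median(counts[nef:neb][counts[nef:neb] > 0]) if np.any(counts[nef:neb] > 0) else plateau
        below = counts < f * plateau
        neb2 = _sustained_run_start(below, nef + 1, m)
        neb = neb2 if neb2 is not None else neb
        boundaries.append((nef, neb))
        above = counts >= f * plateau
        nxt = _sustained_run_start(above, neb + 1, m)
        if nxt is None:
            break
        nef = nxt
        pos += 1
        if pos > 50:  # safety against pathological oscillation
            break

    if not boundaries:
        warnings.warn("no stable nucleus-count plateau found; annotating a single open cycle")
        entries = [CycleEntry(params.last_cycle_index, 0, None)]
        return CycleAnnotation(entries, dt, movie.start_time_min,
                               warning="no stable plateau")

    n = len(boundaries)
    first_index = params.last_cycle_index - n + 1
    entries = [CycleEntry(first_index + i, nef, neb)
               for i, (nef, neb) in enumerate(boundaries)]
    return CycleAnnotation(entries, dt, movie.start_time_min)


# ---------------------------------------------------------------------------
# peak extraction


@dataclass
class PeakSeries:
    """Per-cycle plateau values of the corrected nuclear trace."""

    table: pd.DataFrame  # cycle_index, peak_time_min, plateau_mean, plateau_sd, n_frames

    def __len__(self) -> int:
        return len(self.table)

    def plateau(self, cycle_index: int) -> float:
        row = self.table[self.table["cycle_index"] == cycle_index]
        if row.empty:
            raise KeyError(cycle_index)
        return float(row["plateau_mean"].iloc[0])


def extract_peaks(trace: NuclearTrace, cycles: CycleAnnotation,
                  offset: float = 4.0, window: float = 1.0) -> PeakSeries:
    """Average the corrected trace over [NEF+offset, NEF+offset+window].

    Cycles whose interphase cannot hold the window are omitted (with a
    warning); the plateau sits ~4 min after NEF and is stable for 1-2 min.
    """
    if trace.time_min.size == 0:
        raise ValueError("empty trace")
    rows = []
    omitted = []
    for e in cycles.entries:
        t_nef = cycles.frame_time(e.nef_frame)
        t_end = (cycles.frame_time(e.neb_frame) if e.neb_frame is not None
                 else trace.time_min[-1] + cycles.frame_interval_min)
        t0, t1 = t_nef + offset, t_nef + offset + window
        if t1 > t_end + 1e-9:
            omitted.append(e.cycle_index)
            continue
        sel = (trace.time_min >= t0 - 1e-9) & (trace.time_min <= t1 + 1e-9)
        vals = trace.mean_corrected[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            omitted.append(e.cycle_index)
            continue
        rows.append({
            "cycle_index": e.cycle_index,
            "peak_time_min": t_nef + offset,
            "plateau_mean": float(vals.mean()),
            "plateau_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n_frames": int(vals.size),
        })
    if omitted:
        warnings.warn(f"cycles too short for the plateau window, omitted: {omitted}")
    return PeakSeries(pd.DataFrame(rows, columns=[
        "cycle_index", "peak_time_min", "plateau_mean", "plateau_sd", "n_frames"]))
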