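"""Lipid-droplet morphometry and stained-area measurement of section images.

Droplets appear as bright (unstained) regions on a stained background.
The intensity histogram is auto-thresholded with the Minimum method
(iterated 3-point smoothing until bimodal, threshold at the valley between
the two modes), droplets are labeled as 8-connected bright components,
components below a physical area cutoff (default 18 µm², i.e. 30 pixels at
0.6 µm²/pixel) are discarded, and the surviving areas are binned
([18, 200), [200, 400), ... µm²), summarized per animal (bin relative
frequencies and median area) and compared between groups with unpaired
t tests.  For two-channel immunofluorescence, percent stained areas are
measured with Yen (signal) and Otsu (nuclei) thresholds and reported as a
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import skimage.filters
import skimage.measure

from .exceptions import (
    FormatError,
    InsufficientReplicationError,
    ThresholdingError,
    UndefinedRatioError,
)
from .scoring import _two_sample_t

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_AREA_UM2 = 0.6  # 30 px <-> 18 µm²
DEFAULT_MIN_AREA_UM2 = 18.0
DEFAULT_BIN_WIDTH = 200.0
DEFAULT_FIRST_BIN_LOW = 18.0
DEFAULT_BIN_CAP = 2000.0

#: fixed palette for size-bin colorization (RGB), cycled if bins exceed it
BIN_PALETTE: tuple[tuple[int, int, int], ...] = (
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (255, 187, 120), (152, 223, 138),
)


@dataclass
class CalibratedImage:
    """A raster with a physical pixel-area calibration.

    ``pixels`` is 2-D (8-bit grayscale) or 3-D HxWx3 (RGB); ``pixel_area``
    is µm² per pixel; ``exclusion_mask`` marks pixels (vessels, artifacts)
    to force to background before segmentation.
    """

    pixels: np.ndarray
    pixel_area: float = DEFAULT_PIXEL_AREA_UM2
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if self.exclusion_mask is not None and (
            self.exclusion_mask.shape != self.pixels.shape[:2]
        ):
            raise FormatError("exclusion mask dimensions do not match image")

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


def to_grayscale(img: CalibratedImage, luminance: bool = False) -> CalibratedImage:
    """Collapse RGB to 8-bit gray: unweighted channel mean by default,
    Rec. 601 luminance weights optionally.  Gray input passes through."""
    px = img.pixels
    if px.ndim == 2:
        gray = px
    elif px.ndim == 3 and px.shape[2] == 3:
        chans = px.astype(float)
        if luminance:
            gray = chans @ np.array([0.299, 0.587, 0.114])
        else:
            gray = chans.mean(axis=2)
        gray = np.rint(gray)
    else:
        raise FormatError(f"expected 2-D gray or HxWx3 RGB, got shape {px.shape}")
    if gray.min() < 0 or gray.max() > 255:
        raise FormatError("pixel values outside the 8-bit range [0, 255]")
    return CalibratedImage(
        pixels=gray.astype(np.uint8),
        pixel_area=img.pixel_area,
        exclusion_mask=img.exclusion_mask,
    )


def _local_maxima(hist: np.ndarray) -> list[int]:
    """Indices of local maxima by direction scan (plateaus count once)."""
    maxima = []
    direction = 1
    for i in range(len(hist) - 1):
        if direction > 0:
            if hist[i + 1] < hist[i]:
                direction = -1
                maxima.append(i)
        else:
            if hist[i + 1] > hist[i]:
                direction = 1
    return maxima


def minimum_autothreshold(hist: np.ndarray, max_iter: int = 10000) -> int:
    """Minimum-method threshold of a 256-bin intensity histogram.

    The histogram is repeatedly smoothed with a 3-point running mean until
    exactly two local maxima remain; the returned level is the minimum of
    the smoothed histogram between the two maxima.  Deterministic for a
    given histogram and invariant to scaling all counts by a positive
    constant.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1:
        raise ThresholdingError("histogram must be one-dimensional")
    if np.count_nonzero(hist) < 2:
        raise ThresholdingError("histogram needs counts at >= 2 distinct levels")
    smooth = hist.copy()
    for _ in range(max_iter + 1):
        maxima = _local_maxima(smooth)
        if len(maxima) == 2:
            lo, hi = maxima
            return int(lo + np.argmin(smooth[lo : hi + 1]))
        smooth = scipy.ndimage.uniform_filter1d(smooth, 3)
    raise ThresholdingError(
        f"histogram did not become bimodal within {max_iter} smoothing passes"
    )


def segment_droplets(
    img: CalibratedImage, threshold: int | None = None
) -> tuple[np.ndarray, int]:
    """Label bright (above-threshold) 8-connected components.

    The threshold defaults to the Minimum method on the histogram of
    non-excluded pixels; excluded pixels are forced to background.
    Returns the label raster (0 = background, 1..n components) and the
    threshold used.
    """
    gray = to_grayscale(img)
    px = gray.pixels
    mask = img.exclusion_mask
    if mask is not None:
        usable = px[~mask.astype(bool)]
    else:
        usable = px.ravel()
    if threshold is None:
        hist = np.bincount(usable, minlength=256)
        threshold = minimum_autothreshold(hist)
    fg = px > threshold
    if mask is not None:
        fg &= ~mask.astype(bool)
    labels = skimage.measure.label(fg, connectivity=2)
    return labels, int(threshold)


def measure_droplets(
    labels: np.ndarray,
    pixel_area: float = DEFAULT_PIXEL_AREA_UM2,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> pd.DataFrame:
    """Per-component pixel and physical areas, small components discarded.

    The cutoff is strict in physical units: a component of exactly
    ``min_area_um2`` (30 px at the default calibration) is retained.
    """
    props = skimage.measure.regionprops(labels)
    rows = []
    for p in props:
        area_um2 = p.area * pixel_area
        if area_um2 < min_area_um2:
            continue
        rows.append({
            "droplet_id": int(p.label),
            "area_px": int(p.area),
            "area_um2": float(area_um2),
            "centroid_row": float(p.centroid[0]),
            "centroid_col": float(p.centroid[1]),
        })
    return pd.DataFrame(
        rows, columns=["droplet_id", "area_px", "area_um2", "centroid_row", "centroid_col"]
    )


def bin_edges(
    max_area: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    first_bin_low: float = DEFAULT_FIRST_BIN_LOW,
    cap: float | None = DEFAULT_BIN_CAP,
) -> list[float]:
    """Half-open size-bin edges: [18, 200), [200, 400), ..., [cap, inf)."""
    edges = [first_bin_low]
    upper = bin_width
    stop = cap if cap is not None else max(max_area + bin_width, bin_width)
    while upper < stop or np.isclose(upper, stop):
        if upper > first_bin_low:
            edges.append(upper)
        upper += bin_width
    edges.append(np.inf)
    return edges


def _bin_labels(edges: list[float]) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f">={lo:g}-<{hi:g}")
    return labels


def assign_bins(
    records: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    first_bin_low: float = DEFAULT_FIRST_BIN_LOW,
    cap: float | None = DEFAULT_BIN_CAP,
) -> pd.DataFrame:
    """Add ``bin_index`` / ``bin_label`` columns from droplet areas."""
    records = records.copy()
    if records.empty:
        records["bin_index"] = pd.Series(dtype=int)
        records["bin_label"] = pd.Series(dtype=str)
        return records
    edges = bin_edges(records["area_um2"].max(), bin_width, first_bin_low, cap)
    labels = _bin_labels(edges)
    idx = np.searchsorted(edges, records["area_um2"].to_numpy(), side="right") - 1
    records["bin_index"] = idx
    records["bin_label"] = [labels[i] for i in idx]
    return records


@dataclass
class DropletSizeSummary:
    """Per-animal pooled droplet summary: bin frequencies and median area."""

    frequencies: pd.Series
    median_um2: float
    n_droplets: int
    edges: list[float] = field(default_factory=list)


def size_distribution(
    records: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    first_bin_low: float = DEFAULT_FIRST_BIN_LOW,
    cap: float | None = DEFAULT_BIN_CAP,
) -> DropletSizeSummary:
    """Relative bin frequencies and median area of pooled droplet records.

    Records from all fields of view of one animal should be concatenated
    before calling.  Empty input yields an all-zero summary with a warning.
    """
    if records.empty:
        logger.warning("no droplet records; summary is empty")
        edges = bin_edges(first_bin_low, bin_width, first_bin_low, cap)
        freq = pd.Series(0.0, index=_bin_labels(edges))
        return DropletSizeSummary(freq, float("nan"), 0, edges)
    # a fixed cap keeps bins comparable across animals
    edges = bin_edges(records["area_um2"].max(), bin_width, first_bin_low, cap)
    labels = _bin_labels(edges)
    idx = np.searchsorted(edges, records["area_um2"].to_numpy(), side="right") - 1
    counts = np.bincount(idx, minlength=len(labels))
    freq = pd.Series(counts / counts.sum(), index=labels)
    return DropletSizeSummary(
        frequencies=freq,
        median_um2=float(records["area_um2"].median()),
        n_droplets=len(records),
        edges=edges,
    )


def colorize_droplets(
    labels: np.ndarray,
    records: pd.DataFrame,
    palette: tuple[tuple[int, int, int], ...] = BIN_PALETTE,
    background: tuple[int, int, int] = (0, 0, 0),
) -> tuple[np.ndarray, dict[str, tuple[int, int, int]]]:
    """Paint each measured droplet the color of its size bin.

    Droplets removed by the size filter (absent from ``records``) stay
    background-colored.  Returns the RGB raster and a bin -> color legend.
    """
    if "bin_index" not in records.columns:
        records = assign_bins(records)
    rgb = np.empty((*labels.shape, 3), dtype=np.uint8)
    rgb[:] = background
    legend: dict[str, tuple[int, int, int]] = {}
    for _, rec in records.iterrows():
        color = palette[int(rec["bin_index"]) % len(palette)]
        rgb[labels == rec["droplet_id"]] = color
        legend[str(rec["bin_label"])] = color
    return rgb, legend


def compare_group_medians(
    summaries: dict[str, DropletSizeSummary],
    groups: dict[str, str],
    equal_var: bool = True,
) -> dict[str, pd.DataFrame]:
    """Unpaired two-tailed t tests on per-animal medians and bin frequencies.

    Returns ``{"median": one-row frame, "bins": one row per size bin}``.
    Group means/SDs are included alongside t and p.
    """
    animals = list(summaries)
    levels = sorted(set(groups[a] for a in animals))
    if len(levels) != 2:
        raise InsufficientReplicationError(f"exactly 2 groups required, found {len(levels)}")
    g1, g2 = levels
    a1 = [a for a in animals if groups[a] == g1]
    a2 = [a for a in animals if groups[a] == g2]
    if len(a1) < 2 or len(a2) < 2:
        raise InsufficientReplicationError("each group needs >= 2 animals")

    def _row(name: str, v1: np.ndarray, v2: np.ndarray) -> dict:
        t, p = _two_sample_t(v1, v2, equal_var=equal_var)
        return {
            "measure": name,
            f"mean_{g1}": v1.mean(), f"sd_{g1}": v1.std(ddof=1), f"n_{g1}": len(v1),
            f"mean_{g2}": v2.mean(), f"sd_{g2}": v2.std(ddof=1), f"n_{g2}": len(v2),
            "t": t, "p": p,
        }

    med1 = np.array([summaries[a].median_um2 for a in a1])
    med2 = np.array([summaries[a].median_um2 for a in a2])
    median_stats = pd.DataFrame([_row("median_um2", med1, med2)]).set_index("measure")

    all_bins: list[str] = []
    for a in animals:
        for b in summaries[a].frequencies.index:
            if b not in all_bins:
                all_bins.append(b)
    rows = []
    for b in all_bins:
        f1 = np.array([summaries[a].frequencies.get(b, 0.0) for a in a1])
        f2 = np.array([summaries[a].frequencies.get(b, 0.0) for a in a2])
        rows.append(_row(b, f1, f2))
    bin_stats = pd.DataFrame(rows).set_index("measure")
    return {"median": median_stats, "bins": bin_stats}


def stain_area_ratio(
    signal_img: CalibratedImage, nuclei_img: CalibratedImage
) -> tuple[float, float, float]:
    """Percent stained areas (Yen for signal, Otsu for nuclei) and their ratio.

    Foreground is strictly above the threshold; percent area is
    100 * foreground pixels / total pixels.  A nuclei percent area of zero
    raises :class:`UndefinedRatioError`.
    """
    sig = to_grayscale(signal_img).pixels
    nuc = to_grayscale(nuclei_img).pixels
    if sig.shape != nuc.shape:
        raise FormatError("signal and nuclei images differ in dimensions")

    def _pct(gray: np.ndarray, method) -> float:
        if gray.min() == gray.max():
            return 0.0  # constant image: nothing above any threshold
        thr = method(gray)
        return 100.0 * float((gray > thr).mean())

    signal_pct = _pct(sig, skimage.filters.threshold_yen)
    nuclei_pct = _pct(nuc, skimage.filters.threshold_otsu)
    if nuclei_pct == 0.0:
        raise UndefinedRatioError("nuclei channel has zero thresholded area")
    return signal_pct, nuclei_pct, signal_pct / nuclei_pct


def droplet_pipeline(
    img: CalibratedImage,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    bin_width: float = DEFAULT_BIN_WIDTH,
    cap: float | None = DEFAULT_BIN_CAP,
) -> tuple[np.ndarray, pd.DataFrame, DropletSizeSummary]:
    """Segment, measure, bin and summarize one section image."""
    labels, _ = segment_droplets(img)
    records = measure_droplets(labels, pixel_area=img.pixel_area, min_area_um2=min_area_um2)
    records = assign_bins(records, bin_width=bin_width, first_bin_low=min_area_um2, cap=cap)
    summary = size_distribution(records, bin_width=bin_width, first_bin_low=min_area_um2, cap=cap)
    return labels, records, summary
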