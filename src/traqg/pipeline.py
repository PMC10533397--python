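"""Ratiometric image analysis: background, segmentation, ratio, calibration.

The procedure for one field of view (FOV):

1. estimate a per-channel scalar background from blank FOVs (mean over
   all pixels excluding an edge margin),
2. subtract it from both channels, clipping negatives to zero,
3. segment transfected cells by thresholding the FP reference channel,
4. divide FP by SiR pixel-by-pixel inside the segmented regions,
5. average the ratio per cell (one data point per cell) or per FOV
   (one data point per FOV, used for plate-type calibration imaging),
6. fit / apply a linear calibration curve to express ratios in mM GSH,
7. screen per-cell values with a robust median/MAD outlier rule.

A 3x3 median despeckle is provided for display images only and is never
applied upstream of statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .sensor import CalibrationCurve
from .simulate import ChannelPair

__all__ = [
    "RatioMap",
    "CellMeasurement",
    "estimate_background",
    "subtract_background",
    "segment",
    "ratio_map",
    "per_cell_means",
    "fov_mean",
    "CalibrationModel",
    "CalibrationResults",
    "fit_calibration",
    "apply_calibration",
    "flag_outliers",
    "despeckle",
    "match_labels",
]


@dataclass
class RatioMap:
    """Pixel-wise FP/SiR ratio, defined only inside valid ROI pixels.

    Undefined pixels (outside any ROI, or with SiR at or below ``eps``)
    are NaN.  ``n_excluded`` counts in-ROI pixels lost to the
    divide-by-zero guard.
    """

    values: np.ndarray
    n_excluded: int = 0
    background: tuple[float, float] | None = None
    calibrated: bool = False

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class CellMeasurement:
    """One segmented cell's ratio (and, once calibrated, [GSH]) record."""

    label: int
    area_px: int
    centroid: tuple[float, float]
    mean_ratio: float
    n_valid_px: int
    gsh_mM: float | None = None
    extrapolated: bool = False
    outlier: bool = False

    def replace(self, **kw) -> "CellMeasurement":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# background


def _interior(img: np.ndarray, margin: int) -> np.ndarray:
    h, w = img.shape
    if margin < 0 or 2 * margin >= h or 2 * margin >= w:
        raise ValueError(
            f"margin {margin} leaves no interior in a {h}x{w} image"
        )
    return img[margin : h - margin, margin : w - margin]


def estimate_background(
    blanks: Sequence[ChannelPair], border_margin_px: int = 16
) -> tuple[float, float]:
    """Per-channel background: interior mean of each blank, averaged.

    Edges are excluded because vignetting and readout artefacts
    concentrate there; each blank FOV contributes one mean per channel
    and blanks are weighted equally.
    """
    if len(blanks) == 0:
        raise ValueError("need at least one blank FOV")
    fp = float(np.mean([_interior(b.fp, border_margin_px).mean() for b in blanks]))
    sir = float(np.mean([_interior(b.sir, border_margin_px).mean() for b in blanks]))
    return fp, sir


def subtract_background(
    pair: ChannelPair, bg: tuple[float, float]
) -> tuple[ChannelPair, tuple[int, int]]:
    """Subtract scalar backgrounds; negatives clip to 0 and are counted."""
    bg_fp, bg_sir = bg
    if bg_fp < 0 or bg_sir < 0:
        raise ValueError("background must be non-negative")
    fp = pair.fp - bg_fp
    sir = pair.sir - bg_sir
    n_fp = int(np.count_nonzero(fp < 0))
    n_sir = int(np.count_nonzero(sir < 0))
    np.clip(fp, 0.0, None, out=fp)
    np.clip(sir, 0.0, None, out=sir)
    return ChannelPair(fp=fp, sir=sir), (n_fp, n_sir)


# ---------------------------------------------------------------------------
# segmentation


def segment(
    fp: np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
    min_area_px: int = 50,
    border_margin_px: int = 16,
) -> np.ndarray:
    """Threshold the background-subtracted FP channel into a label map.

    Transfected cells are bright in the reference channel regardless of
    GSH, so the FP channel is the one thresholded.  The Otsu threshold
    is derived on log1p-transformed intensities: expression varies over
    roughly an order of magnitude between cells, and on the raw scale
    Otsu places the cut inside that spread, losing dim cells; on the log
    scale background and foreground are cleanly bimodal.  Connected
    components (8-connectivity) smaller than ``min_area_px`` or touching
    the border margin frame are dropped; surviving labels are renumbered
    1..n in raster order of each component's first pixel.
    """
    fp = np.asarray(fp, dtype=float)
    if method == "otsu":
        if fp.max() <= fp.min():
            return np.zeros(fp.shape, dtype=np.int32)
        thr = float(np.expm1(threshold_otsu(np.log1p(np.maximum(fp, 0.0)))))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = fp > thr
    raw = _cc_label(mask, connectivity=2)
    h, w = fp.shape
    m = border_margin_px
    border = np.zeros_like(mask)
    if m > 0:
        border[:m, :] = True
        border[h - m :, :] = True
        border[:, :m] = True
        border[:, w - m :] = True
    out = np.zeros(fp.shape, dtype=np.int32)
    next_label = 1
    # raster order of first pixel == ascending order of first flat index
    order = []
    flat = raw.ravel()
    first_idx: dict[int, int] = {}
    for idx in np.flatnonzero(flat):
        lab = flat[idx]
        if lab not in first_idx:
            first_idx[lab] = idx
    for lab, _ in sorted(first_idx.items(), key=lambda kv: kv[1]):
        comp = raw == lab
        if int(comp.sum()) < min_area_px:
            continue
        if m > 0 and bool(comp[border].any()):
            continue
        out[comp] = next_label
        next_label += 1
    return out


# ---------------------------------------------------------------------------
# ratio and summaries


def ratio_map(
    pair: ChannelPair,
    labels: np.ndarray,
    eps: float = 1.0,
    background: tuple[float, float] | None = None,
) -> RatioMap:
    """Pixel-wise FP/SiR inside ROIs; SiR <= eps pixels are excluded.

    The orientation is fixed as reference over sensor (mGold over
    TRaQ-G) so the ratio increases with GSH.
    """
    labels = np.asarray(labels)
    if labels.shape != pair.shape:
        raise ValueError(f"label shape {labels.shape} != image shape {pair.shape}")
    roi = labels > 0
    valid = roi & (pair.sir > eps)
    values = np.full(pair.shape, np.nan)
    values[valid] = pair.fp[valid] / pair.sir[valid]
    return RatioMap(
        values=values,
        n_excluded=int(np.count_nonzero(roi & ~valid)),
        background=background,
    )


def per_cell_means(
    rmap: RatioMap,
    labels: np.ndarray,
    min_valid_fraction: float = 0.5,
) -> list[CellMeasurement]:
    """Mean ratio per cell — one data point per segmented cell.

    Cells whose valid-pixel fraction falls below ``min_valid_fraction``
    (too many saturated/zero SiR pixels) are dropped.
    """
    labels = np.asarray(labels)
    if labels.shape != rmap.values.shape:
        raise ValueError("ratio map and label map are not aligned")
    out: list[CellMeasurement] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        area = int(mask.sum())
        vals = rmap.values[mask]
        vals = vals[np.isfinite(vals)]
        if area == 0 or vals.size / area < min_valid_fraction:
            continue
        rr, cc = np.nonzero(mask)
        out.append(
            CellMeasurement(
                label=int(lab),
                area_px=area,
                centroid=(float(rr.mean()), float(cc.mean())),
                mean_ratio=float(vals.mean()),
                n_valid_px=int(vals.size),
            )
        )
    return out


def fov_mean(rmap: RatioMap, border_margin_px: int = 16) -> float:
    """Mean of defined ratio pixels in the FOV interior (one point/FOV)."""
    interior = _interior(rmap.values, border_margin_px)
    vals = interior[np.isfinite(interior)]
    if vals.size == 0:
        raise ValueError("no defined ratio pixels in the FOV interior")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# calibration


class CalibrationModel:
    """Ordinary least-squares line relating FP/SiR ratio to [GSH].

    Only points with concentration inside ``range_mM`` enter the fit —
    the sensor responds linearly over roughly 1-20 mM and calibration
    outside that window is extrapolation.  Curves are pH specific.
    """

    def __init__(
        self,
        concs_mM: Sequence[float],
        ratios: Sequence[float],
        range_mM: tuple[float, float] = (1.0, 20.0),
        ph: float = 7.4,
    ):
        self.concs = np.asarray(list(concs_mM), dtype=float)
        self.ratios = np.asarray(list(ratios), dtype=float)
        if self.concs.shape != self.ratios.shape or self.concs.ndim != 1:
            raise ValueError("concentrations and ratios must be equal-length 1-D")
        self.range_mM = (float(range_mM[0]), float(range_mM[1]))
        self.ph = float(ph)
        lo, hi = self.range_mM
        self.in_range = (self.concs >= lo) & (self.concs <= hi)
        if int(self.in_range.sum()) < 3:
            raise ValueError(
                f"need >= 3 calibration points inside {self.range_mM}, "
                f"got {int(self.in_range.sum())}"
            )

    def fit(self) -> "CalibrationResults":
        x = self.concs[self.in_range]
        y = self.ratios[self.in_range]
        res = stats.linregress(x, y)
        flags = []
        if res.slope <= 0:
            flags.append("non-positive slope: sensor inverted or failed")
            curve = None
        else:
            curve = CalibrationCurve(
                slope=float(res.slope),
                intercept=float(res.intercept),
                range_mM=self.range_mM,
                r_squared=float(min(max(res.rvalue**2, 0.0), 1.0)),
                ph=self.ph,
            )
        return CalibrationResults(
            model=self,
            curve=curve,
            slope=float(res.slope),
            intercept=float(res.intercept),
            slope_se=float(res.stderr),
            intercept_se=float(res.intercept_stderr),
            r_squared=float(res.rvalue**2),
            n_used=int(self.in_range.sum()),
            flags=flags,
        )


@dataclass
class CalibrationResults:
    """Fitted calibration line with uncertainties and QC flags."""

    model: CalibrationModel
    curve: CalibrationCurve | None
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n_used: int
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lo, hi = self.model.range_mM
        lines = [
            "Ratio-to-GSH calibration (OLS)",
            "=" * 46,
            f"validity range: {lo:g}-{hi:g} mM at pH {self.model.ph:g}",
            f"n points used:  {self.n_used}",
            f"slope:          {self.slope:.6g} +/- {self.slope_se:.2g} per mM",
            f"intercept:      {self.intercept:.6g} +/- {self.intercept_se:.2g}",
            f"R^2:            {self.r_squared:.6f}",
        ]
        for fl in self.flags:
            lines.append(f"FLAG: {fl}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.concs, self.model.ratios, "o", label="FOV means")
        if self.curve is not None:
            gg = np.linspace(*self.model.range_mM, 50)
            ax.plot(gg, self.curve.ratio_at(gg), "-", label="calibration")
        ax.set_xlabel("[GSH] (mM)")
        ax.set_ylabel("FP/SiR ratio")
        ax.legend()
        return ax


def fit_calibration(
    concs_mM: Sequence[float],
    ratios: Sequence[float],
    range_mM: tuple[float, float] = (1.0, 20.0),
    ph: float = 7.4,
) -> CalibrationCurve:
    """Fit the linear calibration and return the curve.

    Raises if fewer than 3 points fall inside the validity range or the
    fitted slope is non-positive (a failed or inverted sensor).
    """
    res = CalibrationModel(concs_mM, ratios, range_mM=range_mM, ph=ph).fit()
    if res.curve is None:
        raise ValueError("; ".join(res.flags))
    return res.curve


def apply_calibration(
    measurements: Sequence[CellMeasurement],
    curve: CalibrationCurve,
    policy: Literal["flag", "clip", "drop"] = "flag",
) -> list[CellMeasurement]:
    """Invert the calibration to mM GSH for each cell.

    ``gsh = (ratio - intercept) / slope``.  Values outside the validity
    range are handled per policy — ``flag`` reports them as-is (the
    interpolate/extrapolate convention), ``clip`` pins them to the range
    edge, ``drop`` removes the cell — and always carry the
    ``extrapolated`` flag.
    """
    if policy not in ("flag", "clip", "drop"):
        raise ValueError(f"unknown out-of-range policy {policy!r}")
    lo, hi = curve.range_mM
    out: list[CellMeasurement] = []
    for m in measurements:
        gsh = float(curve.invert(m.mean_ratio))
        extrapolated = not (lo <= gsh <= hi)
        if extrapolated and policy == "drop":
            continue
        if extrapolated and policy == "clip":
            gsh = float(np.clip(gsh, lo, hi))
        out.append(m.replace(gsh_mM=gsh, extrapolated=extrapolated))
    return out


# ---------------------------------------------------------------------------
# QC


def flag_outliers(
    values: Sequence[float], k_mad: float = 3.5, return_info: bool = False
):
    """Robust median/MAD outlier screen.

    A value is flagged iff ``|x - median| > k_mad * 1.4826 * MAD``.  The
    1.4826 factor makes the MAD consistent for the normal SD, and the
    default ``k_mad = 3.5`` flags roughly 1% of clean normal data.  When
    the MAD is zero but the data are not constant (heavily tied data),
    an interquartile fence (1.5 IQR) is used instead and noted.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values for outlier screening")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    info = {"method": "mad", "median": med, "mad": mad}
    if mad > 0:
        mask = np.abs(x - med) > k_mad * 1.4826 * mad
    elif np.all(x == x[0]):
        mask = np.zeros(x.shape, dtype=bool)
    else:
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        mask = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        info["method"] = "iqr_fallback"
    if return_info:
        return mask, info
    return mask


def despeckle(img: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication — display/export only.

    Never applied before per-cell or per-FOV statistics; it exists so
    exported calibrated images match the conventional despeckled look.
    """
    return ndimage.median_filter(np.asarray(img, dtype=float), size=3, mode="nearest")


# ---------------------------------------------------------------------------
# ground-truth matching (for recovery scoring of simulations)


def match_labels(
    seg: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> dict[int, int]:
    """Greedy best-IoU matching of segmented labels to true labels.

    Returns {segmented label: true label} for pairs whose intersection
    over union exceeds the threshold; each true label is used once.
    """
    seg = np.asarray(seg)
    truth = np.asarray(truth)
    pairs = []
    seg_areas = {int(l): int((seg == l).sum()) for l in np.unique(seg) if l != 0}
    tru_areas = {int(l): int((truth == l).sum()) for l in np.unique(truth) if l != 0}
    both = (seg > 0) & (truth > 0)
    combos, counts = np.unique(
        np.stack([seg[both], truth[both]]), axis=1, return_counts=True
    )
    for (s, t), inter in zip(combos.T, counts):
        s, t = int(s), int(t)
        union = seg_areas[s] + tru_areas[t] - int(inter)
        iou = inter / union if union else 0.0
        if iou > iou_threshold:
            pairs.append((iou, s, t))
    pairs.sort(reverse=True)
    used_s: set[int] = set()
    used_t: set[int] = set()
    out: dict[int, int] = {}
    for iou, s, t in pairs:
        if s in used_s or t in used_t:
            continue
        out[s] = t
        used_s.add(s)
        used_t.add(t)
    return out
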