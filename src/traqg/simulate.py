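"""Synthetic two-channel FOV generator with full ground truth.

Emulates confocal fields of view of cells expressing an FP-HaloTag
fusion labelled with the TRaQ-G ligand: each cell is an ellipse of
uniform interior intensity whose FP channel reports expression and whose
SiR channel is quenched by that cell's GSH concentration.  Per-cell GSH
is drawn from stated population distributions (the nucleus preset uses
14.0 +/- 6.7 mM), expression is lognormal, and the camera model is
Poisson shot noise followed by additive Gaussian read noise, clipped at
zero.  Everything downstream of the optics is deterministic given the
seed, and the generator emits the noiseless expected images plus a
per-cell table so recovery can be scored exactly.

Cells are kept non-overlapping with a 2-px exclusion gap so that
threshold-based segmentation sees one connected component per cell; no
point-spread blur is applied by default (an optional Gaussian blur can
stress segmentation).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .sensor import (
    DEFAULT_SENSOR,
    SensorParams,
    TitrationSeries,
    fp_intensity,
    ratio_response,
    sir_intensity,
)

__all__ = [
    "ChannelPair",
    "FOVConfig",
    "GroundTruth",
    "TimelapseProfile",
    "PRESETS",
    "NUCLEUS_CYCLE_PROFILE",
    "FLAT_PROFILE",
    "preset_config",
    "generate_fov",
    "generate_blank",
    "generate_timelapse",
    "generate_titration",
]


@dataclass(frozen=True)
class ChannelPair:
    """One FOV's two co-registered intensity images (photon-scale floats).

    ``fp`` is the GSH-insensitive reference channel (mGold or another
    fused FP); ``sir`` is the GSH-responsive TRaQ-G channel.  Row-major,
    0-based pixel indexing.
    """

    fp: np.ndarray
    sir: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.fp, dtype=np.float64)
        sir = np.asarray(self.sir, dtype=np.float64)
        if fp.ndim != 2 or fp.shape != sir.shape:
            raise ValueError(
                f"channel shapes differ or are not 2-D: fp {fp.shape}, sir {sir.shape}"
            )
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(sir))):
            raise ValueError("channel images must be finite")
        object.__setattr__(self, "fp", fp)
        object.__setattr__(self, "sir", sir)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fp.shape


# population presets: mean, sd of [GSH] in mM as measured per compartment
PRESETS: dict[str, tuple[float, float]] = {
    "nucleus": (14.0, 6.7),
    "whole_cell": (18.9, 9.4),
    "er": (9.2, 5.3),
    "mitochondria": (4.8, 0.7),
}


@dataclass(frozen=True)
class FOVConfig:
    """Everything needed to render one synthetic FOV reproducibly."""

    height_px: int = 256
    width_px: int = 256
    n_cells: int = 15
    radius_px_range: tuple[float, float] = (8.0, 14.0)
    gsh_dist: Literal["truncnorm", "lognormal"] = "truncnorm"
    gsh_mean_mM: float = 14.0
    gsh_sd_mM: float = 6.7
    expression_median: float = 1.0
    expression_sigma: float = 0.4
    background_fp: float = 20.0
    background_sir: float = 20.0
    read_noise_sd: float = 3.0
    exposure_scale: float = 1.0
    border_margin_px: int = 16
    shot_noise: bool = True
    gsh_insensitive: bool = False
    blur_sigma: float = 0.0
    nucleus_fraction: float = 0.0
    nucleus_gsh_offset_mM: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 64 or self.width_px < 64:
            raise ValueError("image dimensions must be at least 64 px")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        lo, hi = self.radius_px_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid radius range {self.radius_px_range}")
        if self.gsh_sd_mM < 0 or self.read_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.gsh_mean_mM < 0:
            raise ValueError("mean GSH must be non-negative")
        if self.background_fp < 0 or self.background_sir < 0:
            raise ValueError("backgrounds must be non-negative")
        if not 0.0 <= self.nucleus_fraction < 1.0:
            raise ValueError("nucleus_fraction must lie in [0, 1)")

    def replace(self, **kw) -> "FOVConfig":
        return dataclasses.replace(self, **kw)


def preset_config(name: str, **overrides) -> FOVConfig:
    """An :class:`FOVConfig` with the GSH distribution of a compartment preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    mean, sd = PRESETS[name]
    return FOVConfig(gsh_mean_mM=mean, gsh_sd_mM=sd, **overrides)


@dataclass
class GroundTruth:
    """Per-cell truth and the noiseless expected images of one FOV.

    ``cells`` columns: label, row, col (centroid), semi_a, semi_b,
    theta_rad, gsh_mM, expression, true_ratio (and gsh_nuc_mM when the
    two-compartment mode is on).
    """

    cells: pd.DataFrame
    expected_fp: np.ndarray
    expected_sir: np.ndarray
    n_requested: int
    n_placed: int
    warnings: list[str] = field(default_factory=list)


def _sample_gsh(rng: np.random.Generator, cfg: FOVConfig, n: int) -> np.ndarray:
    """Draw per-cell concentrations; negative-free by construction."""
    if cfg.gsh_sd_mM == 0:
        return np.full(n, cfg.gsh_mean_mM)
    if cfg.gsh_dist == "truncnorm":
        a = (0.0 - cfg.gsh_mean_mM) / cfg.gsh_sd_mM
        dist = stats.truncnorm(a, np.inf, loc=cfg.gsh_mean_mM, scale=cfg.gsh_sd_mM)
        return dist.rvs(size=n, random_state=rng)
    if cfg.gsh_dist == "lognormal":
        # match mean and sd of the lognormal to the preset moments
        m, s = cfg.gsh_mean_mM, cfg.gsh_sd_mM
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    raise ValueError(f"unknown gsh_dist {cfg.gsh_dist!r}")


def _ellipse_mask(
    shape: tuple[int, int],
    row: float,
    col: float,
    a: float,
    b: float,
    theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates inside a rotated ellipse (rr, cc)."""
    rmax = max(a, b)
    r0 = max(int(math.floor(row - rmax)) - 1, 0)
    r1 = min(int(math.ceil(row + rmax)) + 2, shape[0])
    c0 = max(int(math.floor(col - rmax)) - 1, 0)
    c1 = min(int(math.ceil(col + rmax)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - row
    dc = cc - col
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


_PLACEMENT_GAP_PX = 2.0  # exclusion gap so adjacent cells never touch


def _place_cells(rng: np.random.Generator, cfg: FOVConfig):
    """Rejection-sample non-overlapping ellipses inside the border margin."""
    shape = (cfg.height_px, cfg.width_px)
    occupied = np.zeros(shape, dtype=bool)
    placed = []
    lo, hi = cfg.radius_px_range
    m = cfg.border_margin_px
    for _ in range(cfg.n_cells):
        for _attempt in range(1000):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, math.pi)
            rmax = max(a, b)
            r_lo, r_hi = m + rmax, cfg.height_px - m - rmax
            c_lo, c_hi = m + rmax, cfg.width_px - m - rmax
            if r_hi <= r_lo or c_hi <= c_lo:
                break  # image too small for this radius draw; re-draw radii
            row = rng.uniform(r_lo, r_hi)
            col = rng.uniform(c_lo, c_hi)
            grr, gcc = _ellipse_mask(
                shape, row, col, a + _PLACEMENT_GAP_PX, b + _PLACEMENT_GAP_PX, theta
            )
            if occupied[grr, gcc].any():
                continue
            rr, cc = _ellipse_mask(shape, row, col, a, b, theta)
            if rr.size == 0:
                continue
            occupied[grr, gcc] = True
            placed.append((row, col, a, b, theta, rr, cc))
            break
    return placed


def _apply_camera(
    rng: np.random.Generator, expected: np.ndarray, cfg: FOVConfig
) -> np.ndarray:
    """Poisson shot noise, then Gaussian read noise, then clip at zero."""
    img = expected
    if cfg.shot_noise:
        img = rng.poisson(expected).astype(np.float64)
    else:
        img = img.copy()
    if cfg.read_noise_sd > 0:
        img += rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)
    return img


def generate_fov(
    config: FOVConfig,
    params: SensorParams = DEFAULT_SENSOR,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelPair, np.ndarray, GroundTruth]:
    """Render one synthetic FOV.

    Returns the noisy channel pair, the true label map (uint16, labels
    1..n in placement order) and the :class:`GroundTruth`.  Identical
    config and seed give byte-identical arrays.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = (config.height_px, config.width_px)
    placed = _place_cells(rng, config)
    n_placed = len(placed)
    warnings: list[str] = []
    if n_placed < config.n_cells:
        warnings.append(
            f"placed only {n_placed} of {config.n_cells} requested cells "
            "(packing infeasible at this density)"
        )

    gsh = _sample_gsh(rng, config, n_placed)
    expression = rng.lognormal(
        math.log(config.expression_median), config.expression_sigma, size=n_placed
    )

    expected_fp = np.full(shape, float(config.background_fp))
    expected_sir = np.full(shape, float(config.background_sir))
    labels = np.zeros(shape, dtype=np.uint16)
    records = []
    two_compartment = config.nucleus_fraction > 0.0
    for i, (row, col, a, b, theta, rr, cc) in enumerate(placed):
        label = i + 1
        g_cell = float(gsh[i])
        e_cell = float(expression[i]) * config.exposure_scale
        g_for_sir = 0.0 if config.gsh_insensitive else g_cell
        labels[rr, cc] = label
        expected_fp[rr, cc] += fp_intensity(e_cell, params)
        expected_sir[rr, cc] += sir_intensity(e_cell, g_for_sir, params)
        rec = {
            "label": label,
            "row": row,
            "col": col,
            "semi_a": a,
            "semi_b": b,
            "theta_rad": theta,
            "gsh_mM": g_cell,
            "expression": float(expression[i]),
            "true_ratio": ratio_response(g_for_sir, params),
        }
        if two_compartment:
            # inner concentric ellipse ("nucleus") at an offset concentration
            scale = math.sqrt(config.nucleus_fraction)
            nrr, ncc = _ellipse_mask(shape, row, col, a * scale, b * scale, theta)
            g_nuc = max(g_cell + config.nucleus_gsh_offset_mM, 0.0)
            g_nuc_sir = 0.0 if config.gsh_insensitive else g_nuc
            expected_sir[nrr, ncc] -= sir_intensity(e_cell, g_for_sir, params)
            expected_sir[nrr, ncc] += sir_intensity(e_cell, g_nuc_sir, params)
            rec["gsh_nuc_mM"] = g_nuc
        records.append(rec)

    if config.blur_sigma > 0:
        expected_fp = ndimage.gaussian_filter(expected_fp, config.blur_sigma)
        expected_sir = ndimage.gaussian_filter(expected_sir, config.blur_sigma)

    fp = _apply_camera(rng, expected_fp, config)
    sir = _apply_camera(rng, expected_sir, config)

    columns = [
        "label", "row", "col", "semi_a", "semi_b", "theta_rad",
        "gsh_mM", "expression", "true_ratio",
    ]
    if two_compartment:
        columns.append("gsh_nuc_mM")
    cells = pd.DataFrame(records, columns=columns)
    truth = GroundTruth(
        cells=cells,
        expected_fp=expected_fp,
        expected_sir=expected_sir,
        n_requested=config.n_cells,
        n_placed=n_placed,
        warnings=warnings,
    )
    return ChannelPair(fp=fp, sir=sir), labels, truth


def generate_blank(
    config: FOVConfig, rng: np.random.Generator | None = None
) -> ChannelPair:
    """A cell-free FOV: pure background plus camera noise."""
    pair, _, _ = generate_fov(config.replace(n_cells=0), rng=rng)
    return pair


# ---------------------------------------------------------------------------
# time lapse


@dataclass(frozen=True)
class TimelapseProfile:
    """Piecewise-linear population-mean GSH trajectory for a time lapse.

    ``breakpoints`` are (time_h, gsh_mM) knots; per-cell trajectories are
    the interpolated mean plus a fixed per-cell offset drawn once with SD
    ``cell_sd_mM``.  The default frame grid mirrors a 24 h experiment
    imaged every 30 min (49 frames including t = 0).
    """

    breakpoints: tuple[tuple[float, float], ...]
    frame_interval_h: float = 0.5
    n_frames: int = 49
    cell_sd_mM: float = 2.0

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.breakpoints]
        gs = [g for _, g in self.breakpoints]
        if len(ts) < 2 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("breakpoints need >= 2 strictly ascending times")
        if any(g < 0 for g in gs):
            raise ValueError("profile GSH values must be non-negative")
        if self.frame_interval_h <= 0 or self.n_frames < 1:
            raise ValueError("invalid frame grid")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h

    def mean_at(self, t_h) -> np.ndarray:
        ts = np.array([t for t, _ in self.breakpoints])
        gs = np.array([g for _, g in self.breakpoints])
        return np.interp(np.asarray(t_h, dtype=float), ts, gs)


# nuclear GSH over the cell cycle after release from S-phase block:
# slight rise in the first 1-2 h, steady decline through S phase, then a
# plateau through G2/M.  Magnitudes of rise/plateau are free parameters.
NUCLEUS_CYCLE_PROFILE = TimelapseProfile(
    breakpoints=((0.0, 14.0), (1.5, 15.0), (12.0, 7.0), (24.0, 7.0)),
)
# control-probe analogue: nothing happens
FLAT_PROFILE = TimelapseProfile(breakpoints=((0.0, 14.0), (24.0, 14.0)))


def generate_timelapse(
    config: FOVConfig,
    profile: TimelapseProfile,
    params: SensorParams = DEFAULT_SENSOR,
    drift_sd_px: float = 2.0,
    expression_drift_per_h: float = 0.0,
) -> Iterator[tuple[float, ChannelPair, np.ndarray, GroundTruth]]:
    """Yield (time_h, pair, labels, truth) frames with persistent cells.

    The same cells persist across frames: geometry is drawn once, then
    centroids random-walk with per-frame SD ``drift_sd_px`` (clipped to
    stay inside the border margin) and expression may drift linearly to
    emulate ongoing labelling of newly expressed protein.  Per-frame
    GSH is the profile mean plus each cell's fixed offset, floored at 0.
    """
    rng = np.random.default_rng(config.seed)
    base_cfg = config.replace(gsh_sd_mM=0.0)
    placed = _place_cells(rng, config)
    n = len(placed)
    offsets = rng.normal(0.0, profile.cell_sd_mM, size=n) if n else np.empty(0)
    expression = rng.lognormal(
        math.log(config.expression_median), config.expression_sigma, size=n
    )
    shape = (config.height_px, config.width_px)
    m = config.border_margin_px

    centres = np.array([[p[0], p[1]] for p in placed], dtype=float).reshape(n, 2)
    geom = [(p[2], p[3], p[4]) for p in placed]

    for k, t in enumerate(profile.times_h):
        if k > 0 and drift_sd_px > 0 and n:
            centres = centres + rng.normal(0.0, drift_sd_px, size=(n, 2))
        g_mean = float(profile.mean_at(t))
        expected_fp = np.full(shape, float(config.background_fp))
        expected_sir = np.full(shape, float(config.background_sir))
        labels = np.zeros(shape, dtype=np.uint16)
        records = []
        for i in range(n):
            a, b, theta = geom[i]
            rmax = max(a, b)
            row = float(np.clip(centres[i, 0], m + rmax, shape[0] - m - rmax))
            col = float(np.clip(centres[i, 1], m + rmax, shape[1] - m - rmax))
            centres[i] = (row, col)
            rr, cc = _ellipse_mask(shape, row, col, a, b, theta)
            g_cell = max(g_mean + float(offsets[i]), 0.0)
            e_cell = float(expression[i]) * (1.0 + expression_drift_per_h * t)
            e_cell = max(e_cell, 0.0) * config.exposure_scale
            g_for_sir = 0.0 if config.gsh_insensitive else g_cell
            labels[rr, cc] = i + 1
            expected_fp[rr, cc] += fp_intensity(e_cell, params)
            expected_sir[rr, cc] += sir_intensity(e_cell, g_for_sir, params)
            records.append(
                {
                    "label": i + 1,
                    "row": row,
                    "col": col,
                    "semi_a": a,
                    "semi_b": b,
                    "theta_rad": theta,
                    "gsh_mM": g_cell,
                    "expression": e_cell,
                    "true_ratio": ratio_response(g_for_sir, params),
                }
            )
        fp = _apply_camera(rng, expected_fp, base_cfg)
        sir = _apply_camera(rng, expected_sir, base_cfg)
        truth = GroundTruth(
            cells=pd.DataFrame(
                records,
                columns=[
                    "label", "row", "col", "semi_a", "semi_b", "theta_rad",
                    "gsh_mM", "expression", "true_ratio",
                ],
            ),
            expected_fp=expected_fp,
            expected_sir=expected_sir,
            n_requested=config.n_cells,
            n_placed=n,
            warnings=[],
        )
        yield float(t), ChannelPair(fp=fp, sir=sir), labels, truth


# ---------------------------------------------------------------------------
# titrations


def generate_titration(
    params: SensorParams,
    concs_mM: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    response_kind: Literal["sir_intensity", "fp_over_sir_ratio"] = "sir_intensity",
    expression: float = 1.0,
    offset: float = 0.0,
    n_replicates: int = 3,
) -> TitrationSeries:
    """Simulate a plate-reader titration with multiplicative noise.

    Responses are the sensor forward model evaluated at each
    concentration, perturbed by Gaussian noise with coefficient of
    variation ``noise_cv``; the reported response is the mean of
    ``n_replicates`` wells and per-point SDs are emitted.
    """
    concs = np.asarray(list(concs_mM), dtype=float)
    if concs.size > 1 and np.any(np.diff(concs) <= 0):
        raise ValueError("concentrations must be strictly ascending")
    rng = np.random.default_rng(seed)
    if response_kind == "sir_intensity":
        clean = sir_intensity(expression, concs, params) + offset
    else:
        clean = ratio_response(concs, params)
    if noise_cv > 0:
        reps = clean[:, None] * (
            1.0 + rng.normal(0.0, noise_cv, size=(concs.size, n_replicates))
        )
        resp = reps.mean(axis=1)
        sds = reps.std(axis=1, ddof=1)
    else:
        resp = clean.copy()
        sds = np.zeros_like(clean)
    return TitrationSeries(
        concentrations_mM=tuple(concs),
        responses=tuple(resp),
        replicate_sd=tuple(sds),
        response_kind=response_kind,
    )
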