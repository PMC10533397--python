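"""Forward models of the TRaQ-G glutathione sensor.

TRaQ-G is a chemogenetic sensor: a spirocyclic silicon-rhodamine (SiR)
ligand that becomes fluorescent and GSH-reactive only once covalently
captured by the HaloTag protein.  Reversible nucleophilic attack of GSH on
the SiR chromophore quenches the SiR channel, while a fused,
GSH-insensitive fluorescent protein (e.g. mGold) provides a constant
reference channel.  The FP/SiR intensity ratio therefore cancels
expression level and optical path and increases with GSH.

Two-state equilibrium model
---------------------------
With apparent dissociation constant ``kd`` (mM), the bound (quenched)
fraction of sensor at GSH concentration ``g`` is the Langmuir isotherm
``f = g / (kd + g)``.  Only the unbound fraction fluoresces in the SiR
channel, so the SiR intensity is proportional to ``1 / (1 + g/kd)`` and
the FP/SiR ratio is exactly affine in ``g``:

    R(g) = r0 * (1 + g / kd)

where ``r0`` is the ratio at zero GSH.  This linearity is what makes a
simple linear calibration curve valid over the physiological 1-20 mM
window.

Relaxation kinetics follow the pseudo-first-order approximation (sensor
at ~15 uM is vastly outnumbered by mM GSH): ``k_obs = kon*g + koff``.
The ``koff``-only limit corresponds to quenching the adduct with a thiol
scavenger such as N-ethylmaleimide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "SensorParams",
    "CalibrationCurve",
    "TitrationSeries",
    "TitrationModel",
    "TitrationResults",
    "bound_fraction",
    "ratio_response",
    "sir_intensity",
    "fp_intensity",
    "gsh_from_equivalents",
    "relaxation_rate",
    "relaxation_timecourse",
    "fit_titration",
    "round_half_up",
    "DEFAULT_SENSOR",
]

_REL_TOL = 1e-6  # relative tolerance for internal thermodynamic consistency


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python/numpy round half to even, which would turn 14.25 into 14.2;
    reported concentrations use the familiar half-up rule instead.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SensorParams:
    """Chemistry of one HaloTag-bound probe.

    Parameters
    ----------
    kd_mM : float
        Apparent dissociation constant of the GSH-sensor adduct, mM.
        The default of 10 mM centres the dynamic range on the
        physiological 1-20 mM window.
    r0 : float
        FP/SiR ratio at zero GSH (dimensionless, > 0).
    brightness_fp, brightness_sir0 : float
        Expected photons per expression unit per exposure for the FP
        reference channel, and for the SiR channel at zero GSH.  Their
        quotient must equal ``r0`` so that the imaging model and the
        chemistry agree.
    kon_per_mM_s, koff_per_s : float, optional
        Association / dissociation rate constants.  When both are set
        their quotient must reproduce ``kd_mM``.
    """

    kd_mM: float = 10.0
    r0: float = 0.5
    brightness_fp: float = 500.0
    brightness_sir0: float = 1000.0
    kon_per_mM_s: float | None = 0.01
    koff_per_s: float | None = 0.1

    def __post_init__(self) -> None:
        if not self.kd_mM > 0:
            raise ValueError(f"kd_mM must be positive, got {self.kd_mM}")
        if not self.r0 > 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if self.brightness_fp < 0 or self.brightness_sir0 < 0:
            raise ValueError("brightness terms must be non-negative")
        if self.brightness_fp > 0 and self.brightness_sir0 > 0:
            implied = self.brightness_fp / self.brightness_sir0
            if abs(implied - self.r0) / self.r0 > _REL_TOL:
                raise ValueError(
                    f"brightness_fp/brightness_sir0 = {implied:g} disagrees "
                    f"with r0 = {self.r0:g}; the zero-GSH image ratio must "
                    "equal r0"
                )
        if self.kon_per_mM_s is not None and self.koff_per_s is not None:
            if self.kon_per_mM_s <= 0 or self.koff_per_s <= 0:
                raise ValueError("rate constants must be positive when set")
            kd_kin = self.koff_per_s / self.kon_per_mM_s
            if abs(kd_kin - self.kd_mM) / self.kd_mM > _REL_TOL:
                raise ValueError(
                    f"koff/kon = {kd_kin:g} mM is inconsistent with "
                    f"kd_mM = {self.kd_mM:g}"
                )

    def with_kd(self, kd_mM: float) -> "SensorParams":
        """Copy with a new kd; koff is rescaled to stay consistent."""
        koff = None if self.kon_per_mM_s is None else self.kon_per_mM_s * kd_mM
        return replace(self, kd_mM=kd_mM, koff_per_s=koff)


DEFAULT_SENSOR = SensorParams()


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map between the FP/SiR ratio and [GSH] in mM.

    ``ratio = slope * gsh_mM + intercept`` over the closed validity
    interval ``range_mM``.  Curves are pH specific; ``ph`` is carried as
    metadata and curves generated at different pH are distinct objects.
    """

    slope: float
    intercept: float
    range_mM: tuple[float, float] = (1.0, 20.0)
    r_squared: float = 1.0
    ph: float = 7.4

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        lo, hi = self.range_mM
        if lo < 0 or hi <= lo:
            raise ValueError(f"invalid validity range {self.range_mM}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def ratio_at(self, gsh_mM: float) -> float:
        return self.slope * gsh_mM + self.intercept

    def invert(self, ratio):
        """Map a ratio (scalar or array) back to mM GSH."""
        return (np.asarray(ratio, dtype=float) - self.intercept) / self.slope

    def in_range(self, gsh_mM) -> np.ndarray:
        g = np.asarray(gsh_mM, dtype=float)
        lo, hi = self.range_mM
        return (g >= lo) & (g <= hi)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "range_mM": list(self.range_mM),
            "r_squared": self.r_squared,
            "ph": self.ph,
            "units": {"slope": "ratio per mM", "intercept": "ratio", "range": "mM"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            range_mM=tuple(float(v) for v in d.get("range_mM", (1.0, 20.0))),
            r_squared=float(d.get("r_squared", 1.0)),
            ph=float(d.get("ph", 7.4)),
        )


@dataclass(frozen=True)
class TitrationSeries:
    """One plate-reader titration: response vs GSH concentration."""

    concentrations_mM: tuple[float, ...]
    responses: tuple[float, ...]
    replicate_sd: tuple[float, ...] | None = None
    response_kind: Literal["sir_intensity", "fp_over_sir_ratio"] = "sir_intensity"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_mM, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.ndim != 1 or c.size != r.size:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly ascending")
        if self.replicate_sd is not None and len(self.replicate_sd) != c.size:
            raise ValueError("replicate_sd length mismatch")
        object.__setattr__(self, "concentrations_mM", tuple(float(v) for v in c))
        object.__setattr__(self, "responses", tuple(float(v) for v in r))

    def __len__(self) -> int:
        return len(self.concentrations_mM)


# ---------------------------------------------------------------------------
# equilibrium model


def bound_fraction(gsh_mM, kd_mM: float):
    """Fraction of sensor carrying the GSH adduct at equilibrium.

    Langmuir isotherm ``g / (kd + g)``; monotone in ``g`` and < 1.
    """
    g = np.asarray(gsh_mM, dtype=float)
    if np.any(g < 0):
        raise ValueError("GSH concentration must be non-negative")
    if not kd_mM > 0:
        raise ValueError("kd_mM must be positive")
    out = g / (kd_mM + g)
    return float(out) if np.isscalar(gsh_mM) else out


def ratio_response(gsh_mM, params: SensorParams = DEFAULT_SENSOR):
    """Expected FP/SiR ratio, ``r0 * (1 + g/kd)`` — exactly affine in g."""
    g = np.asarray(gsh_mM, dtype=float)
    if np.any(g < 0):
        raise ValueError("GSH concentration must be non-negative")
    out = params.r0 * (1.0 + g / params.kd_mM)
    return float(out) if np.isscalar(gsh_mM) else out


def sir_intensity(expression, gsh_mM, params: SensorParams = DEFAULT_SENSOR):
    """Expected SiR photons: ``E * brightness_sir0 / (1 + g/kd)``.

    GSH quenches the SiR chromophore, so the signal falls hyperbolically
    with concentration; at ``g = kd`` exactly half the zero-GSH signal
    remains.
    """
    e = np.asarray(expression, dtype=float)
    g = np.asarray(gsh_mM, dtype=float)
    if np.any(e < 0):
        raise ValueError("expression must be non-negative")
    if np.any(g < 0):
        raise ValueError("GSH concentration must be non-negative")
    out = e * params.brightness_sir0 / (1.0 + g / params.kd_mM)
    if np.isscalar(expression) and np.isscalar(gsh_mM):
        return float(out)
    return out


def fp_intensity(expression, params: SensorParams = DEFAULT_SENSOR):
    """Expected FP photons: ``E * brightness_fp``, independent of GSH."""
    e = np.asarray(expression, dtype=float)
    if np.any(e < 0):
        raise ValueError("expression must be non-negative")
    out = e * params.brightness_fp
    return float(out) if np.isscalar(expression) else out


def gsh_from_equivalents(
    total_equivalents_mM: float,
    gsh_to_gssg_ratio: float,
    gssg_equivalents: int = 2,
) -> float:
    """Reduced-GSH concentration implied by a total glutathione pool.

    A total pool ``T`` measured in GSH equivalents together with a molar
    GSH:GSSG ratio ``r`` gives ``[GSH] = T*r / (r + q)`` where ``q`` is
    the number of equivalents each GSSG carries.  The disulfide dimer
    holds two glutathione units, so ``q = 2`` by default (``q = 1``
    selects a molar-count convention instead).

    Example: a 19 mM total ER pool with a 6:1 ratio yields
    ``19*6/8 = 14.25`` mM, printed as 14.3 at one decimal.
    """
    if total_equivalents_mM < 0:
        raise ValueError("total glutathione must be non-negative")
    if not gsh_to_gssg_ratio > 0:
        raise ValueError("GSH:GSSG ratio must be positive")
    if gssg_equivalents not in (1, 2):
        raise ValueError("gssg_equivalents must be 1 or 2")
    r = gsh_to_gssg_ratio
    return total_equivalents_mM * r / (r + gssg_equivalents)


# ---------------------------------------------------------------------------
# kinetics


def relaxation_rate(gsh_mM: float, params: SensorParams = DEFAULT_SENSOR) -> float:
    """Pseudo-first-order relaxation rate ``k_obs = kon*g + koff`` (1/s).

    Valid when sensor concentration (tens of uM) is negligible against
    GSH (>= 1 mM).  At ``g = 0`` this is the pure dissociation rate —
    the regime after quenching free GSH with N-ethylmaleimide.
    """
    if params.kon_per_mM_s is None or params.koff_per_s is None:
        raise ValueError("kon/koff are not set on these sensor parameters")
    if gsh_mM < 0:
        raise ValueError("GSH concentration must be non-negative")
    return params.kon_per_mM_s * gsh_mM + params.koff_per_s


def relaxation_timecourse(
    t_s,
    gsh_mM: float,
    params: SensorParams = DEFAULT_SENSOR,
    f0: float = 0.0,
):
    """Bound fraction vs time under pseudo-first-order kinetics.

    ``f(t) = f_eq + (f0 - f_eq) * exp(-k_obs t)`` with
    ``f_eq = kon*g / k_obs`` — which coincides with the equilibrium
    isotherm ``bound_fraction(g, koff/kon)``.
    """
    k = relaxation_rate(gsh_mM, params)
    f_eq = params.kon_per_mM_s * gsh_mM / k
    t = np.asarray(t_s, dtype=float)
    out = f_eq + (f0 - f_eq) * np.exp(-k * t)
    return float(out) if np.isscalar(t_s) else out


# ---------------------------------------------------------------------------
# titration fitting


def _turnoff_model(g, kd, f0, c):
    return f0 / (1.0 + g / kd) + c


def _ratio_model(g, kd, r0):
    return r0 * (1.0 + g / kd)


class TitrationModel:
    """Nonlinear least-squares model for a GSH titration.

    Two response models are supported:

    ``turnoff``
        SiR fluorescence ``F(g) = F0 / (1 + g/kd) + c`` — the raw
        quenching curve of the SiR channel (plate-reader titrations).
    ``ratio``
        FP/SiR ratio ``R(g) = r0 * (1 + g/kd)`` — the ratiometric
        readout, affine in g.

    Weighting is relative (sigma proportional to the model response) by
    default because plate-reader noise scales with signal; pass
    ``weighting='absolute'`` for unweighted residuals.

    Examples
    --------
    >>> fit = TitrationModel(series, kind="turnoff").fit()
    >>> fit.params["kd_mM"], fit.bse["kd_mM"]
    """

    def __init__(
        self,
        series: TitrationSeries,
        kind: Literal["turnoff", "ratio"] = "turnoff",
        weighting: Literal["relative", "absolute"] = "relative",
    ):
        if kind not in ("turnoff", "ratio"):
            raise ValueError(f"unknown titration model {kind!r}")
        if len(series) < 4:
            raise ValueError("need at least 4 titration points")
        self.series = series
        self.kind = kind
        self.weighting = weighting

    def _initial_guess(self, g: np.ndarray, y: np.ndarray) -> list[float]:
        span = float(y.max() - y.min())
        kd0 = float(np.median(g[g > 0])) if np.any(g > 0) else 1.0
        if self.kind == "turnoff":
            return [kd0, max(span, 1e-12), float(y.min())]
        return [kd0, max(float(y[np.argmin(g)]), 1e-12)]

    def fit(self) -> "TitrationResults":
        g = np.asarray(self.series.concentrations_mM)
        y = np.asarray(self.series.responses)
        if np.ptp(y) <= 1e-12 * max(abs(float(y[0])), 1.0):
            raise RuntimeError(
                "degenerate titration: response is constant across "
                "concentrations (GSH-insensitive probe?)"
            )
        model = _turnoff_model if self.kind == "turnoff" else _ratio_model
        p0 = self._initial_guess(g, y)
        sigma = None
        if self.weighting == "relative":
            sigma = np.maximum(np.abs(y), 1e-12 * np.abs(y).max())
        names = (
            ["kd_mM", "f0", "offset"] if self.kind == "turnoff" else ["kd_mM", "r0"]
        )
        converged = True
        message = "converged"
        try:
            popt, pcov = optimize.curve_fit(
                model, g, y, p0=p0, sigma=sigma, absolute_sigma=False,
                maxfev=20000,
            )
        except RuntimeError as err:  # non-convergence is flagged, never silent
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((len(p0), len(p0)), np.inf)
            converged = False
            message = str(err)
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(pcov))
        resid = y - model(g, *popt)
        if not np.all(np.isfinite(bse)):
            converged = converged and False
            message = message if message != "converged" else (
                "covariance not estimable (flat or unidentifiable response)"
            )
        return TitrationResults(
            model=self,
            params=dict(zip(names, map(float, popt))),
            bse=dict(zip(names, map(float, bse))),
            rss=float(resid @ resid),
            residuals=resid,
            converged=converged,
            message=message,
        )


@dataclass
class TitrationResults:
    """Point estimates, asymptotic SEs and diagnostics of a titration fit."""

    model: TitrationModel
    params: dict[str, float]
    bse: dict[str, float]
    rss: float
    residuals: np.ndarray
    converged: bool
    message: str

    @property
    def kd_mM(self) -> float:
        return self.params["kd_mM"]

    def conf_int(self, name: str = "kd_mM", nsigma: float = 1.96) -> tuple[float, float]:
        p, se = self.params[name], self.bse[name]
        return (p - nsigma * se, p + nsigma * se)

    def to_sensor_params(self, base: SensorParams = DEFAULT_SENSOR) -> SensorParams:
        """Sensor parameters with the fitted kd grafted onto ``base``."""
        return base.with_kd(self.kd_mM)

    def summary(self) -> str:
        lines = [
            "GSH titration fit",
            "=" * 46,
            f"model:      {self.model.kind}",
            f"weighting:  {self.model.weighting}",
            f"n points:   {len(self.model.series)}",
            f"converged:  {self.converged} ({self.message})",
            f"RSS:        {self.rss:.6g}",
            "-" * 46,
            f"{'param':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name in self.params:
            lines.append(f"{name:<10}{self.params[name]:>14.6g}{self.bse[name]:>14.6g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data, fitted curve and residual band on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = np.asarray(self.model.series.concentrations_mM)
        y = np.asarray(self.model.series.responses)
        ax.plot(g, y, "o", label="data")
        gg = np.linspace(g.min(), g.max(), 200)
        fn = _turnoff_model if self.model.kind == "turnoff" else _ratio_model
        ax.plot(gg, fn(gg, *self.params.values()), "-", label="fit")
        ax.set_xlabel("[GSH] (mM)")
        ax.set_ylabel("response")
        ax.legend()
        return ax


def fit_titration(
    series: TitrationSeries,
    model: Literal["turnoff", "ratio"] = "turnoff",
    weighting: Literal["relative", "absolute"] = "relative",
) -> TitrationResults:
    """Fit a titration series; see :class:`TitrationModel`."""
    return TitrationModel(series, kind=model, weighting=weighting).fit()
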