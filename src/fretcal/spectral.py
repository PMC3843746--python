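"""Sensitized emission, proximity ratio, calibration and Förster conversions.

The FRET-channel signal of a cluster mixes three contributions: true
sensitized emission (acceptor photons emitted because of energy transfer),
donor bleed-through (a fraction ``alpha`` of the donor-channel signal that
leaks into the acceptor emission window) and acceptor cross-excitation
(a fraction ``beta`` of the acceptor-channel signal excited directly at
the donor wavelength).  With ``alpha`` and ``beta`` estimated from
single-label control strains,

    SE = I_fret - alpha * I_donor - beta * I_acceptor
    PR = SE / (alpha * I_donor + beta * I_acceptor)

The proximity ratio PR is exposure-invariant (scaling all three channels by
a common factor cancels) and relates to the classical ``FRET_R`` metric as
``FRET_R - 1``.  Donor quenching in strains with and without acceptors
yields an absolute FRET efficiency, and an ordinary least-squares line
``E = slope * PR + intercept`` calibrates PR against E.  Efficiencies
convert to donor-acceptor separations through the Förster equation
``E = 1 / (1 + (R/R0)^6)``, optionally corrected for incomplete acceptor
chromophore maturation (dark acceptors dilute the apparent efficiency).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .types import (
    ClusterMeasurement,
    DomainError,
    InvalidInputError,
    SingularFitError,
    UndefinedRatioError,
)

__all__ = [
    "SpectralCoefficients",
    "FretQuantification",
    "EfficiencyEstimate",
    "ForsterParams",
    "CalibrationResult",
    "ProximityCalibration",
    "estimate_spectral_coefficients",
    "compute_sensitized_emission",
    "compute_proximity_ratio",
    "efficiency_from_donor_quenching",
    "fit_calibration",
    "efficiency_from_proximity_ratio",
    "forster_distance",
    "forster_efficiency",
    "correct_for_maturation",
    "gfp_mcherry_defaults",
]


@dataclass
class SpectralCoefficients:
    """Donor bleed-through (alpha) and acceptor cross-excitation (beta).

    ``alpha`` is FRET-channel counts per donor-channel count measured in
    donor-only cells; ``beta`` likewise per acceptor-channel count in
    acceptor-only cells.  ``*_sem`` are standard errors of the per-cluster
    ratio means.
    """

    alpha: float
    beta: float
    alpha_sem: float = 0.0
    beta_sem: float = 0.0
    n_donor_controls: int = 0
    n_acceptor_controls: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1 and 0 <= self.beta < 1):
            raise InvalidInputError("alpha and beta must lie in [0, 1)")
        if self.alpha_sem < 0 or self.beta_sem < 0:
            raise InvalidInputError("standard errors must be >= 0")

    def to_dict(self) -> dict:
        return {"type": "SpectralCoefficients", **asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralCoefficients":
        d = {k: v for k, v in d.items() if k != "type"}
        return cls(**d)


@dataclass
class FretQuantification:
    """Sensitized emission and proximity ratio of one cluster."""

    sensitized_emission: float
    proximity_ratio: float
    contamination_denominator: float


@dataclass
class EfficiencyEstimate:
    """Donor-quenching FRET efficiency of a strain/phase population."""

    efficiency: float
    sd: float
    n_fret_cells: int
    n_donor_only_cells: int
    phase: str = "metaphase"
    negative_flag: bool = False


@dataclass
class ForsterParams:
    """Parameters of the Förster conversion for one dye pair.

    ``kappa_squared_assumption`` documents the orientation factor assumed
    for the tabulated ``r0_nm`` (2/3 for isotropic fluorophore rotation);
    no anisotropy computation is performed here — it is provenance only.
    ``maturation_fraction`` is the fraction of acceptor proteins carrying a
    functional chromophore.
    """

    r0_nm: float = 5.0
    kappa_squared_assumption: float = 0.66
    maturation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.r0_nm <= 0:
            raise InvalidInputError("r0_nm must be positive")
        if not (0 < self.maturation_fraction <= 1):
            raise InvalidInputError("maturation_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {"type": "ForsterParams", **asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ForsterParams":
        return cls(**{k: v for k, v in d.items() if k != "type"})


def _ratio_stats(ratios: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(ratios))
    sem = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    return mean, sem


def estimate_spectral_coefficients(
    donor_only: Sequence[ClusterMeasurement],
    acceptor_only: Sequence[ClusterMeasurement],
    method: str = "ratio_mean",
) -> SpectralCoefficients:
    """Estimate alpha / beta from single-label control cluster measurements.

    ``ratio_mean`` (default) averages per-cluster ratios I_fret/I_channel,
    the estimator consistent with a "fraction +/- sem" contamination figure;
    ``regression`` fits a line through the origin instead.  Clusters with a
    zero (or negative) denominator are excluded with a warning.
    """
    if not donor_only or not acceptor_only:
        raise InvalidInputError("both control lists must be non-empty")

    def collect(ms: Sequence[ClusterMeasurement], denom_key: str) -> np.ndarray:
        num, den = [], []
        for m in ms:
            d = m.intensities[denom_key]
            if d <= 0:
                warnings.warn(
                    f"cluster {m.cell_id!r}: non-positive {denom_key} intensity excluded "
                    "from coefficient estimation",
                    stacklevel=3,
                )
                continue
            num.append(m.intensities["fret"])
            den.append(d)
        if not num:
            raise InvalidInputError(f"no usable {denom_key}-only control clusters")
        return np.asarray(num), np.asarray(den)

    fd, dd = collect(donor_only, "donor")
    fa, da = collect(acceptor_only, "acceptor")
    if method == "ratio_mean":
        alpha, a_sem = _ratio_stats(fd / dd)
        beta, b_sem = _ratio_stats(fa / da)
    elif method == "regression":
        alpha = float(np.dot(fd, dd) / np.dot(dd, dd))
        beta = float(np.dot(fa, da) / np.dot(da, da))
        a_sem = float(np.std(fd / dd, ddof=1) / math.sqrt(len(dd))) if len(dd) > 1 else 0.0
        b_sem = float(np.std(fa / da, ddof=1) / math.sqrt(len(da))) if len(da) > 1 else 0.0
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return SpectralCoefficients(
        alpha=alpha,
        beta=beta,
        alpha_sem=a_sem,
        beta_sem=b_sem,
        n_donor_controls=len(dd),
        n_acceptor_controls=len(da),
    )


def compute_sensitized_emission(
    m: ClusterMeasurement, c: SpectralCoefficients
) -> float:
    """FRET-channel counts minus bleed-through and cross-excitation.

    May be negative for no-FRET clusters; negative values are kept so
    population means stay unbiased.
    """
    return m["fret"] - c.alpha * m["donor"] - c.beta * m["acceptor"]


def compute_proximity_ratio(
    m: ClusterMeasurement, c: SpectralCoefficients
) -> FretQuantification:
    """Sensitized emission normalized by the summed contamination signals."""
    denom = c.alpha * m["donor"] + c.beta * m["acceptor"]
    if denom <= 0:
        raise UndefinedRatioError(
            f"cluster {m.cell_id!r}: contamination denominator {denom} is not positive"
        )
    se = compute_sensitized_emission(m, c)
    return FretQuantification(
        sensitized_emission=se,
        proximity_ratio=se / denom,
        contamination_denominator=denom,
    )


def efficiency_from_donor_quenching(
    fret_strain_donor_intensities: Iterable[float],
    donor_only_intensities: Iterable[float],
    phase: str = "metaphase",
) -> EfficiencyEstimate:
    """FRET efficiency from donor quenching: E = 1 - mean(FRET strain) / mean(donor only).

    The uncertainty propagates the standard errors of the two sample means
    through the first-order formula for a ratio of means:
    ``sd(r) = r * sqrt((sem_A/mean_A)^2 + (sem_B/mean_B)^2)``.
    """
    a = np.asarray(list(fret_strain_donor_intensities), dtype=float)
    b = np.asarray(list(donor_only_intensities), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both intensity lists must be non-empty")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_b <= 0:
        raise InvalidInputError("donor-only mean intensity must be positive")
    r = mean_a / mean_b
    sem_a = float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0
    sem_b = float(b.std(ddof=1) / math.sqrt(b.size)) if b.size > 1 else 0.0
    sd = abs(r) * math.sqrt((sem_a / mean_a) ** 2 + (sem_b / mean_b) ** 2) if mean_a != 0 else 0.0
    e = 1.0 - r
    negative = e < 0
    if negative:
        warnings.warn(
            f"negative donor-quenching efficiency ({e:.4f}); reported unclipped",
            stacklevel=2,
        )
    return EfficiencyEstimate(
        efficiency=e,
        sd=sd,
        n_fret_cells=int(a.size),
        n_donor_only_cells=int(b.size),
        phase=phase,
        negative_flag=bool(negative),
    )


@dataclass
class CalibrationResult:
    """Fitted proximity-ratio -> efficiency line with OLS uncertainties.

    ``predict(pr)`` maps a proximity ratio to an efficiency.  95% confidence
    intervals come from the t-distribution with ``n_points - 2`` degrees of
    freedom; with exactly two points they are unbounded.
    """

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    n_points: int
    weighted: bool = False
    points: tuple = field(default=(), repr=False)

    def predict(self, pr: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(pr) + self.intercept if np.ndim(pr) else (
            self.slope * float(pr) + self.intercept
        )

    def summary(self) -> str:
        lines = [
            "Proximity-ratio -> FRET-efficiency calibration (OLS)"
            + (" [weighted]" if self.weighted else ""),
            "-" * 56,
            f"n points            {self.n_points:>10d}",
            f"slope               {self.slope:>10.4f}  (se {self.slope_se:.4f})",
            f"  95% CI            [{self.ci95_slope[0]:.4f}, {self.ci95_slope[1]:.4f}]",
            f"intercept           {self.intercept:>10.4f}  (se {self.intercept_se:.4f})",
            f"  95% CI            [{self.ci95_intercept[0]:.4f}, {self.ci95_intercept[1]:.4f}]",
            f"R^2                 {self.r_squared:>10.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("points", None)
        d["ci95_slope"] = list(self.ci95_slope)
        d["ci95_intercept"] = list(self.ci95_intercept)
        return {"type": "CalibrationResult", **d}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        d = {k: v for k, v in d.items() if k != "type"}
        d["ci95_slope"] = tuple(d["ci95_slope"])
        d["ci95_intercept"] = tuple(d["ci95_intercept"])
        return cls(**d)

    def plot(self, ax=None):
        """Scatter the calibration points (if retained) and the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.points:
            pr, e = zip(*self.points)
            ax.plot(pr, e, "o", label="strain means")
            xs = np.linspace(min(pr), max(pr), 50)
        else:
            xs = np.linspace(0, 1, 50)
        ax.plot(xs, self.slope * xs + self.intercept, "k-", label="fit")
        ax.set_xlabel("proximity ratio")
        ax.set_ylabel("FRET efficiency")
        ax.legend()
        return ax


class ProximityCalibration:
    """Linear model of FRET efficiency against proximity ratio.

    Built from per-strain (PR, E) points — typically one point per
    calibration strain and cell-cycle phase.  ``fit()`` returns a
    :class:`CalibrationResult`.

    Parameters
    ----------
    proximity_ratios, efficiencies : array-like
        Matched abscissae/ordinates.  ``efficiencies`` may contain
        :class:`EfficiencyEstimate` objects; their ``efficiency`` (and, for
        the weighted fit, ``1/sd^2``) are used.
    """

    def __init__(self, proximity_ratios, efficiencies):
        pr = np.asarray([float(p) for p in proximity_ratios], dtype=float)
        eff, sds = [], []
        for e in efficiencies:
            if isinstance(e, EfficiencyEstimate):
                eff.append(e.efficiency)
                sds.append(e.sd)
            else:
                eff.append(float(e))
                sds.append(np.nan)
        if pr.size != len(eff):
            raise InvalidInputError("proximity_ratios and efficiencies differ in length")
        if pr.size < 2:
            raise InvalidInputError("at least 2 calibration points are required")
        self.pr = pr
        self.e = np.asarray(eff, dtype=float)
        self.sd = np.asarray(sds, dtype=float)

    @classmethod
    def from_points(cls, points) -> "ProximityCalibration":
        pr, e = zip(*points)
        return cls(pr, e)

    def fit(self, weighted: bool = False) -> CalibrationResult:
        x, y = self.pr, self.e
        n = x.size
        if np.ptp(x) == 0:
            raise SingularFitError("all proximity ratios identical: slope is undefined")
        if weighted:
            if np.any(~np.isfinite(self.sd)) or np.any(self.sd <= 0):
                raise InvalidInputError("weighted fit requires positive sd for every point")
            w = 1.0 / self.sd**2
        else:
            w = np.ones(n)
        sw = w.sum()
        xbar = float(np.dot(w, x) / sw)
        ybar = float(np.dot(w, y) / sw)
        sxx = float(np.dot(w, (x - xbar) ** 2))
        sxy = float(np.dot(w, (x - xbar) * (y - ybar)))
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        resid = y - (slope * x + intercept)
        ss_res = float(np.dot(w, resid**2))
        ss_tot = float(np.dot(w, (y - ybar) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        df = n - 2
        if df > 0:
            s2 = ss_res / df
            slope_se = math.sqrt(s2 / sxx)
            intercept_se = math.sqrt(s2 * (1.0 / sw + xbar**2 / sxx))
            tcrit = float(stats.t.ppf(0.975, df))
            ci_s = (slope - tcrit * slope_se, slope + tcrit * slope_se)
            ci_i = (intercept - tcrit * intercept_se, intercept + tcrit * intercept_se)
        else:  # two points: perfect interpolation, unbounded uncertainty
            slope_se = intercept_se = math.inf
            ci_s = (-math.inf, math.inf)
            ci_i = (-math.inf, math.inf)
        return CalibrationResult(
            slope=slope,
            intercept=intercept,
            r_squared=float(np.clip(r2, 0.0, 1.0)),
            slope_se=slope_se,
            intercept_se=intercept_se,
            ci95_slope=ci_s,
            ci95_intercept=ci_i,
            n_points=n,
            weighted=weighted,
            points=tuple(zip(x.tolist(), y.tolist())),
        )


def fit_calibration(points, weighted: bool = False) -> CalibrationResult:
    """OLS fit of efficiency on proximity ratio from (PR, E) points."""
    pr = [p for p, _ in points]
    e = [v for _, v in points]
    return ProximityCalibration(pr, e).fit(weighted=weighted)


def efficiency_from_proximity_ratio(pr: float, model: CalibrationResult) -> float:
    """Convert a proximity ratio to an efficiency through the calibration line.

    Values outside [0, 1) are flagged with a warning but not clipped.
    """
    e = model.slope * pr + model.intercept
    if not (0 <= e < 1):
        warnings.warn(
            f"calibrated efficiency {e:.4f} lies outside [0, 1); reported unclipped",
            stacklevel=2,
        )
    return e


def forster_distance(e: float, params: ForsterParams | None = None) -> float:
    """Donor-acceptor separation R = R0 * ((1 - E) / E)^(1/6) in nm."""
    params = params or ForsterParams()
    if not (0 < e < 1):
        raise DomainError(f"efficiency must lie strictly in (0, 1); got {e}")
    return params.r0_nm * ((1.0 - e) / e) ** (1.0 / 6.0)


def forster_efficiency(r_nm: float, params: ForsterParams | None = None) -> float:
    """FRET efficiency E = 1 / (1 + (R/R0)^6); exact inverse of forster_distance."""
    params = params or ForsterParams()
    if r_nm <= 0:
        raise DomainError(f"separation must be positive; got {r_nm}")
    return 1.0 / (1.0 + (r_nm / params.r0_nm) ** 6)


def correct_for_maturation(e_apparent: float, params: ForsterParams) -> float:
    """Rescale an apparent efficiency for incomplete acceptor maturation.

    Dark (immature) acceptors leave a fraction of donors unquenched, so the
    population-average efficiency under-reports the true per-pair value by
    the maturation fraction: E_true = E_apparent / maturation_fraction.
    """
    if e_apparent < 0:
        raise DomainError(f"apparent efficiency must be >= 0; got {e_apparent}")
    e_true = e_apparent / params.maturation_fraction
    if e_true >= 1:
        raise DomainError(
            f"maturation-corrected efficiency {e_true:.4f} >= 1; "
            "check maturation_fraction"
        )
    return e_true


def gfp_mcherry_defaults() -> dict:
    """Published default parameter set for the GFP(S65T)/mCherry pair.

    Returns the spectral coefficients, calibration line and Förster
    parameters measured on the budding-yeast kinetochore calibration
    strains; every entry can be overridden by re-estimating on new data.
    """
    return {
        "coefficients": SpectralCoefficients(
            alpha=0.058, beta=0.061, alpha_sem=0.0001, beta_sem=0.0002
        ),
        "calibration": CalibrationResult(
            slope=0.1355,
            intercept=0.002,
            r_squared=0.98,
            slope_se=math.nan,
            intercept_se=math.nan,
            ci95_slope=(math.nan, math.nan),
            ci95_intercept=(math.nan, math.nan),
            n_points=6,
        ),
        "forster": ForsterParams(r0_nm=5.0, kappa_squared_assumption=0.66,
                                 maturation_fraction=0.30),
    }
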