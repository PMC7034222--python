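"""Reduction of the bench flow experiments and hydrogel swelling data.

The flow experiments record, per nanoparticle formulation and inlet mass
concentration (7 levels, 3 replicates each), the transit time through the
channel and the inlet/outlet nanoparticle masses.  This module derives

* mean transit velocity  v = L / t  (reported in cm/s, the bench unit),
* mass-loss percentage  100 (m_in - m_out) / m_in,
* least-squares trend fits (linear / quadratic / cubic / general
  polynomial / power) with the multiple correlation coefficient R
  (sign-preserving square root of the coefficient of determination between
  fitted and observed response),
* per-concentration and overall size-vs-mass-loss correlation reports,
* the hydrogel swelling ratio  100 (W_swollen - W_dry) / W_dry.

Replicates are averaged per condition before trend fitting, matching how
per-condition averages with standard-deviation error bars are analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataQualityError, InvalidInputError
from .physical import Channel

FLOW_TABLE_COLUMNS = ["formulation", "size_nm", "inlet_amount_g", "replicate",
                      "transit_time_s", "inlet_mass_g", "outlet_mass_g"]

SWELLING_COLUMNS = ["sample", "pH", "time_h", "dry_mg", "swollen_mg"]

#: polynomial degree per named family
_FAMILY_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}


def mean_velocity_from_transit(channel: Channel, transit_time: float) -> float:
    """Mean transit velocity L / t, in cm/s.

    The bench measurement records the time for the injected bolus to cover
    the channel length; velocities for the study channel fall in the
    0.47-0.64 cm/s range.
    """
    if not transit_time > 0.0:
        raise InvalidInputError(f"transit_time must be > 0, got {transit_time}")
    return channel.length * 100.0 / transit_time


def mass_loss_percent(inlet_mass: float, outlet_mass: float) -> float:
    """Percent mass lost in transit, 100 (m_in - m_out) / m_in.

    ``outlet_mass > inlet_mass`` is flagged as a data-quality error (never
    silently clipped): a heavier outlet than inlet means a weighing or
    transcription problem.
    """
    if not inlet_mass > 0.0:
        raise InvalidInputError(f"inlet_mass must be > 0, got {inlet_mass}")
    if outlet_mass < 0.0:
        raise InvalidInputError(f"outlet_mass must be >= 0, got {outlet_mass}")
    if outlet_mass > inlet_mass:
        raise DataQualityError(
            f"outlet mass {outlet_mass} g exceeds inlet mass {inlet_mass} g")
    return 100.0 * (inlet_mass - outlet_mass) / inlet_mass


@dataclass(frozen=True)
class FitResult:
    """A fitted trend and its quality-of-fit.

    ``correlation_R`` is NaN (with ``degenerate=True``) when the response
    has zero variance; batch analyses survive such inputs rather than
    raising.
    """

    family: str
    coefficients: np.ndarray = field(repr=False)
    correlation_R: float
    n_points: int
    degree: int | None = None
    group: str | None = None
    degenerate: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "power":
            a, b = self.coefficients
            return a * x**b
        return np.polyval(self.coefficients, x)


def _correlation_r(y: np.ndarray, y_fit: np.ndarray) -> tuple[float, bool]:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0.0:
        return float("nan"), True
    ss_res = float(np.sum((y - y_fit) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if r2 <= 0.0:
        return 0.0, False
    # sign from the fitted-vs-observed covariance (positive for any
    # least-squares fit with an intercept; preserved for completeness)
    sign = np.sign(float(np.cov(y, y_fit)[0, 1])) or 1.0
    return float(sign * np.sqrt(r2)), False


def fit_trend(x, y, family: str, degree: int | None = None) -> FitResult:
    """Least-squares trend fit in one of the study's model families.

    Parameters
    ----------
    x, y : array-like
        Predictor and response (replicate means, usually).
    family : {"linear", "quadratic", "cubic", "polynomial", "power"}
        ``polynomial`` requires ``degree``; ``power`` fits y = a x^b by
        ordinary least squares in log-log space (x, y > 0 required).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")

    if family == "power":
        if np.any(x <= 0.0) or np.any(y <= 0.0):
            raise InvalidInputError("power-family fits need strictly positive x and y")
        if len(x) < 3:
            raise InvalidInputError("power fit needs more points than coefficients")
        if np.ptp(y) == 0.0:
            return FitResult("power", np.array([y[0], 0.0]), float("nan"),
                             len(x), degenerate=True)
        b, log_a = np.polyfit(np.log(x), np.log(y), 1)
        coeffs = np.array([np.exp(log_a), b])
        y_fit = coeffs[0] * x ** coeffs[1]
        r, degen = _correlation_r(y, y_fit)
        return FitResult("power", coeffs, r, len(x), degenerate=degen)

    if family == "polynomial":
        if degree is None:
            raise InvalidInputError("polynomial family requires an explicit degree")
        deg = int(degree)
    elif family in _FAMILY_DEGREE:
        deg = _FAMILY_DEGREE[family]
    else:
        raise InvalidInputError(f"unknown fit family {family!r}")

    if len(x) <= deg:
        raise InvalidInputError(
            f"{family} fit (degree {deg}) needs more than {deg} points, got {len(x)}")
    if np.ptp(y) == 0.0:
        coeffs = np.zeros(deg + 1)
        coeffs[-1] = y[0] if len(y) else 0.0
        return FitResult(family, coeffs, float("nan"), len(x), degree=deg,
                         degenerate=True)
    if len(np.unique(x)) <= deg:
        raise InvalidInputError(
            f"singular design: only {len(np.unique(x))} distinct x for degree {deg}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polyfit(x, y, deg)
    r, degen = _correlation_r(y, np.polyval(coeffs, x))
    return FitResult(family, coeffs, r, len(x), degree=deg, degenerate=degen)


@dataclass
class FlowExperimentTable:
    """Replicate-level flow-experiment records (pandas-backed).

    Columns: formulation, size_nm, inlet_amount_g, replicate,
    transit_time_s, inlet_mass_g, outlet_mass_g.  Constraints checked at
    construction: positive transit times, outlet <= inlet per row, and a
    consistent replicate count per (formulation, inlet amount) condition.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FLOW_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"flow table missing columns: {missing}")
        df = self.data
        if (df["transit_time_s"] <= 0.0).any():
            raise DataQualityError("non-positive transit_time_s in flow table")
        bad = df["outlet_mass_g"] > df["inlet_mass_g"]
        if bad.any():
            rows = df.index[bad].tolist()
            raise DataQualityError(f"outlet mass exceeds inlet mass in rows {rows}")
        counts = df.groupby(["formulation", "inlet_amount_g"]).size()
        if counts.nunique() > 1:
            raise DataQualityError(
                f"uneven replicate counts per condition: {sorted(counts.unique())}")

    @classmethod
    def from_csv(cls, path) -> "FlowExperimentTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def n_replicates(self) -> int:
        return int(self.data.groupby(["formulation", "inlet_amount_g"]).size().iloc[0])

    def with_derived(self, channel: Channel) -> pd.DataFrame:
        """Rows augmented with velocity_cm_s and loss_percent."""
        df = self.data.copy()
        df["velocity_cm_s"] = channel.length * 100.0 / df["transit_time_s"]
        df["loss_percent"] = 100.0 * (df["inlet_mass_g"] - df["outlet_mass_g"]) / df["inlet_mass_g"]
        return df

    def condition_means(self, channel: Channel) -> pd.DataFrame:
        """Replicate means per (formulation, size, inlet amount) condition."""
        df = self.with_derived(channel)
        return (df.groupby(["formulation", "size_nm", "inlet_amount_g"], as_index=False)
                  [["velocity_cm_s", "loss_percent"]].mean())


#: minimum R^2 improvement for the quadratic to displace the linear family
QUADRATIC_IMPROVEMENT_THRESHOLD = 0.05


def size_correlation_report(table: FlowExperimentTable, channel: Channel,
                            grouping: str = "per-concentration") -> list[FitResult]:
    """Fit mean mass-loss%% vs particle size, per concentration or overall.

    For every group a linear and a quadratic fit are reported (the family
    ladder used for the size correlations); the better family is flagged by
    ordering — the first FitResult per group is the preferred one, chosen
    quadratic only when it improves R^2 by more than
    ``QUADRATIC_IMPROVEMENT_THRESHOLD``.  Groups with fewer than three
    distinct sizes are skipped with a warning, never dropped silently.
    """
    if grouping not in ("per-concentration", "overall"):
        raise InvalidInputError(f"unknown grouping {grouping!r}")
    means = table.condition_means(channel)
    if grouping == "overall":
        groups = [("overall",
                   means.groupby("size_nm", as_index=False)["loss_percent"].mean())]
    else:
        groups = [(f"inlet {amount:g} g", sub)
                  for amount, sub in means.groupby("inlet_amount_g")]

    results: list[FitResult] = []
    for label, sub in groups:
        sizes = sub.groupby("size_nm", as_index=False)["loss_percent"].mean()
        if len(sizes) < 3:
            warnings.warn(f"group {label!r} skipped: only {len(sizes)} distinct sizes",
                          stacklevel=2)
            continue
        x = sizes["size_nm"].to_numpy()
        y = sizes["loss_percent"].to_numpy()
        lin = fit_trend(x, y, "linear")
        fits = [FitResult("linear", lin.coefficients, lin.correlation_R,
                          lin.n_points, degree=1, group=label, degenerate=lin.degenerate)]
        if len(sizes) > 3:
            quad = fit_trend(x, y, "quadratic")
            qr = FitResult("quadratic", quad.coefficients, quad.correlation_R,
                           quad.n_points, degree=2, group=label,
                           degenerate=quad.degenerate)
            improvement = (0.0 if (qr.degenerate or lin.degenerate)
                           else qr.correlation_R**2 - lin.correlation_R**2)
            if improvement > QUADRATIC_IMPROVEMENT_THRESHOLD:
                fits.insert(0, qr)
            else:
                fits.append(qr)
        results.extend(fits)
    return results


@dataclass(frozen=True)
class SwellingRecord:
    """One hydrogel swelling measurement (weights in mg, time in h)."""

    dry_weight: float
    swollen_weight: float
    time: float = 0.0
    pH: float = 7.0

    def __post_init__(self) -> None:
        if not self.dry_weight > 0.0:
            raise InvalidInputError(f"dry weight must be > 0, got {self.dry_weight}")
        if self.swollen_weight < 0.0:
            raise InvalidInputError(f"swollen weight must be >= 0, got {self.swollen_weight}")
        if not 1.0 <= self.pH <= 13.0:
            raise InvalidInputError(f"pH must lie in [1, 13], got {self.pH}")


def swelling_ratio(record: SwellingRecord) -> float:
    """Extent of swelling W_t = 100 (W_swollen - W_dry) / W_dry, percent."""
    return 100.0 * (record.swollen_weight - record.dry_weight) / record.dry_weight


def swelling_peak(times_h, ratios_percent) -> tuple[float, float]:
    """(time, ratio) of maximum swelling in a measured series."""
    times = np.asarray(times_h, dtype=float)
    ratios = np.asarray(ratios_percent, dtype=float)
    if times.size == 0:
        raise InvalidInputError("empty swelling series")
    k = int(np.argmax(ratios))
    return float(times[k]), float(ratios[k])
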