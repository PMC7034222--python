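"""Synthetic flow-experiment tables and swelling series.

Stands in for the study's replicate tables: for each nanoparticle
formulation x inlet mass concentration x replicate, a true transit
velocity (cm/s) and mass-loss percentage are drawn from configurable
trends (cubic-in-mass velocity, power/quadratic loss trends, etc.) plus
Gaussian replicate noise, then converted back to the measured quantities
(transit time = L/velocity, outlet mass = inlet mass (1 - loss/100)).
Defaults mirror the study design: four formulations of 69/130/140/144 nm,
seven inlet amounts spanning 2.008-5.24 g, three replicates.

Noise is truncated at the physical bounds by resampling (not clipping, so
the replicate moments stay honest); a *trend* whose true value is already
non-physical raises a GenerationError naming the offending condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidInputError
from .experiment import FlowExperimentTable
from .physical import Channel, NanoparticleFormulation, STUDY_FORMULATIONS

#: the seven inlet mass concentrations (g Fe in the 1 mL dose)
STUDY_INLET_AMOUNTS = tuple(np.round(np.linspace(2.008, 5.24, 7), 4))

#: default velocity trend: cubic in inlet amount, spanning the measured
#: 0.47-0.58 cm/s bench range over the seven amounts
DEFAULT_VELOCITY_COEFFS = (0.02633416, -0.2906807, 1.03454873, -0.64854212)

#: default loss trend: quadratic in particle size through the measured
#: per-formulation average losses (1.77/1.60/1.96/2.45 % at 69/130/140/144 nm)
DEFAULT_LOSS_COEFFS = (8.12312025e-04, -1.65198046e-01, 9.30243695e+00)


def default_velocity_trend(noise_sd: float = 0.02, n_replicates: int = 3,
                           rng_seed: int = 0) -> "TrendSpec":
    """Study-condition velocity trend (cubic in inlet mass, cm/s)."""
    return TrendSpec("cubic", DEFAULT_VELOCITY_COEFFS, noise_sd, n_replicates,
                     rng_seed, predictor="inlet_amount")


def default_loss_trend(noise_sd: float = 0.15, n_replicates: int = 3,
                       rng_seed: int = 1) -> "TrendSpec":
    """Study-condition loss trend (quadratic in size, percent)."""
    return TrendSpec("quadratic", DEFAULT_LOSS_COEFFS, noise_sd, n_replicates,
                     rng_seed, predictor="size_nm")


@dataclass(frozen=True)
class TrendSpec:
    """A generating trend: model family, coefficients, noise and replicates.

    ``family`` is one of {"linear", "quadratic", "cubic", "polynomial",
    "power"}; polynomial coefficients are in numpy's highest-degree-first
    order, power coefficients are (a, b) for a x^b.  ``predictor`` selects
    the design variable the trend is evaluated at: the inlet amount (g) or
    the particle size (nm).  ``noise_sd`` is in the units of the response
    (cm/s for velocity, percentage points for loss).
    """

    family: str
    coefficients: tuple = ()
    noise_sd: float = 0.0
    n_replicates: int = 3
    rng_seed: int = 0
    predictor: str = "inlet_amount"  # or "size_nm"

    def __post_init__(self) -> None:
        if self.noise_sd < 0.0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if self.predictor not in ("inlet_amount", "size_nm"):
            raise InvalidInputError(f"unknown predictor {self.predictor!r}")

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = np.asarray(self.coefficients, dtype=float)
        if self.family == "power":
            if len(c) != 2:
                raise InvalidInputError("power trend needs coefficients (a, b)")
            return c[0] * x ** c[1]
        if self.family in ("linear", "quadratic", "cubic", "polynomial"):
            return np.polyval(c, x)
        raise InvalidInputError(f"unknown trend family {self.family!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Formulations x inlet amounts x channel defining a synthetic study."""

    formulations: tuple[NanoparticleFormulation, ...] = STUDY_FORMULATIONS
    inlet_amounts: tuple[float, ...] = STUDY_INLET_AMOUNTS
    channel: Channel = field(default_factory=Channel.from_mm)

    def __post_init__(self) -> None:
        if len(self.formulations) < 1:
            raise InvalidInputError("design needs at least one formulation")
        amounts = np.asarray(self.inlet_amounts, dtype=float)
        if len(amounts) < 1 or np.any(np.diff(amounts) <= 0.0):
            raise InvalidInputError("inlet amounts must be strictly increasing")


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: float,
                      low: float, high: float, what: str) -> np.ndarray:
    """Gaussian draws resampled (not clipped) into (low, high)."""
    out = rng.normal(mean, sd)
    for _ in range(1000):
        bad = (out <= low) | (out >= high)
        if not bad.any():
            return out
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], sd)
    raise GenerationError(f"could not draw {what} inside ({low}, {high}); "
                          "trend mean too close to a physical bound for this noise_sd")


def generate_flow_experiments(design: StudyDesign, velocity_trend: TrendSpec,
                              loss_trend: TrendSpec) -> FlowExperimentTable:
    """Generate a replicate-level flow table from planted trends.

    Velocity (cm/s) and loss (%) means are the trends evaluated at each
    condition's predictor value; replicate noise is truncated-Gaussian.
    Determinism: the output is a pure function of the design and the two
    trend specs (seeds combined through a SeedSequence).

    Raises
    ------
    GenerationError
        If a trend's *mean* is non-physical at some condition (negative
        velocity, loss outside [0, 100]), naming that condition.
    """
    if velocity_trend.n_replicates != loss_trend.n_replicates:
        raise InvalidInputError("velocity and loss trends must agree on n_replicates")
    n_rep = velocity_trend.n_replicates
    rng = np.random.default_rng(
        np.random.SeedSequence([velocity_trend.rng_seed, loss_trend.rng_seed]))
    L_cm = design.channel.length * 100.0

    rows = []
    for np_form in design.formulations:
        size_nm = np_form.hydrodynamic_diameter * 1e9
        for amount in design.inlet_amounts:
            xv = amount if velocity_trend.predictor == "inlet_amount" else size_nm
            xl = amount if loss_trend.predictor == "inlet_amount" else size_nm
            v_true = float(velocity_trend.evaluate(xv))
            loss_true = float(loss_trend.evaluate(xl))
            cond = f"formulation {np_form.label!r} at inlet {amount} g"
            if v_true <= 0.0:
                raise GenerationError(f"velocity trend gives {v_true} cm/s for {cond}")
            if not 0.0 <= loss_true <= 100.0:
                raise GenerationError(f"loss trend gives {loss_true}% for {cond}")
            v = (_truncated_normal(rng, np.full(n_rep, v_true), velocity_trend.noise_sd,
                                   0.0, np.inf, "velocity")
                 if velocity_trend.noise_sd > 0 else np.full(n_rep, v_true))
            loss = (_truncated_normal(rng, np.full(n_rep, loss_true), loss_trend.noise_sd,
                                      0.0, 100.0, "loss")
                    if loss_trend.noise_sd > 0 else np.full(n_rep, loss_true))
            for rep in range(1, n_rep + 1):
                rows.append({
                    "formulation": np_form.label,
                    "size_nm": size_nm,
                    "inlet_amount_g": amount,
                    "replicate": rep,
                    "transit_time_s": L_cm / v[rep - 1],
                    "inlet_mass_g": amount,
                    "outlet_mass_g": amount * (1.0 - loss[rep - 1] / 100.0),
                })
    return FlowExperimentTable(pd.DataFrame(rows))


def generate_swelling_series(pH_levels, peak_ratio: float, peak_time: float,
                             disintegrate_after: float, noise_sd: float = 0.0,
                             rng_seed: int = 0, time_grid_h=None,
                             dry_weight_mg: float = 8.0) -> pd.DataFrame:
    """Rise-plateau-collapse hydrogel swelling series per pH level.

    The noiseless ratio curve rises smoothly to ``peak_ratio`` (%) at
    ``peak_time`` (h), declines gently on a plateau, and collapses to zero
    at ``disintegrate_after`` (h); records past disintegration carry
    ``disintegrated=True``.  Weights are reported as (dry, swollen) mg
    pairs so the analysis-side swelling ratio inverts the curve exactly.
    """
    if peak_ratio < 0.0:
        raise InvalidInputError(f"peak_ratio must be >= 0, got {peak_ratio}")
    if not peak_time < disintegrate_after:
        raise InvalidInputError("peak_time must precede disintegrate_after")
    if time_grid_h is None:
        # quarter-hour grid through 8 h; contains the study's 1.5/3.5/7 h landmarks
        time_grid_h = np.arange(0.0, 8.01, 0.25)
    times = np.asarray(time_grid_h, dtype=float)
    rng = np.random.default_rng(rng_seed)

    rows = []
    for ph in np.atleast_1d(pH_levels):
        for i, t in enumerate(times):
            if t <= peak_time:
                ratio = peak_ratio * np.sin(0.5 * np.pi * t / peak_time) ** 2
            elif t < disintegrate_after:
                frac = (t - peak_time) / (disintegrate_after - peak_time)
                ratio = peak_ratio * (1.0 - 0.2 * frac)  # gentle plateau decline
            else:
                ratio = 0.0
            disintegrated = t >= disintegrate_after
            if noise_sd > 0.0 and not disintegrated:
                ratio = float(_truncated_normal(rng, np.array([ratio]), noise_sd,
                                                -1e-9, np.inf, "swelling ratio")[0])
            rows.append({
                "sample": f"pH{ph:g}",
                "pH": float(ph),
                "time_h": float(t),
                "dry_mg": dry_weight_mg,
                "swollen_mg": dry_weight_mg * (1.0 + ratio / 100.0),
                "disintegrated": bool(disintegrated),
            })
    return pd.DataFrame(rows)
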