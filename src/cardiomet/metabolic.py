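"""Insulin-sensitivity (Kitt) estimation and caloric-intake bookkeeping.

Kitt, the rate constant of blood-glucose disappearance during an insulin
tolerance test, is obtained from the slope of a least-squares fit to the
linear phase of glucose decline: glucose falls exponentially after the
insulin bolus, so ln(glucose) is fitted over the 4-16 min window
(excluding the pre-injection t = 0 reading), the half-life is
t1/2 = ln(2)/k, and Kitt = 100 x 0.693 / t1/2 in %/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

#: Fit window for the linear phase of glucose decline, minutes (closed).
DEFAULT_WINDOW = (4.0, 16.0)

KCAL_PER_G_CHOW = 2.89
KCAL_PER_G_FRUCTOSE = 4.0


@dataclass
class KittResult:
    """Glucose-disappearance kinetics from one insulin tolerance test."""

    k_per_min: float        # decay rate constant (>= 0)
    t_half_min: float       # ln(2)/k; inf when not decaying
    kitt_pct_per_min: float  # 100 * 0.693 / t_half
    r_squared: float
    window: tuple[float, float]
    n_points: int
    decaying: bool          # False when the fitted slope is non-negative


@dataclass
class IntakeRecord:
    """Daily caloric intake from chow and fructose water."""

    chow_g: float
    fructose_g: float
    kcal_chow: float
    kcal_fructose: float
    total_kcal: float


class KittEstimator(BaseEstimator):
    """Kitt from an ITT glucose series, sklearn-style.

    Parameters
    ----------
    window : closed time window (min) of the linear decline phase
    fit_scale : "log" (default) — least-squares on ln(glucose), the scale on
        which exponential decay is linear; "raw" — a raw-scale linear fit
        variant, with t1/2 taken as the time for the fitted line to halve
        the first in-window reading.

    Attributes (after ``fit``)
    --------------------------
    k_, t_half_, kitt_, r_squared_, decaying_, result_
    """

    def __init__(self, window: tuple[float, float] = DEFAULT_WINDOW,
                 fit_scale: str = "log"):
        self.window = window
        self.fit_scale = fit_scale

    def fit(self, times_min: np.ndarray, glucose_mg_dl: np.ndarray):
        t = np.asarray(times_min, dtype=float)
        g = np.asarray(glucose_mg_dl, dtype=float)
        if t.shape != g.shape:
            raise ValueError("times and glucose must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(g <= 0):
            raise ValueError("glucose readings must be positive")
        lo, hi = self.window
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 3:
            raise ValueError(f"need >= 3 readings in the {lo}-{hi} min window")
        tw, gw = t[sel], g[sel]

        if self.fit_scale == "log":
            y = np.log(gw)
            slope, intercept = np.polyfit(tw, y, 1)
            k = -slope
            resid = y - (slope * tw + intercept)
        elif self.fit_scale == "raw":
            # fractional decline rate: raw-scale slope over the window mean
            slope, intercept = np.polyfit(tw, gw, 1)
            k = -slope / float(gw.mean())
            resid = gw - (slope * tw + intercept)
            y = gw
        else:
            raise ValueError(f"unknown fit_scale {self.fit_scale!r}")

        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

        decaying = bool(k > 1e-12)  # slopes at float-noise level are "no decay"
        t_half = math.log(2.0) / k if decaying else math.inf
        kitt_val = 100.0 * 0.693 / t_half if decaying else 0.0

        self.k_ = max(k, 0.0)
        self.t_half_ = t_half
        self.kitt_ = kitt_val
        self.r_squared_ = r2
        self.decaying_ = decaying
        self.result_ = KittResult(
            k_per_min=self.k_, t_half_min=t_half, kitt_pct_per_min=kitt_val,
            r_squared=r2, window=(lo, hi), n_points=int(sel.sum()),
            decaying=decaying,
        )
        return self


def kitt(times_min: np.ndarray, glucose_mg_dl: np.ndarray,
         window: tuple[float, float] = DEFAULT_WINDOW,
         fit_scale: str = "log") -> KittResult:
    """Functional wrapper over :class:`KittEstimator`."""
    return KittEstimator(window, fit_scale).fit(times_min, glucose_mg_dl).result_


def caloric_intake(chow_g: float, fructose_ml: float,
                   conc_g_per_l: float = 100.0) -> IntakeRecord:
    """Daily caloric intake: 2.89 kcal/g chow + 4.0 kcal/g fructose.

    ``fructose_ml`` is the volume of fructose water drunk; grams of
    fructose follow from the drinking-water concentration (g/L).
    """
    if min(chow_g, fructose_ml, conc_g_per_l) < 0:
        raise ValueError("intake quantities must be non-negative")
    fructose_g = fructose_ml * conc_g_per_l / 1000.0
    kcal_chow = KCAL_PER_G_CHOW * chow_g
    kcal_fructose = KCAL_PER_G_FRUCTOSE * fructose_g
    return IntakeRecord(
        chow_g=chow_g, fructose_g=fructose_g, kcal_chow=kcal_chow,
        kcal_fructose=kcal_fructose, total_kcal=kcal_chow + kcal_fructose,
    )
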