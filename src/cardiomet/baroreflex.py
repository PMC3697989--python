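"""Pharmacological baroreflex-sensitivity estimation.

Reflex gain is quantified from vasoactive-bolus trials (phenylephrine to
raise pressure, sodium nitroprusside to lower it) as the heart-rate change
per unit mean-arterial-pressure change: the bradycardic response (BR,
negative, from pressor boluses) and the tachycardic response (TR, reported
as a positive magnitude, from depressor boluses).  Only boluses whose
|dMAP| falls in the accepted response window (5-40 mmHg, closed interval)
enter the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

#: Accepted |dMAP| response window, mmHg (closed interval).
DEFAULT_WINDOW = (5.0, 40.0)


@dataclass
class ReflexGain:
    """Bradycardic and tachycardic reflex gains, bpm/mmHg."""

    br: float | None       # signed, expected negative
    tr: float | None       # positive magnitude
    n_br: int
    n_tr: int


def filter_responses(delta_map: np.ndarray, delta_hr: np.ndarray,
                     window: tuple[float, float] = DEFAULT_WINDOW
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Retain boluses whose |dMAP| lies in the closed response window."""
    dmap = np.asarray(delta_map, dtype=float)
    dhr = np.asarray(delta_hr, dtype=float)
    if dmap.size == 0:
        raise ValueError("empty trial")
    if dmap.shape != dhr.shape:
        raise ValueError("delta_map and delta_hr must have equal length")
    lo, hi = window
    keep = (np.abs(dmap) >= lo) & (np.abs(dmap) <= hi)
    if not keep.any():
        raise ValueError(
            f"no boluses with |dMAP| in [{lo}, {hi}] mmHg; "
            f"observed |dMAP| range {np.abs(dmap).min():.1f}-{np.abs(dmap).max():.1f}")
    return dmap[keep], dhr[keep]


class ReflexGainEstimator(BaseEstimator):
    """Reflex gain from (dMAP, dHR) bolus responses, sklearn-style.

    Parameters
    ----------
    window : closed |dMAP| acceptance interval, mmHg
    method : "ratio" (default) — mean of per-bolus dHR/dMAP ratios, matching
        the "response per millimeter of mercury" definition; "slope" — an
        ordinary least-squares regression slope, for sensitivity analysis.

    Attributes (after ``fit``)
    --------------------------
    gain_ : signed gain, bpm/mmHg
    n_used_ : boluses retained by the response-window filter
    """

    def __init__(self, window: tuple[float, float] = DEFAULT_WINDOW,
                 method: str = "ratio"):
        self.window = window
        self.method = method

    def fit(self, delta_map: np.ndarray, delta_hr: np.ndarray):
        dmap, dhr = filter_responses(delta_map, delta_hr, self.window)
        if self.method == "ratio":
            self.gain_ = float(np.mean(dhr / dmap))
        elif self.method == "slope":
            self.gain_ = float(np.polyfit(dmap, dhr, 1)[0])
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.n_used_ = int(dmap.size)
        return self


def reflex_gain(trial: pd.DataFrame, window: tuple[float, float] = DEFAULT_WINDOW,
                method: str = "ratio") -> ReflexGain:
    """BR and TR from a tidy bolus table.

    ``trial`` needs columns ``drug`` ("pressor" or "depressor"),
    ``delta_map`` (mmHg) and ``delta_hr`` (bpm).  BR is the signed gain
    over pressor boluses; TR is reported as a positive magnitude over
    depressor boluses, matching the usual sign convention.
    """
    required = {"drug", "delta_map", "delta_hr"}
    if not required.issubset(trial.columns):
        raise ValueError(f"trial table needs columns {sorted(required)}")
    br = tr = None
    n_br = n_tr = 0
    pressor = trial[trial["drug"] == "pressor"]
    if len(pressor):
        est = ReflexGainEstimator(window, method).fit(
            pressor["delta_map"].to_numpy(), pressor["delta_hr"].to_numpy())
        br, n_br = est.gain_, est.n_used_
    depressor = trial[trial["drug"] == "depressor"]
    if len(depressor):
        est = ReflexGainEstimator(window, method).fit(
            depressor["delta_map"].to_numpy(), depressor["delta_hr"].to_numpy())
        tr, n_tr = abs(est.gain_), est.n_used_
    return ReflexGain(br=br, tr=tr, n_br=n_br, n_tr=n_tr)
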