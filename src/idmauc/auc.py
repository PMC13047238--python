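"""Plug-in time-specific AUC estimators for any fitted illness-death model.

Both estimators replace transition probabilities and hazards in the
population expressions by their fitted counterparts:

* incident/dynamic at t: cases die exactly at t, controls survive past t,
  and the marker is the disease state *just before* t.  For models with
  step-function (Aalen-Johansen) probabilities both components are
  evaluated at the left limit t-, so that at a visit time the estimate
  uses only information observed strictly before it; smooth models are
  unaffected (t- = t).
* cumulative/dynamic for (s, t): cases die in (s, t], controls survive
  past t, and the marker is the disease state *at* s, inclusive of a
  screen held exactly at s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import IllnessDeathModel
from .weibull import AUCCurve

__all__ = ["AUCEstimate", "auc_id_estimate", "auc_cd_estimate", "auc_curve"]


@dataclass(frozen=True)
class AUCEstimate:
    """One AUC value together with its two plug-in components.

    ``value`` equals 0.5 + 0.5*(p_hat - pi1_hat) by construction;
    ``pi1_hat`` is the (conditional) disease prevalence among controls
    and ``p_hat`` the disease probability among cases.  ``informative``
    is False when no case could occur (zero denominator), in which case
    the AUC defaults to 0.5.
    """

    kind: str
    t: float
    value: float
    pi1_hat: float
    p_hat: float
    s: Optional[float] = None
    informative: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi1_hat <= 1.0 and 0.0 <= self.p_hat <= 1.0):
            raise ValueError("plug-in components must be probabilities")
        assert abs(self.value - (0.5 + 0.5 * (self.p_hat - self.pi1_hat))) < 1e-12


def auc_id_estimate(model: IllnessDeathModel, t: float) -> AUCEstimate:
    """Incident/dynamic AUC at time t (months) from a fitted model.

    pi1(t) = P01 / (P00 + P01) and p(t) = P01*g / (P00 + P01*g) with
    g = lambda12/lambda02, all at the left limit t- for jump models.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return AUCEstimate(kind="ID", t=0.0, value=0.5, pi1_hat=0.0, p_hat=0.0)
    P = model.transprob_left(0.0, t)
    p00, p01 = P[0, 0], P[0, 1]
    alive = p00 + p01
    if alive <= 0:
        raise ZeroDivisionError("no survivors possible at t; incident AUC undefined")
    pi1 = p01 / alive
    g = model.death_hazard_ratio(t)
    if not np.isfinite(g):
        p_hat = 1.0 if p01 > 0 else 0.0
    else:
        p_hat = p01 * g / (p00 + p01 * g) if p00 + p01 * g > 0 else 0.0
    return AUCEstimate(kind="ID", t=float(t), value=0.5 + 0.5 * (p_hat - pi1),
                       pi1_hat=float(pi1), p_hat=float(p_hat))


def auc_cd_estimate(model: IllnessDeathModel, s: float, t: float) -> AUCEstimate:
    """Cumulative/dynamic AUC for prediction time s and horizon t (months)."""
    if not 0 < s < t:
        raise ValueError("require 0 < s < t")
    P0s = model.transprob(0.0, s)
    P0t = model.transprob(0.0, t)
    Pst = model.transprob(s, t)
    p01_0s, p00_0s = P0s[0, 1], P0s[0, 0]
    alive_t = P0t[0, 0] + P0t[0, 1]
    p11_st, p12_st = Pst[1, 1], Pst[1, 2]
    p02_st = Pst[0, 2]
    pi1 = p01_0s * p11_st / alive_t if alive_t > 0 else 0.0
    denom = p00_0s * p02_st + p01_0s * p12_st  # Pr(die in (s,t] | alive at s)
    informative = denom > 0
    p_hat = p01_0s * p12_st / denom if informative else 0.0
    pi1 = pi1 if informative else 0.0
    return AUCEstimate(kind="CD", t=float(t), s=float(s),
                       value=0.5 + 0.5 * (p_hat - pi1),
                       pi1_hat=float(pi1), p_hat=float(p_hat),
                       informative=bool(informative))


def auc_curve(
    model: IllnessDeathModel,
    kind: str,
    grid: np.ndarray,
    window: float = 60.0,
) -> AUCCurve:
    """Evaluate an AUC estimator on a time grid (months).

    For CD curves the value at grid time s is AUC(s, s + window); grid
    points are used as-is, so the caller restricts the grid to keep
    s + window inside the model's supported range.
    """
    grid = np.asarray(grid, dtype=float)
    if kind == "ID":
        values = np.array([auc_id_estimate(model, t).value for t in grid])
        return AUCCurve(times=grid, values=values, kind="ID")
    if kind == "CD":
        values = np.array([auc_cd_estimate(model, s, s + window).value for s in grid])
        return AUCCurve(times=grid, values=values, kind="CD", window=window)
    raise ValueError("kind must be 'ID' or 'CD'")
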