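"""Weibull illness-death model: hazards, transition probabilities and true AUCs.

Each transition h->l carries a Weibull intensity

    lambda_hl(t) = alpha_hl * k_hl * t**(k_hl - 1),
    Lambda_hl(t) = alpha_hl * t**k_hl,

with rate alpha_hl > 0 and shape k_hl > 0 on the months time scale.  The
progressive Markov structure gives closed forms for staying probabilities
and a one-dimensional integral for P01:

    P00(s,t) = exp(-[L01(t)-L01(s)] - [L02(t)-L02(s)])
    P11(s,t) = exp(-[L12(t)-L12(s)])
    P01(s,t) = int_s^t P00(s,u) lambda01(u) P11(u,t) du

For shapes below one the integrand is singular (but integrable) at u=0;
the substitution u = w**2 removes the singularity for k = 0.5 exactly and
softens it otherwise, after which adaptive quadrature reaches absolute
tolerances far below the 2-decimal reporting precision.

The module also evaluates the *true* incident/dynamic and
cumulative/dynamic AUC of the binary disease marker under this model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import quad

from .core import TRANSITIONS, IllnessDeathModel, validate_transprob

__all__ = [
    "WeibullIDMParams",
    "SIMULATION_TRUTH",
    "weibull_hazard",
    "weibull_cumhaz",
    "weibull_transprob",
    "WeibullIDM",
    "true_auc_id",
    "true_auc_cd",
    "AUCCurve",
]


@dataclass(frozen=True)
class WeibullIDMParams:
    """Shapes k_hl and rates alpha_hl of the three transition hazards."""

    k01: float
    k02: float
    k12: float
    a01: float
    a02: float
    a12: float

    def __post_init__(self) -> None:
        for name in ("k01", "k02", "k12", "a01", "a02", "a12"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def common_shape(self) -> Optional[float]:
        """The shared shape if all three coincide, else None."""
        if self.k01 == self.k02 == self.k12:
            return self.k01
        return None

    def shape(self, tr: str) -> float:
        return getattr(self, f"k{tr}")

    def rate(self, tr: str) -> float:
        return getattr(self, f"a{tr}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, text: str) -> "WeibullIDMParams":
        return cls(**json.loads(text))


#: generating parameters of the simulation study: common shape 0.5,
#: rates 0.05 / 0.05 / 0.56, i.e. disease-vs-no-disease death HR 11.2
SIMULATION_TRUTH = WeibullIDMParams(k01=0.5, k02=0.5, k12=0.5, a01=0.05, a02=0.05, a12=0.56)


def weibull_hazard(params: WeibullIDMParams, tr: str, t) -> float | np.ndarray:
    """lambda_tr(t) = alpha*k*t**(k-1); +inf at t=0 when k < 1."""
    if tr not in TRANSITIONS:
        raise ValueError(f"unknown transition {tr!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    a, k = params.rate(tr), params.shape(tr)
    with np.errstate(divide="ignore"):
        out = a * k * np.power(t, k - 1.0)
    return float(out) if out.ndim == 0 else out


def weibull_cumhaz(params: WeibullIDMParams, tr: str, t) -> float | np.ndarray:
    """Lambda_tr(t) = alpha * t**k."""
    if tr not in TRANSITIONS:
        raise ValueError(f"unknown transition {tr!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = params.rate(tr) * np.power(t, params.shape(tr))
    return float(out) if out.ndim == 0 else out


def _p00(params: WeibullIDMParams, s, t):
    return np.exp(
        -(weibull_cumhaz(params, "01", t) - weibull_cumhaz(params, "01", s))
        - (weibull_cumhaz(params, "02", t) - weibull_cumhaz(params, "02", s))
    )


def _p11(params: WeibullIDMParams, s, t):
    return np.exp(-(weibull_cumhaz(params, "12", t) - weibull_cumhaz(params, "12", s)))


def _p01(params: WeibullIDMParams, s: float, t: float, epsabs: float = 1e-10) -> float:
    """P01(s,t) by adaptive quadrature on the w = sqrt(u) scale."""
    if t <= s:
        return 0.0
    a01, k01 = params.a01, params.k01

    def integrand(w):
        u = w * w
        # lambda01(u) du = a k u^(k-1) * 2w dw = 2 a k w^(2k-1) dw
        return _p00(params, s, u) * 2.0 * a01 * k01 * w ** (2.0 * k01 - 1.0) * _p11(params, u, t)

    val, _err = quad(integrand, np.sqrt(s), np.sqrt(t), epsabs=epsabs, epsrel=1e-10, limit=200)
    return float(val)


def weibull_transprob(params: WeibullIDMParams, s: float, t: float) -> np.ndarray:
    """3x3 transition probability matrix P(s,t) of the Weibull model."""
    if s > t:
        raise ValueError("require s <= t")
    if s < 0:
        raise ValueError("require s >= 0")
    if s == t:
        return np.eye(3)
    p00 = float(_p00(params, s, t))
    p11 = float(_p11(params, s, t))
    p01 = _p01(params, s, t)
    P = np.array(
        [
            [p00, p01, max(1.0 - p00 - p01, 0.0)],
            [0.0, p11, 1.0 - p11],
            [0.0, 0.0, 1.0],
        ]
    )
    validate_transprob(P)
    return P


class WeibullIDM(IllnessDeathModel):
    """A Weibull illness-death model as a fitted-model object.

    Used both for the generating truth and for plug-in evaluation of a
    maximum-likelihood Weibull fit.
    """

    jump_times = None  # smooth hazards

    def __init__(self, params: WeibullIDMParams):
        self.params = params

    def hazard(self, tr: str, t: float) -> float:
        return weibull_hazard(self.params, tr, t)

    def cumhaz(self, tr: str, t: float) -> float:
        return weibull_cumhaz(self.params, tr, t)

    def transprob(self, s: float, t: float) -> np.ndarray:
        return weibull_transprob(self.params, s, t)

    def death_hazard_ratio(self, t: float) -> float:
        p = self.params
        if p.k12 == p.k02:
            return p.a12 / p.a02
        if t == 0:
            return float("inf") if p.k12 < p.k02 else 0.0
        return weibull_hazard(p, "12", t) / weibull_hazard(p, "02", t)


@dataclass
class AUCCurve:
    """A time-specific AUC evaluated on an ascending time grid (months).

    ``kind`` is "ID" (incident/dynamic) or "CD" (cumulative/dynamic);
    ``window`` (months) applies to CD curves only, where the value at
    grid time s is AUC(s, s + window).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    window: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("ID", "CD"):
            raise ValueError("kind must be 'ID' or 'CD'")
        if self.times.size != self.values.size:
            raise ValueError("times and values differ in length")
        if self.values.size and (np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12):
            raise ValueError("AUC values must lie in [0,1]")


def true_auc_id(params: WeibullIDMParams, t: float) -> float:
    """True incident/dynamic AUC at time t (months).

    AUC(t) = 0.5 + 0.5*(p(t) - pi1(t)) where pi1(t) is the disease
    prevalence among survivors and p(t) the probability that a subject
    dying at t carries the disease; both follow from P(0,t) and the
    death-hazard ratio gamma(t).  Returns 0.5 at t=0 (no disease yet).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return 0.5
    p00 = float(_p00(params, 0.0, t))
    p01 = _p01(params, 0.0, t)
    pi1 = p01 / (p00 + p01)
    gamma = WeibullIDM(params).death_hazard_ratio(t)
    p = p01 * gamma / (p00 + p01 * gamma)
    return 0.5 + 0.5 * (p - pi1)


def true_auc_cd(params: WeibullIDMParams, s: float, t: float) -> float:
    """True cumulative/dynamic AUC for prediction time s and horizon t.

    Cases die in (s,t], controls survive past t; the marker is the
    disease state at s.
    """
    if not 0 < s < t:
        raise ValueError("require 0 < s < t")
    p00_0s = float(_p00(params, 0.0, s))
    p01_0s = _p01(params, 0.0, s)
    p00_0t = float(_p00(params, 0.0, t))
    p01_0t = _p01(params, 0.0, t)
    p00_st = float(_p00(params, s, t))
    p01_st = _p01(params, s, t)
    p11_st = float(_p11(params, s, t))
    p02_st = 1.0 - p00_st - p01_st
    p12_st = 1.0 - p11_st
    pi1 = p01_0s * p11_st / (p00_0t + p01_0t)
    denom = p00_0s * p02_st + p01_0s * p12_st
    p = p01_0s * p12_st / denom if denom > 0 else 0.0
    return 0.5 + 0.5 * (p - pi1)
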