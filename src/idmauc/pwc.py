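"""Piecewise-constant Markov illness-death model for panel data.

The disease state is observed only at visits, death times are exact, and
the terminal disease status of subjects whose last screen was negative is
unknown.  With piecewise-constant transition intensities (change points
c_1 < ... < c_k) the interval transition matrices have closed forms, so
the panel likelihood is available in closed form as well:

* consecutive visit pairs contribute P00 / P01 / P11 over the pair;
* a death at T* from last-known state h contributes
  sum_l P_hl(v*, T*-) lambda_l2(T*-) over the live states l, which
  integrates out the unknown disease status between the last screen v*
  and death;
* censoring alive contributes sum_l P_hl(v*, T*).

The likelihood is maximized over log rates (L-BFGS-B), optionally under
the proportional-death-hazards constraint lambda12,j = lambda02,j e^beta.
Visit grids are regular, so pair contributions collapse onto a small set
of distinct intervals whose piece-overlap durations are precomputed once
per fit; the per-evaluation cost is a handful of vectorized exponentials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from ._numdiff import numerical_covariance
from .core import IllnessDeathModel, PanelDataset

__all__ = [
    "PwcParams",
    "interval_transmat",
    "panel_loglik",
    "fit_pwc",
    "PwcFit",
    "PwcIDM",
    "DEFAULT_CHANGEPOINTS",
]

#: study default: hazards may change at 6, 30, 60 and 90 months
DEFAULT_CHANGEPOINTS = (6.0, 30.0, 60.0, 90.0)

_TINY = 1e-300


@dataclass(frozen=True)
class PwcParams:
    """Step hazards of the three transitions on a shared change-point grid.

    ``rates[tr]`` has one entry per piece (k change points give k+1
    pieces).  Under the proportional constraint the 1->2 rates are
    derived: lambda12,j = lambda02,j * exp(beta).
    """

    changepoints: np.ndarray
    rates: dict
    constrained: bool = False
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        cps = np.asarray(self.changepoints, dtype=float)
        object.__setattr__(self, "changepoints", cps)
        if np.any(np.diff(cps) <= 0) or np.any(cps <= 0):
            raise ValueError("change points must be positive and ascending")
        npieces = cps.size + 1
        rates = {tr: np.asarray(self.rates[tr], dtype=float) for tr in ("01", "02", "12")}
        object.__setattr__(self, "rates", rates)
        for tr, r in rates.items():
            if r.size != npieces:
                raise ValueError(f"transition {tr}: expected {npieces} rates")
            if np.any(r < 0):
                raise ValueError(f"transition {tr}: negative rate")
        if self.constrained:
            if self.beta is None:
                raise ValueError("constrained model requires beta")
            expected = rates["02"] * np.exp(self.beta)
            if not np.allclose(rates["12"], expected, rtol=1e-10, atol=1e-300):
                raise ValueError("constrained model: lambda12 must equal lambda02*exp(beta)")

    @property
    def n_pieces(self) -> int:
        return self.changepoints.size + 1

    def piece_index(self, t, side: str = "left"):
        """Piece containing t; side='left' gives the left-limit piece at
        a change point (hazard is left-continuous: lambda(c_j) = lambda_j)."""
        return np.searchsorted(self.changepoints, t, side=side)

    def rate_at(self, tr: str, t, side: str = "left"):
        return self.rates[tr][self.piece_index(t, side)]


def _piece_durations(changepoints: np.ndarray, s, t) -> np.ndarray:
    """Overlap of (s, t] with each piece; vectorized over s, t arrays."""
    bounds = np.concatenate(([0.0], changepoints, [np.inf]))
    s = np.asarray(s, dtype=float)[..., None]
    t = np.asarray(t, dtype=float)[..., None]
    lo = np.maximum(s, bounds[:-1])
    hi = np.minimum(t, bounds[1:])
    return np.clip(hi - lo, 0.0, None)


def _piece_p01(q01, q02, q12, d):
    """Closed-form P01 of the constant-hazard illness-death chain over
    duration d, with the q01*d*exp(-q12 d) limit when q01+q02 = q12."""
    d = np.asarray(d, dtype=float)
    den = q01 + q02 - q12
    e12 = np.exp(-q12 * d)
    e0 = np.exp(-(q01 + q02) * d)
    if abs(den) < 1e-9 * max(q12, q01 + q02, 1e-12):
        return q01 * d * e12
    return q01 / den * (e12 - e0)


def _pxx_products(lam01, lam02, lam12, D):
    """(P00, P01, P11) over intervals whose piece durations are rows of D."""
    p00_total = np.exp(-D @ (lam01 + lam02))
    p11_total = np.exp(-D @ lam12)
    p00 = np.ones(D.shape[0])
    p01 = np.zeros(D.shape[0])
    for j in range(D.shape[1]):
        d = D[:, j]
        p01 = p00 * _piece_p01(lam01[j], lam02[j], lam12[j], d) + p01 * np.exp(-lam12[j] * d)
        p00 = p00 * np.exp(-(lam01[j] + lam02[j]) * d)
    return p00_total, p01, p11_total


def interval_transmat(params: PwcParams, s: float, t: float) -> np.ndarray:
    """3x3 transition probability matrix P(s,t) under step hazards."""
    if s > t:
        raise ValueError("require s <= t")
    D = _piece_durations(params.changepoints, s, t).reshape(1, -1)
    p00, p01, p11 = _pxx_products(params.rates["01"], params.rates["02"], params.rates["12"], D)
    p00, p01, p11 = float(p00[0]), float(p01[0]), float(p11[0])
    return np.array(
        [
            [p00, p01, max(1.0 - p00 - p01, 0.0)],
            [0.0, p11, 1.0 - p11],
            [0.0, 0.0, 1.0],
        ]
    )


class _PanelAgg:
    """Sufficient statistics of a panel for the piecewise likelihood."""

    def __init__(self, data: PanelDataset, changepoints: np.ndarray):
        pair_counts: dict[tuple[float, float], list] = {}
        vstar, tstar, state, delta = [], [], [], []
        for s in data:
            v, m = s.visit_times, s.marker
            for i in range(v.size - 1):
                if m[i] == 1 and m[i + 1] == 0:
                    raise ValueError(f"subject {s.id}: non-chronological disease marker")
                key = (float(v[i]), float(v[i + 1]))
                c = pair_counts.setdefault(key, [0, 0, 0])
                c[m[i] + m[i + 1]] += 1  # 0: 0->0, 1: 0->1, 2: 1->1
            vstar.append(float(v[-1]))
            tstar.append(float(s.tstar))
            state.append(int(m[-1]))
            delta.append(int(s.delta))
        keys = sorted(pair_counts)
        self.pair_D = (
            _piece_durations(changepoints, [k[0] for k in keys], [k[1] for k in keys])
            if keys
            else np.zeros((0, changepoints.size + 1))
        )
        self.pair_counts = np.array([pair_counts[k] for k in keys], dtype=float).reshape(-1, 3)
        self.tail_D = _piece_durations(changepoints, vstar, tstar)
        self.tstar = np.asarray(tstar)
        self.state = np.asarray(state)
        self.delta = np.asarray(delta)
        # left-limit piece of the death/censoring time
        self.tstar_piece = np.searchsorted(changepoints, self.tstar, side="left")
        self.n_events = {
            "01": int(self.pair_counts[:, 1].sum()),
            "02": int(np.sum((self.delta == 1) & (self.state == 0))),
            "12": int(np.sum((self.delta == 1) & (self.state == 1))),
        }


def _loglik_arrays(lam01, lam02, lam12, agg: _PanelAgg) -> float:
    ll = 0.0
    if agg.pair_counts.size:
        p00, p01, p11 = _pxx_products(lam01, lam02, lam12, agg.pair_D)
        probs = np.stack([p00, p01, p11], axis=1)
        ll += float(np.sum(agg.pair_counts * np.log(np.maximum(probs, _TINY))))
    p00, p01, p11 = _pxx_products(lam01, lam02, lam12, agg.tail_D)
    l02 = lam02[agg.tstar_piece]
    l12 = lam12[agg.tstar_piece]
    dead, healthy = agg.delta == 1, agg.state == 0
    f = np.where(
        dead,
        np.where(healthy, p00 * l02 + p01 * l12, p11 * l12),
        np.where(healthy, p00 + p01, p11),
    )
    ll += float(np.sum(np.log(np.maximum(f, _TINY))))
    return ll


def panel_loglik(params: PwcParams, data: PanelDataset) -> float:
    """Closed-form panel log-likelihood of a piecewise-constant model."""
    agg = _PanelAgg(data, params.changepoints)
    return _loglik_arrays(params.rates["01"], params.rates["02"], params.rates["12"], agg)


@dataclass
class PwcFit:
    params: PwcParams
    loglik: float
    converged: bool
    covariance: Optional[np.ndarray] = None  # on the optimized (log-rate[, beta]) scale
    se_beta: Optional[float] = None
    n_evals: int = 0
    message: str = ""

    @property
    def hazard_ratio(self) -> Optional[float]:
        return None if self.params.beta is None else float(np.exp(self.params.beta))

    def to_json(self) -> str:
        return json.dumps(
            {
                "changepoints": self.params.changepoints.tolist(),
                "rates": {tr: r.tolist() for tr, r in self.params.rates.items()},
                "constrained": self.params.constrained,
                "beta": self.params.beta,
                "loglik": self.loglik,
                "converged": self.converged,
            }
        )


def _crude_rates(data: PanelDataset) -> dict:
    """Occurrence/exposure rates treating the diagnosis time R as exact."""
    from .core import summarize_intervals

    exp0 = exp1 = 1e-9
    n01 = n02 = n12 = 0
    for iv in summarize_intervals(data):
        if iv.R is None:
            exp0 += iv.tstar
            n02 += iv.delta
        else:
            exp0 += iv.R
            exp1 += iv.tstar - iv.R
            n01 += 1
            n12 += iv.delta
    return {
        "01": max(n01, 0.5) / exp0,
        "02": max(n02, 0.5) / exp0,
        "12": max(n12, 0.5) / max(exp1, 1e-6),
    }


def _theta_to_rates(theta: np.ndarray, npieces: int, constrained: bool):
    lam01 = np.exp(theta[:npieces])
    lam02 = np.exp(theta[npieces : 2 * npieces])
    if constrained:
        beta = theta[2 * npieces]
        lam12 = lam02 * np.exp(beta)
    else:
        beta = None
        lam12 = np.exp(theta[2 * npieces : 3 * npieces])
    return lam01, lam02, lam12, beta


def fit_pwc(
    data: PanelDataset,
    changepoints: Sequence[float] = DEFAULT_CHANGEPOINTS,
    constrained: bool = False,
    init: Optional[np.ndarray] = None,
    compute_cov: bool = False,
) -> PwcFit:
    """Maximum-likelihood fit of the piecewise-constant illness-death model.

    Optimization runs on log rates (positivity for free); the constrained
    variant replaces the free 1->2 rates by lambda02*exp(beta).  Rates in
    pieces with no information drift to the lower bound and are simply
    reported there.  Set ``compute_cov`` for a numerical-Hessian
    covariance of the optimized parameters.
    """
    cps = np.asarray(changepoints, dtype=float)
    npieces = cps.size + 1
    agg = _PanelAgg(data, cps)
    if init is None:
        crude = _crude_rates(data)
        log01 = np.full(npieces, np.log(crude["01"]))
        log02 = np.full(npieces, np.log(crude["02"]))
        if constrained:
            beta0 = np.log(max(crude["12"] / crude["02"], 1e-3))
            init = np.concatenate([log01, log02, [beta0]])
        else:
            init = np.concatenate([log01, log02, np.full(npieces, np.log(crude["12"]))])

    def neg(theta):
        lam01, lam02, lam12, _ = _theta_to_rates(theta, npieces, constrained)
        return -_loglik_arrays(lam01, lam02, lam12, agg)

    bounds = [(-16.0, 3.0)] * (2 * npieces) + (
        [(-8.0, 8.0)] if constrained else [(-16.0, 3.0)] * npieces
    )
    res = minimize(neg, init, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    lam01, lam02, lam12, beta = _theta_to_rates(res.x, npieces, constrained)
    params = PwcParams(
        changepoints=cps,
        rates={"01": lam01, "02": lam02, "12": lam12},
        constrained=constrained,
        beta=beta,
    )
    cov = se_beta = None
    if compute_cov:
        cov = numerical_covariance(neg, res.x)
        if constrained and cov is not None:
            se_beta = float(np.sqrt(cov[2 * npieces, 2 * npieces]))
    return PwcFit(
        params=params,
        loglik=-res.fun,
        converged=bool(res.success),
        covariance=cov,
        se_beta=se_beta,
        n_evals=res.nfev,
        message=str(res.message),
    )


class PwcIDM(IllnessDeathModel):
    """Fitted piecewise-constant model under the shared model contract.

    Transition probabilities are continuous in t (no jumps), so the
    left-limit evaluation coincides with the plain one; the death-hazard
    ratio uses the left-limit piece so that evaluation exactly at a
    change point refers to the piece ending there.
    """

    jump_times = None

    def __init__(self, params: PwcParams):
        self.params = params

    def hazard(self, tr: str, t: float) -> float:
        return float(self.params.rate_at(tr, t))

    def cumhaz(self, tr: str, t: float) -> float:
        D = _piece_durations(self.params.changepoints, 0.0, t)
        return float(D @ self.params.rates[tr])

    def transprob(self, s: float, t: float) -> np.ndarray:
        return interval_transmat(self.params, s, t)

    def death_hazard_ratio(self, t: float) -> float:
        return float(self.params.rate_at("12", t) / self.params.rate_at("02", t))
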