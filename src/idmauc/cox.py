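"""Cox model with the observed time-dependent disease marker.

This is the naive approach that ignores interval censoring: the disease
marker X(t) switches from 0 to 1 at the *first positive visit* R (the
diagnosis time), not at the unobserved true onset.  The model

    lambda(t | X(t)) = lambda0(t) * exp(beta * X(t))

is the illness-death model with lambda02 = lambda0 and
lambda12 = lambda0 * exp(beta); the 0->1 hazard is not modelled by the
partial likelihood and is estimated separately by Nelson-Aalen treating R
as an exact event time.

With a single binary covariate the Breslow partial likelihood depends on
the data only through per-death-time counts (deaths split by marker and
risk-set sizes split by marker), so the score equation is solved by a
scalar Newton iteration.  Transition probabilities come from the
Aalen-Johansen product-integral over the merged jump grid, with
d(Lambda12) = exp(beta) * d(Lambda02) (Breslow baseline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import IllnessDeathModel, PanelDataset, summarize_intervals

__all__ = [
    "build_counting_process",
    "fit_cox_td",
    "CoxFit",
    "CoxIDM",
    "riskset_auc_id",
]


def build_counting_process(
    data: PanelDataset, diseased_at_death: bool = True
) -> pd.DataFrame:
    """Expand a panel into counting-process rows (tstart, tstop] with marker x.

    A subject diagnosed at R contributes (0, R] with x=0 and (R, T*] with
    x=1; an undiagnosed subject contributes a single (0, T*] row.  The
    death indicator is attached to the final row.  When diagnosis falls
    exactly at the end of follow-up (R = T*) no zero-length exposure
    interval is emitted; if the subject died there, the convention
    X(T*) = X(v*) (``diseased_at_death=True``, the default) records the
    death with x=1 on a degenerate marker-only row.
    """
    rows = []
    for iv in summarize_intervals(data):
        if iv.R is None or iv.R >= iv.tstar:
            if iv.R is not None and iv.delta == 1 and diseased_at_death:
                # diagnosis at the death time: exposure is all x=0 but the
                # death itself carries the just-switched marker
                rows.append((iv.id, 0.0, iv.tstar, 0, 0))
                rows.append((iv.id, iv.tstar, iv.tstar, 1, 1))
            else:
                rows.append((iv.id, 0.0, iv.tstar, 0, iv.delta))
        else:
            rows.append((iv.id, 0.0, iv.R, 0, 0))
            rows.append((iv.id, iv.R, iv.tstar, 1, iv.delta))
    return pd.DataFrame(rows, columns=["id", "tstart", "tstop", "x", "event"])


@dataclass
class CoxFit:
    """Fitted Cox model plus the non-parametric pieces of the multi-state fit.

    ``event_times``/``breslow_dL`` hold the Breslow baseline cumulative
    hazard increments (the 0->2 hazard); ``diag_times``/``dL01`` hold the
    Nelson-Aalen increments of the 0->1 (diagnosis) hazard.
    """

    beta: float
    se_beta: float
    loglik: float
    separated: bool
    event_times: np.ndarray
    breslow_dL: np.ndarray
    diag_times: np.ndarray
    dL01: np.ndarray

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta,
                "se_beta": self.se_beta,
                "loglik": self.loglik,
                "separated": self.separated,
                "event_times": self.event_times.tolist(),
                "breslow_dL": self.breslow_dL.tolist(),
                "diag_times": self.diag_times.tolist(),
                "dL01": self.dL01.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CoxFit":
        d = json.loads(text)
        for key in ("event_times", "breslow_dL", "diag_times", "dL01"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def _event_table(rows: pd.DataFrame):
    """Per-unique-death-time counts (d, d1, n0, n1) for the partial likelihood."""
    tstart = rows["tstart"].to_numpy(float)
    tstop = rows["tstop"].to_numpy(float)
    x = rows["x"].to_numpy(int)
    event = rows["event"].to_numpy(int)
    degenerate = tstart == tstop
    death_times = np.unique(tstop[event == 1])
    d = np.zeros(death_times.size)
    d1 = np.zeros(death_times.size)
    n0 = np.zeros(death_times.size)
    n1 = np.zeros(death_times.size)
    for j, u in enumerate(death_times):
        at_risk = ((tstart < u) & (u <= tstop)) | (degenerate & (tstop == u))
        dying = at_risk & (event == 1) & (tstop == u)
        d[j] = dying.sum()
        d1[j] = (dying & (x == 1)).sum()
        n1[j] = (at_risk & (x == 1)).sum()
        n0[j] = at_risk.sum() - n1[j]
    return death_times, d, d1, n0, n1


def breslow_partial_loglik(beta: float, d, d1, n0, n1) -> float:
    """Breslow log partial likelihood as a function of beta."""
    eb = np.exp(beta)
    return float(np.sum(d1 * beta - d * np.log(n0 + n1 * eb)))


def fit_cox_td(rows: pd.DataFrame, tol: float = 1e-10, max_iter: int = 100) -> CoxFit:
    """Maximize the Breslow partial likelihood (scalar Newton iteration).

    Also computes the Breslow baseline cumulative-hazard increments at
    death times and the Nelson-Aalen increments of the diagnosis hazard.
    A fit with all deaths on one marker level is flagged ``separated``
    (beta diverges); downstream AUC evaluation refuses such fits.
    """
    death_times, d, d1, n0, n1 = _event_table(rows)
    if death_times.size == 0:
        raise ValueError("no deaths observed; Cox fit undefined")

    beta = 0.0
    separated = False
    for _ in range(max_iter):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        score = np.sum(d1 - d * n1 * eb / denom)
        info = np.sum(d * n0 * n1 * eb / denom**2)
        if info <= 1e-12:
            # a flat partial likelihood (marker constant in every death-time
            # risk set) is degenerate but harmless: keep beta = 0; a
            # monotone likelihood (non-zero score) is true separation
            separated = abs(score) > 1e-8
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < tol:
            break
        if abs(beta) > 25:
            separated = True
            break
    eb = np.exp(beta)
    denom = n0 + n1 * eb
    info = np.sum(d * n0 * n1 * eb / denom**2)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    breslow_dL = d / denom

    diag_times, dL01 = _nelson_aalen_diagnosis(rows)
    return CoxFit(
        beta=float(beta),
        se_beta=se,
        loglik=breslow_partial_loglik(beta, d, d1, n0, n1),
        separated=separated,
        event_times=death_times,
        breslow_dL=breslow_dL,
        diag_times=diag_times,
        dL01=dL01,
    )


def _nelson_aalen_diagnosis(rows: pd.DataFrame):
    """Nelson-Aalen increments for 0->1, treating diagnosis times as exact.

    A subject is at risk of observed diagnosis until min(R, T*); events
    are first positive visits.  Returned as (times, increments).
    """
    first = rows.groupby("id", sort=False).first()
    has_diag = rows.groupby("id", sort=False)["x"].max() == 1
    exit0 = first["tstop"].to_numpy(float)  # min(R, T*): end of the x=0 row
    diag = has_diag.to_numpy()
    diag_times = np.unique(exit0[diag])
    dL = np.zeros(diag_times.size)
    for j, u in enumerate(diag_times):
        at_risk = exit0 >= u
        dL[j] = np.sum(diag & (exit0 == u)) / at_risk.sum()
    return diag_times, dL


class CoxIDM(IllnessDeathModel):
    """Aalen-Johansen transition probabilities implied by a Cox fit.

    Step-function hazards: d(Lambda01) at diagnosis times (Nelson-Aalen),
    d(Lambda02) at death times (Breslow baseline), and
    d(Lambda12) = exp(beta) d(Lambda02).
    """

    def __init__(self, fit: CoxFit):
        if fit.separated:
            raise ValueError("separated Cox fit: hazard ratio diverges, AUC undefined")
        self.fit = fit
        grid = np.union1d(fit.event_times, fit.diag_times)
        self.jump_times = grid
        # per-jump increments aligned to the merged grid
        self._d01 = np.zeros(grid.size)
        self._d02 = np.zeros(grid.size)
        self._d01[np.searchsorted(grid, fit.diag_times)] = fit.dL01
        self._d02[np.searchsorted(grid, fit.event_times)] = fit.breslow_dL
        self._d12 = np.exp(fit.beta) * self._d02

    def hazard(self, tr: str, t: float) -> float:
        """Jump size of the cumulative hazard at t (0 between jumps)."""
        j = np.searchsorted(self.jump_times, t)
        if j < self.jump_times.size and np.isclose(self.jump_times[j], t):
            return {"01": self._d01, "02": self._d02, "12": self._d12}[tr][j]
        return 0.0

    def cumhaz(self, tr: str, t: float) -> float:
        mask = self.jump_times <= t
        return float({"01": self._d01, "02": self._d02, "12": self._d12}[tr][mask].sum())

    def death_hazard_ratio(self, t: float = None) -> float:
        return float(np.exp(self.fit.beta))

    def _product(self, mask: np.ndarray) -> np.ndarray:
        p00, p01, p11 = 1.0, 0.0, 1.0
        for j in np.flatnonzero(mask):
            f00 = max(1.0 - self._d01[j] - self._d02[j], 0.0)
            f11 = max(1.0 - self._d12[j], 0.0)
            p01 = p00 * self._d01[j] + p01 * f11
            p00 = p00 * f00
            p11 = p11 * f11
        return np.array(
            [
                [p00, p01, max(1.0 - p00 - p01, 0.0)],
                [0.0, p11, 1.0 - p11],
                [0.0, 0.0, 1.0],
            ]
        )

    def transprob(self, s: float, t: float) -> np.ndarray:
        """P(s,t) inclusive of jumps at t: product over jumps in (s, t]."""
        if s > t:
            raise ValueError("require s <= t")
        return self._product((self.jump_times > s) & (self.jump_times <= t))

    def transprob_left(self, s: float, t: float) -> np.ndarray:
        """P(s,t-): product over jumps strictly inside (s, t)."""
        if s > t:
            raise ValueError("require s <= t")
        return self._product((self.jump_times > s) & (self.jump_times < t))


def riskset_auc_id(fit: CoxFit, rows: pd.DataFrame):
    """ROC-based incident/dynamic AUC at each death time (risk-set weights).

    Incident sensitivity weights each risk-set member i by
    exp(beta x_i) / sum_j exp(beta x_j); dynamic specificity is empirical
    in the risk set.  For the binary marker the ties-aware AUC reduces to
    a function of the weighted and empirical prevalence.  The curve is a
    step function carried forward between death times and equals 0.5
    before any disease is observed.
    """
    from .weibull import AUCCurve  # local import to avoid cycle

    if fit.separated:
        raise ValueError("separated Cox fit: AUC undefined")
    death_times, d, d1, n0, n1 = _event_table(rows)
    eb = np.exp(fit.beta)
    q1 = n1 * eb / (n0 + n1 * eb)  # model-weighted Pr(X=1 | case)
    r1 = n1 / (n0 + n1)  # empirical Pr(X=1) in the risk set (controls)
    values = q1 * (1 - r1) + 0.5 * (q1 * r1 + (1 - q1) * (1 - r1))
    return AUCCurve(times=death_times, values=values, kind="ID")
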