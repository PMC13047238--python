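"""Simulate illness-death data with an interval-censored disease state.

Latent paths are drawn from Weibull transition hazards with a *common*
shape k (the inversion formulas below require it):

1. U1 ~ U(0,1);  T1 = (-ln U1 / (a01 + a02))**(1/k) is the first exit
   time from the healthy state.
2. The exit state is 1 (disease) with probability a01/(a01+a02), else 2
   (death), in which case TD = T1.
3. If diseased, U2 ~ U(0,1) and, conditional on having survived to T1,
   TD = (T1**k - ln U2 / a12)**(1/k).

Death is censored administratively at the follow-up horizon y or by an
independent Uniform(a, y) censoring time.  The disease state is then
observed only on the regular visit grid {0, tau, 2tau, ..., y}: the true
illness time T1 maps to the first visit v at or after it, and visits stop
at the last visit v* before end of follow-up.  Illness that occurs but is
never screened before death/censoring is unobserved.

Reproducibility: each subject draws from its own counter-based stream
(SeedSequence spawn key = subject index), so datasets are identical
regardless of iteration order or parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import PanelDataset, SubjectRecord
from .weibull import SIMULATION_TRUTH, WeibullIDMParams

__all__ = [
    "LatentPath",
    "ScenarioConfig",
    "SCENARIOS",
    "scenario",
    "draw_latent_path",
    "sample_latent_paths",
    "apply_censoring",
    "discretize_marker",
    "simulate_scenario",
]


@dataclass(frozen=True)
class LatentPath:
    """A latent (uncensored) trajectory of one subject."""

    t1: float
    first_exit_state: int  # 1 = disease, 2 = death
    td: float
    u1: float
    u2: Optional[float]


@dataclass(frozen=True)
class CensoringScheme:
    """Administrative censoring at y, or Uniform(a, y) random censoring."""

    kind: str  # "admin" | "uniform"
    a: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("admin", "uniform"):
            raise ValueError("censoring kind must be 'admin' or 'uniform'")
        if self.kind == "uniform" and self.a is None:
            raise ValueError("uniform censoring needs lower bound a")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: size, censoring scheme and visit spacing."""

    name: str
    n_subjects: int
    censoring: CensoringScheme
    tau: float  # visit spacing (months)
    y: float = 120.0  # follow-up horizon (months)
    params: WeibullIDMParams = SIMULATION_TRUTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.tau <= 0 or self.tau > self.y:
            raise ValueError("invalid visit spacing")
        if self.censoring.kind == "uniform" and not (0 <= self.censoring.a < self.y):
            raise ValueError("uniform censoring needs 0 <= a < y")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return ScenarioConfig(self.name, self.n_subjects, self.censoring, self.tau, self.y, self.params, seed)


def _catalogue() -> dict[str, ScenarioConfig]:
    """The 18 study scenarios A-R: N in {1000, 2000, 400}, censoring
    Uniform(5,10)y vs administrative 10y, visit spacing 3/6/12 months."""
    unif = CensoringScheme("uniform", a=60.0)
    admin = CensoringScheme("admin")
    cat: dict[str, ScenarioConfig] = {}
    names = iter("ABCDEFGHIJKLMNOPQR")
    for n in (1000, 2000, 400):
        for cens in (unif, admin):
            for tau in (3.0, 6.0, 12.0):
                name = next(names)
                cat[name] = ScenarioConfig(name=name, n_subjects=n, censoring=cens, tau=tau)
    return cat


SCENARIOS: dict[str, ScenarioConfig] = _catalogue()


def scenario(name: str, seed: int = 0) -> ScenarioConfig:
    """Look up a catalogue scenario by letter and attach a seed."""
    try:
        return SCENARIOS[name.upper()].with_seed(seed)
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; choose one of A-R") from None


def draw_latent_path(params: WeibullIDMParams, rng: np.random.Generator) -> LatentPath:
    """Draw one latent path by Weibull inversion (common shape required)."""
    k = params.common_shape
    if k is None:
        raise ValueError("inversion sampling requires a common shape across transitions")
    a01, a02, a12 = params.a01, params.a02, params.a12
    u1 = rng.uniform()
    t1 = (-np.log(u1) / (a01 + a02)) ** (1.0 / k)
    u_exit = rng.uniform()
    if u_exit < a01 / (a01 + a02):
        u2 = rng.uniform()
        td = (t1**k - np.log(u2) / a12) ** (1.0 / k)
        return LatentPath(t1=t1, first_exit_state=1, td=td, u1=u1, u2=u2)
    return LatentPath(t1=t1, first_exit_state=2, td=t1, u1=u1, u2=None)


def sample_latent_paths(params: WeibullIDMParams, n: int, rng: np.random.Generator):
    """Vectorized latent-path sampler for Monte Carlo checks.

    Returns arrays (t1, first_exit_state, td).
    """
    k = params.common_shape
    if k is None:
        raise ValueError("inversion sampling requires a common shape across transitions")
    a01, a02, a12 = params.a01, params.a02, params.a12
    t1 = (-np.log(rng.uniform(size=n)) / (a01 + a02)) ** (1.0 / k)
    exit_state = np.where(rng.uniform(size=n) < a01 / (a01 + a02), 1, 2)
    u2 = rng.uniform(size=n)
    td = np.where(exit_state == 2, t1, (t1**k - np.log(u2) / a12) ** (1.0 / k))
    return t1, exit_state, td


def apply_censoring(
    path: LatentPath, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[float, int]:
    """Censor the latent death time; returns (tstar, delta)."""
    if config.censoring.kind == "admin":
        c = config.y
    else:
        c = rng.uniform(config.censoring.a, config.y)
    if path.td <= c:
        return float(path.td), 1
    return float(c), 0


def discretize_marker(
    path: LatentPath, tstar: float, delta: int, tau: float, y: float, id: str = "S0"
) -> SubjectRecord:
    """Observe the disease state on the visit grid {0, tau, ..., y}.

    v* is the last visit at or before T*; the observed illness time v is
    the first visit at or after the true illness time T1 ("at/after" is
    inclusive on both).  Illness is observed only when the subject became
    ill during follow-up (T1 <= T*) and was screened afterwards
    (v <= v*); otherwise the marker stays 0 at every visit.
    """
    n_vstar = int(np.floor(tstar / tau + 1e-9))
    vstar = min(n_vstar * tau, y)
    visits = np.arange(0, n_vstar + 1) * tau
    visits = visits[visits <= y]
    marker = np.zeros(visits.size, dtype=int)
    if path.first_exit_state == 1 and path.t1 <= tstar:
        # "at/after" is inclusive: a T1 exactly on the grid maps to itself
        # (the guard is tiny so a T1 just above 0 still maps to the next visit)
        v = np.ceil(path.t1 / tau - 1e-12) * tau
        if 0 < v <= vstar:
            marker[visits >= v - 1e-9 * tau] = 1
    return SubjectRecord(id=id, visit_times=visits, marker=marker, tstar=tstar, delta=delta)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def simulate_scenario(config: ScenarioConfig) -> PanelDataset:
    """Generate one dataset for a scenario; deterministic given its seed."""
    width = max(4, len(str(config.n_subjects)))
    subjects = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config.seed, i)
        path = draw_latent_path(config.params, rng)
        tstar, delta = apply_censoring(path, config, rng)
        subjects.append(
            discretize_marker(path, tstar, delta, config.tau, config.y, id=f"S{i:0{width}d}")
        )
    return PanelDataset(subjects)
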