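"""Diversification statistics on dated, ultrametric phylogenies.

Covers the classic toolkit for asking whether a clade diversified at a
constant rate: lineage-through-time (LTT) curves, the Pybus–Harvey
gamma-statistic constant-rates test, and the survival-model framework that
treats branching times as waiting-time observations measured back from the
present — model A with constant hazard delta, model B with a Weibull hazard
h(x) = delta*beta*(delta*x)^(beta-1) whose shape beta < 1 concentrates
diversification near the present, and model C with a single temporal shift in
an otherwise constant hazard.  State-dependent diversification (BiSSE) lives
in :mod:`salmodiv.bisse` and is re-exported here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .bisse import (  # noqa: F401  (module surface: BiSSE ops live here too)
    BisseFit,
    BisseParams,
    McmcTrace,
    bisse_loglik,
    bisse_lrt,
    bisse_mcmc,
    bisse_ml,
)
from .io_formats import BranchingTimes, TestResult, branching_times

__all__ = [
    "LttCurve",
    "GammaResult",
    "SurvivalFit",
    "SurvivalComparison",
    "ltt",
    "gamma_test",
    "fit_survival",
    "akaike_weights",
    "BisseParams",
    "BisseFit",
    "McmcTrace",
    "bisse_loglik",
    "bisse_ml",
    "bisse_lrt",
    "bisse_mcmc",
]


# ---------------------------------------------------------------------------
# Lineages through time


@dataclass(frozen=True)
class LttCurve:
    """Step function (age Ma, lineage count), root (count 2) to present."""

    ages: np.ndarray  # branching ages, descending; ages[0] = root age
    counts: np.ndarray  # lineage count immediately after each branching

    @property
    def n_tips(self) -> int:
        return int(self.counts[-1])

    def count_at(self, age: float) -> int:
        """Reconstructed lineage count at ``age`` (Ma before present)."""
        if age > self.ages[0]:
            return 1
        return 1 + int(np.sum(self.ages >= age))

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"age_ma": self.ages, "lineages": self.counts})


def ltt(tree: dendropy.Tree, tol: float = 1e-6) -> LttCurve:
    """Lineage-through-time curve of an ultrametric binary tree."""
    bt = branching_times(tree, tol=tol)
    counts = np.arange(2, bt.n + 1)
    return LttCurve(ages=bt.times.copy(), counts=counts)


# ---------------------------------------------------------------------------
# Gamma constant-rates test


@dataclass(frozen=True)
class GammaResult:
    """Pybus–Harvey gamma with its two-tailed normal p-value."""

    gamma: float
    p_two_tailed: float
    n: int


def gamma_test(bt: BranchingTimes) -> GammaResult:
    """Constant-rates test based on the gamma-statistic.

    gamma = [ mean(T_2..T_{n-1}) - T/2 ] / [ T * sqrt(1/(12(n-2))) ]; under a
    constant-rate pure-birth process gamma is asymptotically standard normal.
    Positive values indicate branching times concentrated towards the present.
    """
    n = bt.n
    if n < 3:
        raise ValueError("gamma test requires >= 3 tips")
    if bt.T <= 0:
        raise ValueError("total lineage-time T is zero")
    inner = bt.T_i[:-1]  # T_2 .. T_{n-1}
    g = (inner.sum() / (n - 2) - bt.T / 2.0) / (bt.T * math.sqrt(1.0 / (12.0 * (n - 2))))
    p = 2.0 * (1.0 - norm.cdf(abs(g)))
    return GammaResult(gamma=float(g), p_two_tailed=float(p), n=n)


# ---------------------------------------------------------------------------
# Survival models A / B / C


@dataclass(frozen=True)
class SurvivalFit:
    model: str
    params: dict
    loglik: float
    n_params: int


@dataclass(frozen=True)
class SurvivalComparison:
    fit_a: SurvivalFit
    fit_b: SurvivalFit
    fit_c: SurvivalFit
    lrt_ab: TestResult
    lrt_ac: TestResult
    akaike_weights: dict  # over {"B", "C"}
    breakpoint_mode: str  # "fixed" or "profile"


def _fit_model_a(x: np.ndarray) -> SurvivalFit:
    n = x.size
    delta = n / x.sum()
    loglik = n * math.log(delta) - delta * x.sum()
    return SurvivalFit("A", {"delta": float(delta)}, float(loglik), 1)


def _weibull_profile_loglik(x: np.ndarray, beta: float) -> tuple[float, float]:
    """Profile log-likelihood over delta for fixed Weibull shape beta."""
    n = x.size
    s = np.sum(x**beta)
    delta = (n / s) ** (1.0 / beta)
    loglik = (
        n * math.log(beta)
        + n * beta * math.log(delta)
        + (beta - 1.0) * np.sum(np.log(x))
        - delta**beta * s
    )
    return float(loglik), float(delta)


def _fit_model_b(x: np.ndarray) -> SurvivalFit:
    res = minimize_scalar(
        lambda lb: -_weibull_profile_loglik(x, math.exp(lb))[0],
        bounds=(math.log(0.02), math.log(50.0)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [math.exp(res.x), 1.0]  # beta = 1 nests model A exactly
    best_beta, best_ll, best_delta = None, -np.inf, None
    for beta in candidates:
        ll, delta = _weibull_profile_loglik(x, beta)
        if ll > best_ll:
            best_beta, best_ll, best_delta = beta, ll, delta
    return SurvivalFit(
        "B", {"delta": best_delta, "beta": best_beta}, best_ll, 2
    )


def _model_c_at(x: np.ndarray, tc: float) -> tuple[float, float, float]:
    """MLEs and log-likelihood of the single-shift model for fixed Tc."""
    recent = x < tc
    d1, d2 = int(recent.sum()), int((~recent).sum())
    e1 = float(np.minimum(x, tc).sum())
    e2 = float(np.maximum(x - tc, 0.0).sum())
    loglik = 0.0
    delta1 = d1 / e1 if e1 > 0 else 0.0
    delta2 = d2 / e2 if e2 > 0 else 0.0
    if d1 > 0:
        loglik += d1 * math.log(delta1)
    loglik -= delta1 * e1
    if d2 > 0:
        loglik += d2 * math.log(delta2)
    loglik -= delta2 * e2
    return delta1, delta2, loglik


def _fit_model_c(x: np.ndarray, breakpoint) -> tuple[SurvivalFit, str]:
    if breakpoint == "profile":
        uniq = np.unique(x)
        if uniq.size < 2:
            raise ValueError("cannot profile a shift time on tied times")
        candidates = (uniq[1:] + uniq[:-1]) / 2.0
        best = max(
            ((tc, *_model_c_at(x, tc)) for tc in candidates),
            key=lambda row: row[3],
        )
        tc, d1, d2, ll = best
        return (
            SurvivalFit(
                "C", {"delta1": d1, "delta2": d2, "tc": float(tc)}, float(ll), 3
            ),
            "profile",
        )
    tc = float(breakpoint)
    if tc <= 0:
        raise ValueError("breakpoint must be positive (Ma before present)")
    d1, d2, ll = _model_c_at(x, tc)
    return (
        SurvivalFit("C", {"delta1": d1, "delta2": d2, "tc": tc}, float(ll), 2),
        "fixed",
    )


def akaike_weights(logliks, n_params) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    ll = np.asarray(logliks, dtype=float)
    k = np.asarray(n_params, dtype=float)
    if ll.size < 2:
        raise ValueError("need at least two models")
    aic = 2.0 * k - 2.0 * ll
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def fit_survival(bt: BranchingTimes, breakpoint="profile") -> SurvivalComparison:
    """Fit the three survival models to branching times and compare them.

    Branching times are treated as uncensored waiting times measured from the
    present (no extinction correction).  Model A has the closed-form MLE
    delta = N / sum(x); model B profiles the Weibull shape; model C either
    uses a fixed shift age (``breakpoint`` in Ma) or profiles it over
    midpoints of the observed branching times.  LRT df is 1 for A-vs-B, and
    1 (fixed Tc) or 2 (profiled Tc — the shift age is estimated, a caveat the
    chi-square reference distribution only roughly covers).
    """
    x = np.asarray(bt.times, dtype=float)
    if x.size < 3:
        raise ValueError("survival models require >= 4 tips")
    if np.any(x <= 0):
        raise ValueError(
            "branching times must be strictly positive waiting times"
        )
    fit_a = _fit_model_a(x)
    fit_b = _fit_model_b(x)
    fit_c, mode = _fit_model_c(x, breakpoint)

    def lrt(full: SurvivalFit, null: SurvivalFit) -> TestResult:
        stat = max(2.0 * (full.loglik - null.loglik), 0.0)
        df = full.n_params - null.n_params
        return TestResult(
            statistic=float(stat),
            df=df,
            pvalue=float(chi2.sf(stat, df)),
            method=f"survival_{null.model}_vs_{full.model}",
        )

    lrt_ac = lrt(fit_c, fit_a)
    if mode == "profile":
        warnings.warn(
            "model C shift time was profiled; the A-vs-C LRT uses df=2 but the "
            "breakpoint is not a regular parameter",
            RuntimeWarning,
            stacklevel=2,
        )
    w = akaike_weights(
        [fit_b.loglik, fit_c.loglik], [fit_b.n_params, fit_c.n_params]
    )
    return SurvivalComparison(
        fit_a=fit_a,
        fit_b=fit_b,
        fit_c=fit_c,
        lrt_ab=lrt(fit_b, fit_a),
        lrt_ac=lrt_ac,
        akaike_weights={"B": float(w[0]), "C": float(w[1])},
        breakpoint_mode=mode,
    )
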