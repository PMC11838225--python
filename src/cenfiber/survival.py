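"""Censored survival analysis of optical-trap rupture-force assays.

In a force-ramp experiment the load on a kinetochore-microtubule attachment
increases linearly (0.25 pN/s) until the attachment ruptures; force is
therefore a monotone reparameterization of time and plays the role of the
survival axis. "Escape" events — the bead left the trap, or the recording
ended, before rupture — are right-censored observations: the attachment is
known to have survived at least to the recorded force.

The module provides the Kaplan-Meier product-limit estimator with Greenwood
variance and log-log 95% bands, the survival median, the two-group log-rank
test, and a BIC-based Gaussian-mixture assessment of whether a rupture-force
sample is uni- or bimodal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .errors import MedianUndefinedError, ParameterError

__all__ = [
    "RuptureEvent",
    "SurvivalCurve",
    "LogRankResult",
    "BimodalityResult",
    "km_survival",
    "survival_median",
    "logrank",
    "bimodality",
]


@dataclass(frozen=True)
class RuptureEvent:
    """One force-ramp outcome: the recorded force and whether it ruptured."""

    force: float
    outcome: str  # "rupture" | "escape"
    condition: str = ""

    def __post_init__(self):
        if not np.isfinite(self.force) or self.force <= 0:
            raise ParameterError(f"force must be finite and positive, got {self.force}")
        if self.outcome not in ("rupture", "escape"):
            raise ParameterError(f"outcome must be 'rupture' or 'escape', got {self.outcome!r}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over force.

    ``breakpoints`` are the distinct rupture forces; ``survival[i]`` is the
    estimate just after ``breakpoints[i]``. ``censored[i]`` counts escapes in
    ``[breakpoints[i], breakpoints[i+1])`` (escapes below the first breakpoint
    are in ``censored_before_first``).
    """

    breakpoints: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    greenwood_variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_total: int
    censored_before_first: int = 0

    def survival_at(self, force: float) -> float:
        """Step-function value of the estimate at ``force``."""
        i = int(np.searchsorted(self.breakpoints, force, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass(frozen=True)
class BimodalityResult:
    bic_1: float
    bic_2: float
    preferred: str  # "unimodal" | "bimodal"
    margin: float
    means: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    converged: bool = True


def _split(events) -> tuple[np.ndarray, np.ndarray]:
    forces = np.array([e.force for e in events], dtype=float)
    ruptured = np.array([e.outcome == "rupture" for e in events], dtype=bool)
    return forces, ruptured


def km_survival(events, z: float = 1.959963984540054) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator over force.

    At each distinct rupture force f with d ruptures and n events still at
    risk (force >= f; escapes recorded exactly at f are still at risk there,
    i.e. ruptures are processed before censorings at tied forces), the
    survival estimate multiplies by (1 - d/n). The variance is Greenwood's
    formula and the 95% band uses the log(-log) transform.
    """
    if len(events) == 0:
        raise ParameterError("km_survival requires at least one event")
    forces, ruptured = _split(events)
    n_total = forces.size
    rupture_forces = np.unique(forces[ruptured])
    if rupture_forces.size == 0:
        return SurvivalCurve(
            breakpoints=rupture_forces,
            survival=np.empty(0),
            at_risk=np.empty(0, dtype=np.int64),
            events=np.empty(0, dtype=np.int64),
            censored=np.empty(0, dtype=np.int64),
            greenwood_variance=np.empty(0),
            ci_lower=np.empty(0),
            ci_upper=np.empty(0),
            n_total=n_total,
            censored_before_first=n_total,
        )
    sorted_forces = np.sort(forces)
    at_risk = n_total - np.searchsorted(sorted_forces, rupture_forces, side="left")
    d = np.array([np.count_nonzero(forces[ruptured] == f) for f in rupture_forces])
    # exact rational product so the uncensored case reduces to the empirical
    # survival function bit-for-bit (the telescoping (n-d)/n cancels exactly)
    acc = Fraction(1)
    surv = np.empty(rupture_forces.size)
    for i, (di, ni) in enumerate(zip(d, at_risk)):
        acc *= Fraction(int(ni - di), int(ni))
        surv[i] = float(acc)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_sum = np.cumsum(np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf))
        var = surv**2 * gw_sum
        # log-log band: exp(-exp(log(-log S) ± z * se(log(-log S))))
        log_s = np.log(surv)
        se_loglog = np.sqrt(gw_sum) / np.abs(log_s)
        theta = np.log(-log_s)
        lo = np.exp(-np.exp(theta + z * se_loglog))
        hi = np.exp(-np.exp(theta - z * se_loglog))
    degenerate = (surv <= 0) | (surv >= 1)
    lo[degenerate] = surv[degenerate]
    hi[degenerate] = surv[degenerate]
    var[surv <= 0] = 0.0
    cens_forces = np.sort(forces[~ruptured])
    edges = np.searchsorted(cens_forces, np.append(rupture_forces, np.inf), side="left")
    censored_before_first = int(edges[0])
    censored = np.diff(edges)
    return SurvivalCurve(
        breakpoints=rupture_forces,
        survival=surv,
        at_risk=at_risk.astype(np.int64),
        events=d.astype(np.int64),
        censored=censored.astype(np.int64),
        greenwood_variance=var,
        ci_lower=lo,
        ci_upper=hi,
        n_total=n_total,
        censored_before_first=censored_before_first,
    )


def survival_median(curve: SurvivalCurve) -> float:
    """Smallest breakpoint at which the survival estimate is <= 0.5."""
    below = np.flatnonzero(curve.survival <= 0.5)
    if below.size == 0:
        raise MedianUndefinedError(
            "survival curve never reaches 0.5 (heavy censoring or too few ruptures)"
        )
    return float(curve.breakpoints[below[0]])


def logrank(a, b, include_escapes: bool = True) -> LogRankResult:
    """Two-group log-rank test over force.

    At each distinct rupture force, compares observed rupture counts in group
    A against the hypergeometric expectation given the pooled risk sets;
    the statistic is chi-square with 1 df, two-sided.
    ``include_escapes=False`` drops censored events entirely instead of
    treating them as right-censored.
    """
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be non-empty")
    if not include_escapes:
        a = [e for e in a if e.outcome == "rupture"]
        b = [e for e in b if e.outcome == "rupture"]
        if len(a) == 0 or len(b) == 0:
            raise ParameterError("a group has no ruptures after excluding escapes")
    fa, ra = _split(a)
    fb, rb = _split(b)
    for label, r in (("a", ra), ("b", rb)):
        if not r.any():
            warnings.warn(f"group {label} has zero ruptures (all censored)", stacklevel=2)
    times = np.unique(np.concatenate([fa[ra], fb[rb]]))
    sa, sb = np.sort(fa), np.sort(fb)
    n1 = fa.size - np.searchsorted(sa, times, side="left")
    n2 = fb.size - np.searchsorted(sb, times, side="left")
    d1 = np.array([np.count_nonzero(fa[ra] == t) for t in times], dtype=float)
    d2 = np.array([np.count_nonzero(fb[rb] == t) for t in times], dtype=float)
    n = (n1 + n2).astype(float)
    d = d1 + d2
    e1 = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    v = np.where(n > 1, v, 0.0)
    o1, ee1 = float(d1.sum()), float(e1.sum())
    var = float(v.sum())
    chi2 = 0.0 if var == 0 else (o1 - ee1) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        observed=(o1, float(d2.sum())),
        expected=(ee1, float(d2.sum() + d1.sum() - ee1)),
    )


def bimodality(
    forces,
    margin: float = 6.0,
    seed: int = 0,
    n_init: int = 5,
) -> BimodalityResult:
    """Is a rupture-force sample better described by one Gaussian or two?

    Fits 1- and 2-component Gaussian mixtures by EM (multi-start, fixed seed)
    and compares BIC; "bimodal" requires the 2-component fit to beat the
    1-component fit by at least ``margin`` BIC units (default 6, the usual
    strong-evidence convention). Only true rupture forces should be passed in;
    censored escapes carry no modal information about rupture strength.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(forces, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ParameterError(f"bimodality requires n >= 20 rupture forces, got {x.shape[0]}")
    fits = {}
    converged = True
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=n_init, random_state=seed)
        gm.fit(x)
        converged &= bool(gm.converged_)
        fits[k] = gm
    bic1 = float(fits[1].bic(x))
    bic2 = float(fits[2].bic(x))
    if not converged:
        preferred = "unimodal"
    else:
        preferred = "bimodal" if bic2 + margin < bic1 else "unimodal"
    means: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    if preferred == "bimodal":
        order = np.argsort(fits[2].means_.ravel())
        means = tuple(float(m) for m in fits[2].means_.ravel()[order])
        weights = tuple(float(w) for w in fits[2].weights_[order])
    return BimodalityResult(
        bic_1=bic1,
        bic_2=bic2,
        preferred=preferred,
        margin=margin,
        means=means,
        weights=weights,
        converged=converged,
    )
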