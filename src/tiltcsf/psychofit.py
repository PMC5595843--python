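"""Descriptive (ad-hoc) psychometric fitting of trial-level data.

Two measures share a three-key response design:

* **Contrast detection (CSF)** -- two-interval forced choice with an
  "undecided" third key.  A 2D logistic surface over (contrast, SF) is
  fitted, whose midpoint traces the sensitivity function
  ``S(f) = M f^a exp(-f / b)``.  The guess rate gamma is not fitted but
  derived from the session's third-key usage ``p3`` through
  ``gamma = max(0, (1 - p3 / 0.7) / 2)``: a subject who never uses the
  third key guesses at the standard 2AFC rate of 50%, and heavier usage
  removes guesses from the scored responses.
* **Tilt discrimination** -- clockwise/counter-clockwise judgments with
  a "not seen" third key.  Per surround orientation a 1D logistic is
  fitted whose midpoint is the perceived vertical ("bias"); spreads of
  opposite surround orientations are tied by the symmetry of the
  design.  "Not seen" trials are removed before fitting; their pooled
  proportion is the surround-suppression summary.

All fits maximise the Bernoulli likelihood (flat-prior MAP over bounded
boxes, i.e. constrained maximum likelihood) with a deterministic
multi-start Nelder-Mead search, and report the negative log-likelihood
at the optimum for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .tilt_model import LOGISTIC_SLOPE

__all__ = [
    "guess_rate_from_undecided",
    "sensitivity_function",
    "eval_csf_psychometric",
    "eval_tilt_psychometric",
    "CSFFit",
    "TiltFit",
    "fit_csf_adhoc",
    "fit_tilt_adhoc",
    "suppression_proportion",
    "logit_with_guard",
    "bernoulli_nll",
]

# Trial-table column dialect (CSV-friendly).  CSF rows carry
# (sf, contrast, response in {correct, incorrect, undecided}); tilt rows
# carry (sf, surround_orientation, target_orientation, response in
# {cw, ccw, not_seen}).
CSF_RESPONSES = ("correct", "incorrect", "undecided")
TILT_RESPONSES = ("cw", "ccw", "not_seen")

_PCLIP = 1e-9


def guess_rate_from_undecided(p3: float) -> float:
    """Guess rate implied by the proportion of third-key presses:
    ``gamma = max(0, (1 - p3 / 0.7) / 2)``, i.e. 50% for a subject who
    never declares indecision, 0 from ``p3 >= 0.7`` on."""
    if not 0.0 <= p3 <= 1.0:
        raise ValueError("p3 must lie in [0, 1]")
    return max(0.0, (1.0 - p3 / 0.7) / 2.0)


def sensitivity_function(f: np.ndarray | float, M: float, a: float,
                         b: float) -> np.ndarray | float:
    """Three-parameter contrast sensitivity shape ``M f^a exp(-f/b)``."""
    f = np.asarray(f, dtype=float)
    out = M * f ** a * np.exp(-f / b)
    return out if out.ndim else float(out)


def eval_csf_psychometric(c: np.ndarray | float, f: np.ndarray | float,
                          M: float, a: float, b: float, sigma: float,
                          gamma: float, lam: float = 0.01) -> np.ndarray | float:
    """2D detection psychometric surface.

    Logistic in log-contrast with midpoint at the inverse sensitivity
    ``1 / S(f)`` and slope ``log(21/4) / sigma``, running from the guess
    rate ``gamma`` to ``1 - lam``.  One spread unit above the midpoint
    lands at the 84% convention point (21/25 of the range).
    """
    c = np.asarray(c, dtype=float)
    s = sensitivity_function(f, M, a, b)
    core = expit(LOGISTIC_SLOPE * (np.log(c) + np.log(s)) / sigma)
    out = gamma + (1.0 - gamma - lam) * core
    return out if out.ndim else float(out)


def eval_tilt_psychometric(theta: np.ndarray | float, bias: float,
                           sigma: float, lam: float = 0.01) -> np.ndarray | float:
    """1D orientation psychometric: probability of a clockwise response,
    logistic in the target orientation with midpoint ``bias``."""
    theta = np.asarray(theta, dtype=float)
    core = expit(LOGISTIC_SLOPE * (theta - bias) / sigma)
    out = lam + (1.0 - 2.0 * lam) * core
    return out if out.ndim else float(out)


def bernoulli_nll(p: np.ndarray, success: np.ndarray,
                  weights: np.ndarray | None = None) -> float:
    """Negative log Bernoulli likelihood with probability clipping."""
    p = np.clip(np.asarray(p, dtype=float), _PCLIP, 1.0 - _PCLIP)
    success = np.asarray(success, dtype=float)
    ll = success * np.log(p) + (1.0 - success) * np.log(1.0 - p)
    if weights is not None:
        ll = ll * np.asarray(weights, dtype=float)
    return float(-ll.sum())


def _multistart_simplex(nll, starts, maxiter=600):
    """Deterministic multi-start Nelder-Mead; returns (x, fun)."""
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(nll, np.asarray(x0, dtype=float), method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-6,
                                "fatol": 1e-8})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    return best_x, best_f


class _BoxTransform:
    """Sigmoid box transform mapping R^k onto open parameter boxes, so the
    simplex search is unconstrained while the fit stays inside its bounds."""

    def __init__(self, bounds):
        self.lo = np.array([b[0] for b in bounds], dtype=float)
        self.hi = np.array([b[1] for b in bounds], dtype=float)

    def to_params(self, z: np.ndarray) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * expit(z)

    def to_z(self, params: np.ndarray) -> np.ndarray:
        frac = (np.asarray(params, dtype=float) - self.lo) / (self.hi - self.lo)
        return logit(np.clip(frac, 1e-6, 1.0 - 1e-6))


@dataclass
class CSFFit:
    """Descriptive CSF fit: sensitivity shape, spread, and fit objective."""

    M: float
    a: float
    b: float
    sigma: float
    gamma: float
    lam: float
    neg_log_ml: float
    n_trials: int
    p3: float
    boundary_warning: bool = False

    @property
    def peak_sf(self) -> float:
        return self.a * self.b

    def sensitivity(self, f: np.ndarray | float) -> np.ndarray | float:
        return sensitivity_function(f, self.M, self.a, self.b)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("M", "a", "b", "sigma", "gamma", "lam", "neg_log_ml",
                 "n_trials", "p3", "boundary_warning")}


#: Default search boxes for the descriptive CSF fit.
CSF_BOUNDS = {"M": (0.5, 2000.0), "a": (0.05, 6.0), "b": (0.1, 40.0),
              "sigma": (0.02, 5.0)}


def undecided_loglik_weights(n_undecided: int) -> tuple[float, float]:
    """Likelihood treatment of undecided detection trials.

    Pressing the third key marks a trial on which the subject had no
    percept to report; in the scored-response model such a trial is
    equally compatible with either outcome.  Each undecided trial
    therefore contributes half a correct and half an incorrect
    pseudo-trial to the Bernoulli likelihood (its main information,
    the guess rate, enters through ``p3``).  Isolated here so the
    treatment can be swapped in one place.
    """
    return 0.5 * n_undecided, 0.5 * n_undecided


def fit_csf_adhoc(trials: pd.DataFrame, lam: float = 0.01,
                  gamma: float | None = None,
                  bounds: dict | None = None) -> CSFFit:
    """Fit the 2D detection surface to a CSF session.

    ``trials`` needs columns ``sf``, ``contrast`` and ``response``.
    ``gamma`` defaults to the value derived from the session's
    third-key proportion; it is a data-derived constant, never fitted.
    """
    if not len(trials):
        raise ValueError("no trials to fit")
    b = dict(CSF_BOUNDS)
    if bounds:
        b.update(bounds)
    undecided = trials["response"] == "undecided"
    p3 = float(undecided.mean())
    if gamma is None:
        gamma = guess_rate_from_undecided(p3)
    answered = trials.loc[~undecided]
    y = (answered["response"] == "correct").to_numpy(dtype=float)
    c = answered["contrast"].to_numpy(dtype=float)
    f = answered["sf"].to_numpy(dtype=float)
    cu = trials.loc[undecided, "contrast"].to_numpy(dtype=float)
    fu = trials.loc[undecided, "sf"].to_numpy(dtype=float)
    boundary = bool(y.size and (y.all() or not y.any()))

    box = _BoxTransform([b["M"], b["a"], b["b"], b["sigma"]])

    def nll(z: np.ndarray) -> float:
        M, a_, b_, sigma = box.to_params(z)
        total = bernoulli_nll(
            eval_csf_psychometric(c, f, M, a_, b_, sigma, gamma, lam), y)
        if cu.size:
            pu = np.clip(eval_csf_psychometric(cu, fu, M, a_, b_, sigma,
                                               gamma, lam), _PCLIP, 1 - _PCLIP)
            total -= 0.5 * (np.log(pu) + np.log1p(-pu)).sum()
        return total

    starts = [box.to_z(np.array(s)) for s in
              [(20.0, 1.0, 3.0, 0.4), (100.0, 1.0, 3.0, 0.4),
               (20.0, 0.5, 8.0, 0.8), (100.0, 2.0, 1.5, 0.2),
               (5.0, 1.0, 5.0, 1.0)]]
    z, fun = _multistart_simplex(nll, starts)
    M, a_, b_, sigma = box.to_params(z)
    return CSFFit(M=float(M), a=float(a_), b=float(b_), sigma=float(sigma),
                  gamma=float(gamma), lam=float(lam), neg_log_ml=fun,
                  n_trials=int(len(trials)), p3=p3, boundary_warning=boundary)


@dataclass
class TiltFit:
    """Descriptive tilt fit: per-SO biases, pair-tied thresholds, and
    derived half-difference biases and pooled suppression."""

    biases: dict = field(default_factory=dict)          # SO -> perceived vertical (deg)
    thresholds: dict = field(default_factory=dict)      # |SO| -> spread (deg)
    half_difference: dict = field(default_factory=dict) # |SO| -> (bias+ - bias-)/2
    lam: float = 0.01
    neg_log_ml: float = 0.0
    insufficient: list = field(default_factory=list)    # SOs with < min_trials data

    def to_dict(self) -> dict:
        return {"biases": {str(k): v for k, v in self.biases.items()},
                "thresholds": {str(k): v for k, v in self.thresholds.items()},
                "half_difference": {str(k): v for k, v in self.half_difference.items()},
                "lam": self.lam, "neg_log_ml": self.neg_log_ml,
                "insufficient": list(self.insufficient)}


TILT_BIAS_BOUNDS = (-45.0, 45.0)
TILT_SIGMA_BOUNDS = (0.2, 60.0)


def fit_tilt_adhoc(trials: pd.DataFrame, lam: float = 0.01,
                   min_trials: int = 5) -> TiltFit:
    """Fit per-SO logistic psychometric functions to a tilt session.

    ``trials`` needs columns ``surround_orientation``,
    ``target_orientation`` and ``response``.  Not-seen trials are
    dropped first.  For each pair of opposite surround orientations a
    joint fit with two biases and one shared spread is performed; the
    derived half-difference bias cancels any constant response bias of
    the subject.
    """
    fit = TiltFit(lam=lam)
    seen = trials.loc[trials["response"] != "not_seen"]
    sos = np.unique(trials["surround_orientation"].to_numpy(dtype=float))
    total_nll = 0.0
    for mag in sorted({abs(so) for so in sos}):
        pair = [so for so in sos if abs(so) == mag]
        sub = seen.loc[np.isin(seen["surround_orientation"], pair)]
        counts = {so: int((sub["surround_orientation"] == so).sum()) for so in pair}
        if any(v < min_trials for v in counts.values()):
            fit.insufficient.extend(pair)
            continue
        theta = sub["target_orientation"].to_numpy(dtype=float)
        y = (sub["response"] == "cw").to_numpy(dtype=float)
        so_col = sub["surround_orientation"].to_numpy(dtype=float)
        n_b = len(pair)
        box = _BoxTransform([TILT_BIAS_BOUNDS] * n_b + [TILT_SIGMA_BOUNDS])
        masks = [so_col == so for so in pair]

        def nll(z: np.ndarray) -> float:
            p = box.to_params(z)
            sigma = p[-1]
            total = 0.0
            for i, m in enumerate(masks):
                pr = eval_tilt_psychometric(theta[m], p[i], sigma, lam)
                total += bernoulli_nll(pr, y[m])
            return total

        starts = [box.to_z(np.array(list(b0) + [s0]))
                  for b0 in ([(0.0,) * n_b, (3.0, -3.0)[:n_b],
                              (-3.0, 3.0)[:n_b]])
                  for s0 in (2.0, 6.0)]
        z, fun = _multistart_simplex(nll, starts)
        p = box.to_params(z)
        for i, so in enumerate(pair):
            fit.biases[float(so)] = float(p[i])
        fit.thresholds[float(mag)] = float(p[-1])
        if len(pair) == 2:
            fit.half_difference[float(mag)] = 0.5 * (
                fit.biases[float(mag)] - fit.biases[float(-mag)])
        total_nll += fun
    fit.neg_log_ml = total_nll
    return fit


def suppression_proportion(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion of not-seen responses, pooled over opposite surround
    orientations, per (|SO|, SF)."""
    df = trials.copy()
    df["abs_so"] = df["surround_orientation"].abs()
    grouped = df.groupby(["abs_so", "sf"], as_index=False).agg(
        n_trials=("response", "size"),
        n_not_seen=("response", lambda r: int((r == "not_seen").sum())))
    grouped["proportion"] = grouped["n_not_seen"] / grouped["n_trials"]
    return grouped


def logit_with_guard(p: np.ndarray | float, floor: float = 1.0 / 120.0
                     ) -> np.ndarray | float:
    """Logit transform with zero/one proportions pulled to ``floor`` /
    ``1 - floor`` (the usual guard before analysing proportions)."""
    p = np.clip(np.asarray(p, dtype=float), floor, 1.0 - floor)
    out = logit(p)
    return out if out.ndim else float(out)
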