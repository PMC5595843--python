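"""Two-stage model fitting pipeline and cohort-level analyses.

Stage 1 fits the tilt-repulsion model to the orientation-discrimination
trials of one eye at one SF: the likelihood of the clockwise /
counter-clockwise responses under the model psychometric function is
maximised over (I_inh, sigma_theta, threshold_sigma), using only the
direct-effect surrounds (+-15 and +-30 deg; the +-75 deg indirect effect
lies outside the model's reach) and excluding not-seen trials.  Stage 2
freezes the low-SF ``I_inh`` and fits the detection trials over the
neuronal sensitivity parameters (c_min, a, b), with the guess rate
derived from the session's third-key usage.  Both stages report the
negative log-likelihood at the optimum so the model can be compared
like-for-like against the descriptive fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .csf_model import DetectionNoise, DEFAULT_NOISE, NeuronalSensitivity, \
    detection_probability
from .psychofit import (
    CSFFit,
    TiltFit,
    _BoxTransform,
    _multistart_simplex,
    bernoulli_nll,
    guess_rate_from_undecided,
)
from .tilt_model import TiltParams, predict_bias, tilt_psychometric_model
from .v1_core import DEFAULT_FIXED, FixedParams

__all__ = [
    "TiltModelFit",
    "CSFModelFit",
    "EyeResult",
    "fit_tilt_v1",
    "fit_csf_v1",
    "fit_eye",
    "compare_fits",
    "choose_sfs",
    "vector_blur",
    "correlate_parameters",
    "MODEL_SURROUNDS",
]

#: Surround orientations the model stage is fit to (direct effect only).
MODEL_SURROUNDS = (15.0, 30.0)

#: Search boxes of the two model stages.  Generous around the plausible
#: physiological ranges; configurable per call.
TILT_MODEL_BOUNDS = {"I_inh": (0.0, 5.0), "sigma_theta": (2.0, 60.0),
                     "threshold_sigma": (0.2, 60.0)}
CSF_MODEL_BOUNDS = {"c_min": (1e-4, 1.0), "a": (0.1, 5.0), "b": (0.2, 32.0)}


@dataclass
class TiltModelFit:
    """Stage-1 result: network parameters inferred from tilt trials."""

    I_inh: float
    sigma_theta: float
    threshold_sigma: float
    lam: float
    neg_log_ml: float
    n_trials: int
    biases: dict = field(default_factory=dict)  # SO -> predicted bias
    converged: bool = True

    def params(self) -> TiltParams:
        return TiltParams(self.I_inh, self.sigma_theta, self.threshold_sigma,
                          self.lam)

    def to_dict(self) -> dict:
        return {"I_inh": self.I_inh, "sigma_theta": self.sigma_theta,
                "threshold_sigma": self.threshold_sigma, "lam": self.lam,
                "neg_log_ml": self.neg_log_ml, "n_trials": self.n_trials,
                "biases": {str(k): v for k, v in self.biases.items()},
                "converged": self.converged}


@dataclass
class CSFModelFit:
    """Stage-2 result: neuronal sensitivity with inherited inhibition."""

    c_min: float
    a: float
    b: float
    I_inh: float  # inherited from stage 1, never fitted here
    gamma: float
    lam: float
    neg_log_ml: float
    n_trials: int
    converged: bool = True

    def sensitivity(self) -> NeuronalSensitivity:
        return NeuronalSensitivity(self.c_min, self.a, self.b)

    def to_dict(self) -> dict:
        return {"c_min": self.c_min, "a": self.a, "b": self.b,
                "I_inh": self.I_inh, "gamma": self.gamma, "lam": self.lam,
                "neg_log_ml": self.neg_log_ml, "n_trials": self.n_trials,
                "converged": self.converged}


def _usable_tilt_trials(trials: pd.DataFrame,
                        surrounds=MODEL_SURROUNDS) -> pd.DataFrame:
    mags = [abs(s) for s in surrounds]
    keep = (trials["response"] != "not_seen") & \
        trials["surround_orientation"].abs().isin(mags)
    return trials.loc[keep]


def fit_tilt_v1(trials: pd.DataFrame, lam: float = 0.01,
                fixed: FixedParams = DEFAULT_FIXED,
                bounds: dict | None = None,
                weights: np.ndarray | None = None,
                n_starts: int = 3) -> TiltModelFit:
    """Fit (I_inh, sigma_theta, threshold_sigma) to one tilt session.

    Only +-15 and +-30 deg surrounds enter; not-seen trials are
    excluded.  The model bias is antisymmetric, so each likelihood
    evaluation needs only one bias computation per surround magnitude.
    Optional ``weights`` turn the trials into fractional pseudo-trials
    (used for noise-free self-consistency checks).
    """
    b = dict(TILT_MODEL_BOUNDS)
    if bounds:
        b.update(bounds)
    sub = _usable_tilt_trials(trials)
    if not len(sub):
        raise ValueError("no usable tilt trials at the model surrounds")
    theta = sub["target_orientation"].to_numpy(dtype=float)
    so = sub["surround_orientation"].to_numpy(dtype=float)
    y = (sub["response"] == "cw").to_numpy(dtype=float)
    if weights is None:
        w = None
    else:  # weights align positionally with the rows of ``trials``
        w = np.asarray(weights, dtype=float)[trials.index.get_indexer(sub.index)]
    mags = sorted({abs(s) for s in so})
    sign = np.sign(so)
    mag_masks = [np.abs(so) == m for m in mags]

    box = _BoxTransform([b["I_inh"], b["sigma_theta"], b["threshold_sigma"]])

    def nll(z: np.ndarray) -> float:
        I_inh, sigma_theta, thr = box.to_params(z)
        params = TiltParams(I_inh, sigma_theta, thr, lam)
        total = 0.0
        for m, mask in zip(mags, mag_masks):
            try:
                bias = predict_bias(m, params, fixed)
            except ValueError:
                return 1e9  # inhibition silenced the population
            p = tilt_psychometric_model(theta[mask], m, params,
                                        bias=sign[mask] * bias)
            total += bernoulli_nll(p, y[mask],
                                   None if w is None else w[mask])
        return total

    # coarse deterministic grid, then simplex from the best corners
    grid = [(i, s, t)
            for i in (0.03, 0.1, 0.25)
            for s in (10.0, 20.0, 32.0)
            for t in (1.5, 4.0, 10.0)]
    zs = [box.to_z(np.array(g)) for g in grid]
    scored = sorted(zip([nll(z) for z in zs], range(len(zs))))
    starts = [zs[i] for _, i in scored[:n_starts]]
    z, fun = _multistart_simplex(nll, starts)
    I_inh, sigma_theta, thr = box.to_params(z)
    fit_params = TiltParams(float(I_inh), float(sigma_theta), float(thr), lam)
    biases = {}
    for m in mags:
        bias = predict_bias(m, fit_params, fixed)
        biases[float(m)] = bias
        biases[float(-m)] = -bias
    return TiltModelFit(I_inh=float(I_inh), sigma_theta=float(sigma_theta),
                        threshold_sigma=float(thr), lam=lam, neg_log_ml=fun,
                        n_trials=int(len(sub)), biases=biases)


def fit_csf_v1(trials: pd.DataFrame, I_inh: float, lam: float = 0.01,
               gamma: float | None = None,
               fixed: FixedParams = DEFAULT_FIXED,
               noise: DetectionNoise = DEFAULT_NOISE,
               bounds: dict | None = None,
               n_starts: int = 3) -> CSFModelFit:
    """Fit (c_min, a, b) to one detection session with ``I_inh`` frozen.

    The guess rate comes from the session's third-key proportion, as in
    the descriptive fit; undecided trials contribute half-correct
    pseudo-trials through the same treatment.
    """
    b = dict(CSF_MODEL_BOUNDS)
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

    box = _BoxTransform([b["c_min"], b["a"], b["b"]])

    def nll(z: np.ndarray) -> float:
        c_min, a_, b_ = box.to_params(z)
        sens = NeuronalSensitivity(c_min, a_, b_)
        p = detection_probability(c, f, sens, I_inh, gamma, lam, fixed, noise)
        total = bernoulli_nll(p, y)
        if cu.size:
            pu = np.clip(detection_probability(cu, fu, sens, I_inh, gamma,
                                               lam, fixed, noise),
                         1e-9, 1.0 - 1e-9)
            total -= 0.5 * (np.log(pu) + np.log1p(-pu)).sum()
        return total

    grid = [(cm, a_, b_)
            for cm in (0.005, 0.02, 0.08)
            for a_ in (0.6, 1.2)
            for b_ in (1.5, 4.0)]
    zs = [box.to_z(np.array(g)) for g in grid]
    scored = sorted(zip([nll(z) for z in zs], range(len(zs))))
    starts = [zs[i] for _, i in scored[:n_starts]]
    z, fun = _multistart_simplex(nll, starts)
    c_min, a_, b_ = box.to_params(z)
    return CSFModelFit(c_min=float(c_min), a=float(a_), b=float(b_),
                       I_inh=float(I_inh), gamma=float(gamma), lam=lam,
                       neg_log_ml=fun, n_trials=int(len(trials)))


def noise_free_tilt_trials(params: TiltParams, n_per_point: float = 100.0,
                           surrounds=MODEL_SURROUNDS,
                           n_theta: int = 25,
                           fixed: FixedParams = DEFAULT_FIXED,
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Fractional pseudo-trials carrying the model's exact response
    probabilities (for self-consistency recovery checks).

    For each surround (both signs) a ladder of target orientations spans
    the psychometric transition; every level contributes a clockwise and
    a counter-clockwise pseudo-trial weighted by the exact probability
    mass.  Returns the trial table and the weight vector aligned with
    its rows.
    """
    rows, weights = [], []
    for mag in surrounds:
        bias = predict_bias(mag, params, fixed)
        for sgn in (1.0, -1.0):
            so = sgn * mag
            thetas = sgn * bias + np.linspace(-3.0, 3.0, n_theta) \
                * params.threshold_sigma
            p = tilt_psychometric_model(thetas, so, params, fixed,
                                        bias=sgn * bias)
            for th, pc in zip(thetas, p):
                rows.append({"measure": "tilt", "sf": np.nan,
                             "surround_orientation": so,
                             "target_orientation": float(th),
                             "response": "cw"})
                weights.append(n_per_point * pc)
                rows.append({"measure": "tilt", "sf": np.nan,
                             "surround_orientation": so,
                             "target_orientation": float(th),
                             "response": "ccw"})
                weights.append(n_per_point * (1.0 - pc))
    return pd.DataFrame(rows), np.asarray(weights)


@dataclass
class EyeResult:
    """Complete per-eye fitting result of the two-stage pipeline."""

    eye_type: str
    low_sf: float
    high_sf: float
    tilt_low: TiltModelFit
    tilt_high: TiltModelFit | None
    csf_model: CSFModelFit
    adhoc_csf: CSFFit | None = None
    adhoc_tilt_low: TiltFit | None = None
    adhoc_tilt_high: TiltFit | None = None
    predicted_low_sf_sensitivity: float | None = None

    def __post_init__(self) -> None:
        if self.csf_model.I_inh != self.tilt_low.I_inh:
            raise ValueError(
                "stage 2 must inherit the low-SF tilt fit's I_inh")

    def to_dict(self) -> dict:
        return {
            "eye_type": self.eye_type, "low_sf": self.low_sf,
            "high_sf": self.high_sf,
            "tilt_low": self.tilt_low.to_dict(),
            "tilt_high": None if self.tilt_high is None else self.tilt_high.to_dict(),
            "csf_model": self.csf_model.to_dict(),
            "adhoc_csf": None if self.adhoc_csf is None else self.adhoc_csf.to_dict(),
            "adhoc_tilt_low": None if self.adhoc_tilt_low is None else self.adhoc_tilt_low.to_dict(),
            "adhoc_tilt_high": None if self.adhoc_tilt_high is None else self.adhoc_tilt_high.to_dict(),
            "predicted_low_sf_sensitivity": self.predicted_low_sf_sensitivity,
        }


def fit_eye(tilt_trials_low: pd.DataFrame, csf_trials: pd.DataFrame,
            eye_type: str = "NTE",
            tilt_trials_high: pd.DataFrame | None = None,
            low_sf: float | None = None, high_sf: float | None = None,
            lam: float = 0.01, fixed: FixedParams = DEFAULT_FIXED,
            noise: DetectionNoise = DEFAULT_NOISE,
            with_adhoc: bool = True) -> EyeResult:
    """Run the full two-stage pipeline for one eye.

    Stage 1 on the low-SF (and optionally high-SF) tilt session, stage 2
    on the detection session with the low-SF ``I_inh`` frozen.
    Descriptive fits of the same trial sets are attached for model
    comparison unless ``with_adhoc`` is false.
    """
    from . import psychofit
    from .csf_model import threshold_contrast

    tilt_low = fit_tilt_v1(tilt_trials_low, lam=lam, fixed=fixed)
    tilt_high = None
    if tilt_trials_high is not None:
        tilt_high = fit_tilt_v1(tilt_trials_high, lam=lam, fixed=fixed)
    csf_model = fit_csf_v1(csf_trials, I_inh=tilt_low.I_inh, lam=lam,
                           fixed=fixed, noise=noise)

    predicted = None
    if low_sf is not None:
        thr = threshold_contrast(low_sf, csf_model.sensitivity(),
                                 csf_model.I_inh, fixed, noise)
        predicted = None if thr is None else 1.0 / thr

    adhoc_csf = adhoc_low = adhoc_high = None
    if with_adhoc:
        adhoc_csf = psychofit.fit_csf_adhoc(csf_trials, lam=lam)
        adhoc_low = psychofit.fit_tilt_adhoc(tilt_trials_low, lam=lam)
        if tilt_trials_high is not None:
            adhoc_high = psychofit.fit_tilt_adhoc(tilt_trials_high, lam=lam)

    return EyeResult(eye_type=eye_type,
                     low_sf=float(low_sf) if low_sf is not None else np.nan,
                     high_sf=float(high_sf) if high_sf is not None else np.nan,
                     tilt_low=tilt_low, tilt_high=tilt_high,
                     csf_model=csf_model, adhoc_csf=adhoc_csf,
                     adhoc_tilt_low=adhoc_low, adhoc_tilt_high=adhoc_high,
                     predicted_low_sf_sensitivity=predicted)


def compare_fits(adhoc_neg_log_ml: float, model_neg_log_ml: float,
                 n_trials_adhoc: int, n_trials_model: int) -> dict:
    """Paired negative log-likelihoods of descriptive vs model fits.

    Both fits must have been computed on the identical trial set; a
    mismatch in trial counts is a caller error.  The difference
    ``model - adhoc`` is positive when the descriptive fit explains the
    data better (it nests more freedom), near zero when the model is as
    good.
    """
    if n_trials_adhoc != n_trials_model:
        raise ValueError("fits were computed on different trial sets")
    return {"adhoc_neg_log_ml": float(adhoc_neg_log_ml),
            "model_neg_log_ml": float(model_neg_log_ml),
            "delta_neg_log_ml": float(model_neg_log_ml - adhoc_neg_log_ml),
            "n_trials": int(n_trials_adhoc)}


def choose_sfs(csf_fit: CSFFit, sf_grid: np.ndarray,
               margin: float = 2.0) -> tuple[float, float | None]:
    """Pick the two tilt-measurement SFs from a fitted CSF.

    The low SF is the grid point nearest the fitted sensitivity peak
    (``a * b``); the high SF is the largest grid point whose fitted
    sensitivity still exceeds ``margin`` (threshold comfortably below
    full contrast), so the tilt stimulus stays visible.  Returns
    ``(low_sf, None)`` when no grid SF above the low SF clears the
    margin -- the subject cannot be measured at a high SF.
    """
    grid = np.asarray(sf_grid, dtype=float)
    low = float(grid[np.argmin(np.abs(np.log2(grid) - np.log2(csf_fit.peak_sf)))])
    sens = np.asarray(csf_fit.sensitivity(grid))
    ok = (sens >= margin) & (grid > low)
    if not ok.any():
        return low, None
    return low, float(grid[np.nonzero(ok)[0][-1]])


def vector_blur(sphere: float, cylinder: float) -> float:
    """Scalar optical blur of an eye from its spherical and cylindrical
    refractive errors: ``sqrt(s^2 + s c + c^2) / 2`` diopters."""
    return float(np.sqrt(sphere ** 2 + sphere * cylinder + cylinder ** 2) / 2.0)


def correlate_parameters(results: pd.DataFrame, x: str, y: str,
                         min_n: int = 5) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties, two-sided p) between two
    fitted-parameter columns across a cohort."""
    sub = results[[x, y]].dropna()
    if len(sub) < min_n:
        raise ValueError(f"need at least {min_n} paired observations, "
                         f"got {len(sub)}")
    rho, p = stats.spearmanr(sub[x], sub[y])
    return float(rho), float(p)
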