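"""Contrast sensitivity predictions from the V1 population model.

A vertical grating of contrast ``c`` and spatial frequency ``f`` drives
every hypercolumn it covers identically, so centre and surround inputs
are equal and the orientation dimension collapses to unity.  Detection
at each SF is carried by the second-layer neuron with the *best*
(smallest) contrast semi-saturation constant at that SF,

    ck_min(f_j) = c_min * ((a b)^a e^{-a}) / (f_j^a e^{-f_j / b}),

a bell-shaped neuronal sensitivity envelope in the SF dimension with
minimum ``c_min`` at ``f_j = a b``.  The first-layer SF tuning width
shrinks with preferred SF, ``sigma_SF(f_j) = exp(-(f_j - 2) / 0.2)``
octaves; feed-forward SF weights are half that width.  Because both
widths scale together, the Gaussian-convolution drive factor in the SF
dimension is scale-free (``2 / sqrt(5)`` at the preferred SF) and is
evaluated in closed form -- at high preferred SFs the widths fall far
below any practical grid spacing, where a discrete sum would be
meaningless.

Two-interval detection probability follows signal detection theory:
``d' = (R_j - R_0) / sqrt(Var(R_j) + Var(R_0))`` with Poisson-like
neuronal variance ``Var(R) = (R + r0) / n_pool``, where ``r0`` is a
spontaneous-discharge floor and ``n_pool`` the number of independently
pooled neurons across the stimulus extent.  Then
``P_th = 2 (Phi(d'/sqrt(2)) - 0.5)`` and
``P(c, f) = gamma + (1 - gamma - lambda) P_th``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .v1_core import (
    DEFAULT_FIXED,
    FixedParams,
    contrast_response,
    firing_rate,
    steady_state_voltage,
)

__all__ = [
    "NeuronalSensitivity",
    "DetectionNoise",
    "CSFPrediction",
    "ck_min_of_sf",
    "sf_width_of_preferred",
    "sf_drive_factor",
    "decision_neuron_rate",
    "detection_probability",
    "threshold_contrast",
    "predict_csf",
    "DEFAULT_CSF_SF_GRID",
]

#: SFs at which the behavioural CSF is sampled (c/d), half-octave spaced.
DEFAULT_CSF_SF_GRID = np.array(
    [0.71, 1.0, 1.41, 2.0, 2.83, 4.0, 5.66, 8.0, 11.31, 16.0, 22.63])

#: Semi-saturation constants above this value are pruned from the grid.
CK_PRUNE_LIMIT = 1000.0

#: d' at the midpoint of the 2AFC psychometric function (P_th = 0.5).
DPRIME_AT_THRESHOLD = float(np.sqrt(2.0) * ndtri(0.75))


@dataclass(frozen=True)
class NeuronalSensitivity:
    """Parameters of the neuronal sensitivity envelope across SFs.

    ``c_min`` is the best (smallest) semi-saturation constant over the
    whole population, attained at the preferred SF ``a * b`` (c/d);
    ``a`` and ``b`` set the shape and scale of the bell.
    """

    c_min: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if min(self.c_min, self.a, self.b) <= 0:
            raise ValueError("c_min, a and b must all be positive")

    @property
    def peak_sf(self) -> float:
        return self.a * self.b


@dataclass(frozen=True)
class DetectionNoise:
    """Noise model of the detection decision variable.

    ``r0`` is the spontaneous-rate floor added to the Poisson-like rate
    variance (so the zero-signal interval has nonzero variance);
    ``n_pool`` is the effective number of independent neurons pooled
    over the grating's spatial extent, which divides the variance of the
    pooled rate.
    """

    r0: float = 1.0
    n_pool: int = 50

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.n_pool < 1:
            raise ValueError("r0 must be positive and n_pool >= 1")


DEFAULT_NOISE = DetectionNoise()


def ck_min_of_sf(f_j: np.ndarray | float,
                 sens: NeuronalSensitivity) -> np.ndarray | float:
    """Best semi-saturation constant at preferred SF ``f_j``.

    Bell-shaped inverse: minimum ``c_min`` exactly at ``f_j = a * b``,
    diverging toward both very low and very high SFs.
    """
    f_j = np.asarray(f_j, dtype=float)
    if np.any(f_j <= 0):
        raise ValueError("preferred SF must be positive")
    a, b = sens.a, sens.b
    # (ab)^a e^{-a} / (f^a e^{-f/b}) computed in log space for stability
    log_ratio = a * (np.log(a * b) - np.log(f_j)) - a + f_j / b
    out = sens.c_min * np.exp(log_ratio)
    return out if out.ndim else float(out)


def sf_width_of_preferred(f_j: np.ndarray | float) -> np.ndarray | float:
    """First-layer SF tuning width (octaves) at preferred SF ``f_j``:
    ``exp(-(f_j - 2) / 0.2)``, strictly decreasing with preferred SF."""
    f_j = np.asarray(f_j, dtype=float)
    if np.any(f_j <= 0):
        raise ValueError("preferred SF must be positive")
    out = np.exp(-(f_j - 2.0) / 0.2)
    return out if out.ndim else float(out)


def sf_drive_factor(f: np.ndarray | float,
                    f_j: np.ndarray | float) -> np.ndarray | float:
    """SF-dimension feed-forward drive onto a neuron preferring ``f_j``
    from a grating at ``f``.

    Closed-form Gaussian convolution of the unit-mass connection weight
    (width ``sigma_SF(f_j) / 2``) with the first-layer log-Gaussian
    tuning (width ``sigma_SF(f_j)``): amplitude ``2 / sqrt(5)`` at the
    preferred SF, falling off with combined width
    ``sqrt(5) / 2 * sigma_SF``.
    """
    f = np.asarray(f, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    s = sf_width_of_preferred(f_j)
    # combined variance (s/2)^2 + s^2 = 1.25 s^2; guard the exponent
    # against underflowing widths far from the preferred SF
    log_dist2 = (np.log2(f) - np.log2(f_j)) ** 2
    with np.errstate(divide="ignore", over="ignore"):
        expo = np.exp(-0.5 * log_dist2 / (1.25 * np.asarray(s) ** 2))
    out = (2.0 / np.sqrt(5.0)) * np.where(log_dist2 == 0.0, 1.0, expo)
    return out if out.ndim else float(out)


def decision_neuron_rate(c: np.ndarray | float, f: np.ndarray | float,
                         sens: NeuronalSensitivity, I_inh: float,
                         fixed: FixedParams = DEFAULT_FIXED,
                         ) -> np.ndarray | float:
    """Second-layer rate of the detection neuron at stimulus SF ``f``.

    The decision neuron prefers the stimulus SF and carries the best
    semi-saturation constant ``ck_min(f)``; the extended grating drives
    the surround hypercolumns with the same contrast, so excitation and
    inhibition share the same contrast weighting.  Preferred
    semi-saturations beyond the pruning limit leave no responsive
    neuron (rate 0).
    """
    if I_inh < 0:
        raise ValueError("I_inh must be nonnegative")
    c = np.asarray(c, dtype=float)
    f = np.asarray(f, dtype=float)
    ck = np.asarray(ck_min_of_sf(f, sens), dtype=float)
    pruned = ck > CK_PRUNE_LIMIT
    ck_safe = np.where(pruned, 1.0, ck)
    amp = fixed.A * contrast_response(c, ck_safe, fixed.n, normalized=True)
    drive = sf_drive_factor(f, f)  # 2/sqrt(5) at the preferred SF
    g_e = fixed.I_c * amp * drive
    g_i = fixed.n_s * I_inh * amp * drive
    rate = firing_rate(steady_state_voltage(g_e, g_i, fixed), fixed)
    out = np.where(pruned, 0.0, rate)
    return out if out.ndim else float(out)


def detection_probability(c: np.ndarray | float, f: np.ndarray | float,
                          sens: NeuronalSensitivity, I_inh: float,
                          gamma: float = 0.5, lam: float = 0.01,
                          fixed: FixedParams = DEFAULT_FIXED,
                          noise: DetectionNoise = DEFAULT_NOISE,
                          ) -> np.ndarray | float:
    """Probability of a correct two-interval detection response.

    ``P = gamma + (1 - gamma - lam) * P_th`` with
    ``P_th = 2 (Phi(d'/sqrt 2) - 0.5)``; bounded by the guess rate at
    zero contrast and by ``1 - lam`` from above, and nondecreasing in
    contrast.
    """
    r_j = np.asarray(decision_neuron_rate(c, f, sens, I_inh, fixed))
    r_0 = 0.0  # no signal -> no first-layer drive -> subthreshold
    var = (r_j + noise.r0) / noise.n_pool + (r_0 + noise.r0) / noise.n_pool
    dprime = (r_j - r_0) / np.sqrt(var)
    p_th = 2.0 * (ndtr(dprime / np.sqrt(2.0)) - 0.5)
    out = gamma + (1.0 - gamma - lam) * p_th
    return out if out.ndim else float(out)


def threshold_contrast(f: float, sens: NeuronalSensitivity, I_inh: float,
                       fixed: FixedParams = DEFAULT_FIXED,
                       noise: DetectionNoise = DEFAULT_NOISE,
                       log10_tol: float = 1e-4,
                       log10_floor: float = -5.0) -> float | None:
    """Contrast at the psychometric midpoint (P_th = 0.5) at SF ``f``.

    Bisection on log10-contrast of the monotone d' criterion.  Returns
    ``None`` when even full contrast stays below the midpoint -- the
    stimulus is not detectable at that SF.
    """
    def excess(log10_c: float) -> float:
        r = decision_neuron_rate(10.0 ** log10_c, f, sens, I_inh, fixed)
        var = (r + 2.0 * noise.r0) / noise.n_pool
        return r / np.sqrt(var) - DPRIME_AT_THRESHOLD

    if excess(0.0) < 0.0:
        return None
    lo, hi = log10_floor, 0.0
    if excess(lo) >= 0.0:
        return 10.0 ** lo
    while hi - lo > log10_tol:
        mid = 0.5 * (lo + hi)
        if excess(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
    return 10.0 ** (0.5 * (lo + hi))


@dataclass(frozen=True)
class CSFPrediction:
    """Model-predicted contrast sensitivity across SFs.

    ``sensitivity`` is 1 / threshold contrast; NaN marks SFs where the
    midpoint is not reachable at full contrast (not measurable).
    """

    sf_grid: np.ndarray
    sensitivity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sf": self.sf_grid, "sensitivity": self.sensitivity})


def predict_csf(sens: NeuronalSensitivity, I_inh: float,
                sf_grid: np.ndarray | None = None,
                fixed: FixedParams = DEFAULT_FIXED,
                noise: DetectionNoise = DEFAULT_NOISE) -> CSFPrediction:
    """Predicted CSF: inverse threshold contrast at each SF of the grid."""
    grid = DEFAULT_CSF_SF_GRID if sf_grid is None else np.asarray(sf_grid, dtype=float)
    sensitivity = np.full(grid.shape, np.nan)
    for i, f in enumerate(grid):
        thr = threshold_contrast(float(f), sens, I_inh, fixed, noise)
        if thr is not None:
            sensitivity[i] = 1.0 / thr
    return CSFPrediction(sf_grid=grid, sensitivity=sensitivity)
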