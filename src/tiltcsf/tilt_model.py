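"""Tilt-repulsion predictions from the V1 population model.

The centre hypercolumn is stimulated with a grating of orientation
``theta_c`` while all surrounding hypercolumns see a grating at
``theta_s``; both at full contrast, so the input amplitude is fixed at
``A`` and only the orientation dimension matters.  The perceived
orientation is read out from the second-layer rates by vector-average
decoding on doubled angles (the only rotation-equivariant average for an
axial variable).  Surround inhibition dents the population profile on
the surround side, which repels the decoded orientation away from the
surround -- the direct tilt illusion.

Two parameters shape the predicted repulsion curve: the orientation
tuning width ``sigma_theta`` (shape and peak position) and the lateral
inhibitory strength ``I_inh`` (mainly amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .v1_core import (
    DEFAULT_FIXED,
    FixedParams,
    PopulationResponse,
    conductances_closed_form_tilt,
    conductances_numeric,
    default_orientation_grid,
    population_rates,
)

__all__ = [
    "TiltParams",
    "population_response_tilt",
    "decode_orientation",
    "predict_bias",
    "predict_bias_curve",
    "tilt_psychometric_model",
    "LOGISTIC_SLOPE",
]

#: Slope factor of the logistic psychometric function; with this choice
#: one spread unit above the midpoint maps to exactly 21/25 = 84%.
LOGISTIC_SLOPE = np.log(21.0 / 4.0)


@dataclass(frozen=True)
class TiltParams:
    """Free parameters of the tilt-repulsion model for one eye and SF.

    ``I_inh`` is the mean inhibitory strength per surrounding
    hypercolumn, ``sigma_theta`` the orientation tuning width in
    degrees, ``threshold_sigma`` the orientation discrimination spread
    (degrees, shared across surround orientations), and ``lapse`` the
    lapse rate of the psychometric function.
    """

    I_inh: float
    sigma_theta: float
    threshold_sigma: float = 3.0
    lapse: float = 0.01

    def __post_init__(self) -> None:
        if self.I_inh < 0:
            raise ValueError("I_inh must be nonnegative")
        if self.sigma_theta <= 0 or self.threshold_sigma <= 0:
            raise ValueError("tuning width and threshold must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")


def population_response_tilt(theta_c: float, theta_s: float,
                             params: TiltParams,
                             fixed: FixedParams = DEFAULT_FIXED,
                             orientations: np.ndarray | None = None,
                             method: str = "closed_form",
                             ) -> PopulationResponse:
    """Second-layer population response to a centre/surround pair.

    ``method`` selects the closed-form conductances (default, fast) or
    the direct grid summation (identical to numerical precision).
    """
    ori = default_orientation_grid() if orientations is None else np.asarray(orientations)
    if method == "closed_form":
        g_e, g_i = conductances_closed_form_tilt(
            ori, theta_c, theta_s, params.sigma_theta, params.I_inh, fixed)
    elif method == "numeric":
        g_e, g_i = conductances_numeric(
            ori, theta_c, theta_s, params.sigma_theta, params.I_inh, fixed)
    else:
        raise ValueError(f"unknown method {method!r}")
    rates = population_rates(g_e, g_i, fixed)
    return PopulationResponse(orientations=ori, rates=rates, g_e=g_e, g_i=g_i)


def decode_orientation(response: PopulationResponse | None = None,
                       rates: np.ndarray | None = None,
                       orientations: np.ndarray | None = None) -> float:
    """Vector-average decoded orientation, in degrees in (-90, 90].

    Orientation is axial, so each neuron contributes a unit vector at
    twice its preferred angle weighted by its rate; the decoded angle is
    half the argument of the resultant.  An all-zero or fully uniform
    rate profile has no resultant and raises ``ValueError``.
    """
    if response is not None:
        rates = response.rates
        orientations = response.orientations
    rates = np.asarray(rates, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    total = rates.sum()
    if total <= 0:
        raise ValueError("cannot decode an all-zero population response")
    doubled = np.deg2rad(2.0 * orientations)
    zx = float(rates @ np.cos(doubled))
    zy = float(rates @ np.sin(doubled))
    if np.hypot(zx, zy) < 1e-12 * total:
        raise ValueError("population response has no orientation resultant")
    angle = 0.5 * np.degrees(np.arctan2(zy, zx))
    # map to the axial convention (-90, 90]
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return angle


def predict_bias(surround_orientation: float, params: TiltParams,
                 fixed: FixedParams = DEFAULT_FIXED,
                 orientations: np.ndarray | None = None) -> float:
    """Predicted perceived-vertical bias for one surround orientation.

    A physically vertical target flanked by a surround at ``+SO`` is
    decoded away from the surround (repulsion), so the orientation that
    *appears* vertical is tilted toward the surround:
    ``bias = -decode(theta_c = 0, theta_s = SO)``.  Positive bias shares
    the sign of the surround for the direct effect.
    """
    if params.I_inh == 0.0:
        return 0.0
    resp = population_response_tilt(0.0, surround_orientation, params,
                                    fixed, orientations)
    return -decode_orientation(resp)


def predict_bias_curve(params: TiltParams,
                       surround_orientations: np.ndarray,
                       fixed: FixedParams = DEFAULT_FIXED,
                       orientations: np.ndarray | None = None) -> pd.DataFrame:
    """Predicted bias at each surround orientation.

    Returns a DataFrame with columns ``surround_orientation`` and
    ``bias`` (degrees).  Antisymmetric in the surround orientation and
    zero at 0 and 90 deg by the reflection symmetry of the network.
    """
    sos = np.asarray(surround_orientations, dtype=float)
    biases = [predict_bias(so, params, fixed, orientations) for so in sos]
    return pd.DataFrame({"surround_orientation": sos, "bias": biases})


def tilt_psychometric_model(theta: np.ndarray | float, surround_orientation: float,
                            params: TiltParams,
                            fixed: FixedParams = DEFAULT_FIXED,
                            bias: float | None = None) -> np.ndarray | float:
    """Model-based probability of a clockwise response to target ``theta``.

    Logistic psychometric function whose midpoint is the model-predicted
    perceived vertical and whose spread uses the same
    ``log(21/4)`` slope convention as the descriptive fits, so negative
    log-likelihoods are directly comparable.  ``bias`` short-circuits
    the model prediction when the caller has already computed it.
    """
    if bias is None:
        bias = predict_bias(surround_orientation, params, fixed)
    theta = np.asarray(theta, dtype=float)
    lam = params.lapse
    core = 1.0 / (1.0 + np.exp(-LOGISTIC_SLOPE * (theta - bias)
                               / params.threshold_sigma))
    out = lam + (1.0 - 2.0 * lam) * core
    return out if out.ndim else float(out)
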