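"""Two-layer conductance-based V1 population model: tuning and conductances.

The model describes a local orientation hypercolumn of primary visual
cortex.  A first layer of linear-filter ("simple") cells is tuned to
orientation (wrapped Gaussian), spatial frequency (log-Gaussian) and
contrast (hyperbolic ratio).  A second layer receives feed-forward
excitation from the first layer of the same hypercolumn and divisive,
conductance-based inhibition pooled from surrounding hypercolumns.  The
steady-state membrane voltage of a second-layer cell is

    v = (v_e * g_e + v_i * g_i) / (1 + g_e + g_i)

and its firing rate is the rectified linear transduction
``R = m * max(0, v - T)``.

This module holds the feature grids, the fixed network constants, the
tuning primitives, and the excitatory/inhibitory conductance
computations (direct grid summation and, for the orientation-only tilt
configuration, the equivalent Gaussian-convolution closed form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ORIENTATION_PERIOD",
    "FixedParams",
    "DEFAULT_FIXED",
    "PopulationGrid",
    "ConnectionWidths",
    "PopulationResponse",
    "wrapped_gaussian_sum",
    "orientation_tuning",
    "sf_tuning",
    "contrast_response",
    "half_amplitude_constant",
    "first_layer_response",
    "steady_state_voltage",
    "membrane_derivative",
    "firing_rate",
    "population_rates",
    "conductances_numeric",
    "conductances_closed_form_tilt",
]

#: Orientation is an axial variable: theta and theta + 180 deg are the
#: same stimulus.
ORIENTATION_PERIOD = 180.0

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class FixedParams:
    """Fixed constants of the normalized conductance-based network.

    Attributes
    ----------
    n_s
        Effective number of surrounding hypercolumns feeding inhibition
        onto the centre hypercolumn.
    n
        Exponent of the hyperbolic-ratio contrast response.
    A
        Maximum firing amplitude of first-layer cells.
    m
        Slope of the voltage-to-rate transduction.
    T
        Voltage threshold of firing.
    I_c
        Excitatory (within-hypercolumn) input strength.
    v_e, v_i
        Excitatory and inhibitory reversal potentials (dimensionless,
        ``v_i < 0 < v_e``).
    sigma_sf_firstlayer
        Default first-layer spatial-frequency tuning width in octaves
        (the CSF configuration replaces it with a preferred-SF-dependent
        width).
    tau
        Membrane time constant.  The steady state does not depend on it;
        it is kept so the fixed point can be checked against the
        forward-integrated membrane dynamics.
    """

    n_s: int = 6
    n: float = 2.0
    A: float = 2.0
    m: float = 1.0
    T: float = 1.0
    I_c: float = 1.0
    v_e: float = 14.0 / 3.0
    v_i: float = -2.0 / 3.0
    sigma_sf_firstlayer: float = 1.0
    tau: float = 10.0

    def __post_init__(self) -> None:
        if not (self.v_i < 0.0 < self.v_e):
            raise ValueError("reversal potentials must satisfy v_i < 0 < v_e")
        if self.T <= 0.0:
            raise ValueError("firing threshold T must be positive")
        if min(self.n_s, self.n, self.A, self.m, self.I_c) < 0:
            raise ValueError("network strengths must be nonnegative")


DEFAULT_FIXED = FixedParams()


def default_orientation_grid(spacing: float = 2.0) -> np.ndarray:
    """Preferred orientations covering one 180 deg period, in degrees
    relative to vertical: ``[-90, -90 + spacing, ..., 90 - spacing]``."""
    return np.arange(-90.0, 90.0, spacing)


def default_sf_grid() -> np.ndarray:
    """Preferred spatial frequencies, quarter-octave spaced, 0.5-64 c/d."""
    return 2.0 ** np.arange(-1.0, 6.0 + 1e-9, 0.25)


def default_ck_grid() -> np.ndarray:
    """Log-spaced semi-saturation constants; values above 1000 are pruned
    by :class:`PopulationGrid`."""
    return np.logspace(-3.0, 3.0, 31)


@dataclass(frozen=True)
class PopulationGrid:
    """Discretised feature space on which population responses live.

    ``orientations`` are degrees relative to vertical (period 180),
    ``sfs`` are cycles/degree on a log2-equispaced ladder, and
    ``contrast_semisaturations`` are the dimensionless semi-saturation
    constants of the contrast dimension.  Neurons with semi-saturation
    above 1000 respond to no physical contrast and are pruned.
    """

    orientations: np.ndarray = field(default_factory=default_orientation_grid)
    sfs: np.ndarray = field(default_factory=default_sf_grid)
    contrast_semisaturations: np.ndarray = field(default_factory=default_ck_grid)

    def __post_init__(self) -> None:
        ori = np.asarray(self.orientations, dtype=float)
        if ori.ndim != 1 or ori.size < 2:
            raise ValueError("orientation grid must be a 1-d array")
        spacing = np.diff(ori)
        if not np.allclose(spacing, spacing[0]):
            raise ValueError("orientation grid must be equispaced")
        if not np.isclose(spacing[0] * ori.size, ORIENTATION_PERIOD):
            raise ValueError("orientation grid must cover one full 180 deg period")
        if np.unique(np.mod(ori, ORIENTATION_PERIOD)).size != ori.size:
            raise ValueError("orientation grid contains duplicate axial angles")

        sfs = np.asarray(self.sfs, dtype=float)
        if np.any(sfs <= 0) or np.any(np.diff(sfs) <= 0):
            raise ValueError("SF grid must be positive and strictly increasing")
        log_steps = np.diff(np.log2(sfs))
        if not np.allclose(log_steps, log_steps[0]):
            raise ValueError("SF grid must be log2-equispaced")

        ck = np.asarray(self.contrast_semisaturations, dtype=float)
        if np.any(ck <= 0):
            raise ValueError("semi-saturation constants must be positive")
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "sfs", sfs)
        # pruning rule: neurons with c_k > 1000 never reach half their
        # asymptote within the physical contrast range
        object.__setattr__(self, "contrast_semisaturations", ck[ck <= 1000.0])

    @property
    def orientation_spacing(self) -> float:
        return float(self.orientations[1] - self.orientations[0])


@dataclass(frozen=True)
class ConnectionWidths:
    """Feed-forward connection tuning widths.

    Centre and surround weight widths are entangled with the first-layer
    tuning widths and fixed at half of them; this rule is applied by
    :meth:`from_tuning` and asserted here.
    """

    sigma_theta_cs: float
    sigma_sf_cs: float

    @classmethod
    def from_tuning(cls, sigma_theta: float, sigma_sf: float) -> "ConnectionWidths":
        return cls(sigma_theta_cs=sigma_theta / 2.0, sigma_sf_cs=sigma_sf / 2.0)

    def __post_init__(self) -> None:
        if self.sigma_theta_cs <= 0 or self.sigma_sf_cs <= 0:
            raise ValueError("connection widths must be positive")


@dataclass(frozen=True)
class PopulationResponse:
    """Second-layer rates and conductances over an orientation grid."""

    orientations: np.ndarray
    rates: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray


# ---------------------------------------------------------------------------
# tuning primitives
# ---------------------------------------------------------------------------

def wrapped_gaussian_sum(delta: np.ndarray | float, sigma: float,
                         n_wraps: int = 2) -> np.ndarray | float:
    """Unnormalised wrapped Gaussian, summed over ``2 * n_wraps + 1``
    period images.  Truncation error is below 1e-12 for sigma <= 40 deg."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = ORIENTATION_PERIOD / 2.0
    # centre the offset into (-90, 90] first so periodicity is exact
    delta = np.mod(np.asarray(delta, dtype=float) + half,
                   ORIENTATION_PERIOD) - half
    offsets = np.arange(-n_wraps, n_wraps + 1) * ORIENTATION_PERIOD
    d = delta[..., np.newaxis] + offsets
    out = np.exp(-0.5 * (d / sigma) ** 2).sum(axis=-1)
    return out if out.ndim else float(out)


def orientation_tuning(theta: np.ndarray | float, theta_i: np.ndarray | float,
                       sigma_theta: float) -> np.ndarray | float:
    """Wrapped-Gaussian orientation tuning, normalised to 1 at the
    preferred orientation and periodic with period 180 deg."""
    peak = wrapped_gaussian_sum(0.0, sigma_theta)
    return wrapped_gaussian_sum(np.asarray(theta) - np.asarray(theta_i),
                                sigma_theta) / peak


def sf_tuning(f: np.ndarray | float, f_j: np.ndarray | float,
              sigma_sf: float) -> np.ndarray | float:
    """Log-Gaussian spatial-frequency tuning (width in octaves)."""
    if sigma_sf <= 0:
        raise ValueError("sigma_sf must be positive")
    f = np.asarray(f, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    if np.any(f <= 0) or np.any(f_j <= 0):
        raise ValueError("spatial frequencies must be positive")
    out = np.exp(-0.5 * ((np.log2(f) - np.log2(f_j)) / sigma_sf) ** 2)
    return out if out.ndim else float(out)


def contrast_response(c: np.ndarray | float, c_k: np.ndarray | float,
                      n: float = DEFAULT_FIXED.n,
                      normalized: bool = True) -> np.ndarray | float:
    """Hyperbolic-ratio contrast response ``c^n / (c_k^n + c^n)``.

    With ``normalized=True`` the amplitude is multiplied by
    ``(1 + c_k^n)`` so that the response is exactly 1 at full contrast
    (c = 1) for every semi-saturation constant.
    """
    c = np.asarray(c, dtype=float)
    c_k = np.asarray(c_k, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("contrast must lie in [0, 1]")
    if np.any(c_k <= 0):
        raise ValueError("semi-saturation constant must be positive")
    cn = c ** n
    out = cn / (c_k ** n + cn)
    if normalized:
        out = out * (1.0 + c_k ** n)
    return out if out.ndim else float(out)


def half_amplitude_constant(c_k: np.ndarray | float,
                            n: float = DEFAULT_FIXED.n) -> np.ndarray | float:
    """Contrast at which the normalised hyperbolic ratio reaches half of
    its value at full contrast: ``c_1/2^n = c_k^n / (1 + 2 c_k^n)``.

    For low exponents or large ``c_k`` the semi-saturation constant no
    longer marks the half-amplitude point, hence this correction.
    """
    c_k = np.asarray(c_k, dtype=float)
    if np.any(c_k <= 0) or n <= 0:
        raise ValueError("c_k and n must be positive")
    ckn = c_k ** n
    out = (ckn / (1.0 + 2.0 * ckn)) ** (1.0 / n)
    return out if out.ndim else float(out)


def first_layer_response(theta: float, f: float, c: float,
                         theta_i: float, f_j: float, c_k: float,
                         params: FixedParams = DEFAULT_FIXED,
                         sigma_theta: float = 20.0,
                         sigma_sf: float | None = None) -> float:
    """Separable first-layer rate ``A * T(theta) * F(f) * C(c)``."""
    s_sf = params.sigma_sf_firstlayer if sigma_sf is None else sigma_sf
    return (params.A
            * orientation_tuning(theta, theta_i, sigma_theta)
            * sf_tuning(f, f_j, s_sf)
            * contrast_response(c, c_k, params.n, normalized=True))


# ---------------------------------------------------------------------------
# second layer
# ---------------------------------------------------------------------------

def steady_state_voltage(g_e: np.ndarray | float, g_i: np.ndarray | float,
                         params: FixedParams = DEFAULT_FIXED) -> np.ndarray | float:
    """Fixed point of the conductance-based membrane equation.

    The voltage lies in ``[v_i, v_e]`` for any nonnegative conductances.
    """
    g_e = np.asarray(g_e, dtype=float)
    g_i = np.asarray(g_i, dtype=float)
    if np.any(g_e < 0) or np.any(g_i < 0):
        raise ValueError("conductances must be nonnegative")
    out = (params.v_e * g_e + params.v_i * g_i) / (1.0 + g_e + g_i)
    return out if out.ndim else float(out)


def membrane_derivative(v: np.ndarray | float, g_e: np.ndarray | float,
                        g_i: np.ndarray | float,
                        params: FixedParams = DEFAULT_FIXED) -> np.ndarray | float:
    """dv/dt of the membrane equation (for dynamical consistency checks)."""
    return (-v + (params.v_e - v) * g_e + (params.v_i - v) * g_i) / params.tau


def firing_rate(v: np.ndarray | float,
                params: FixedParams = DEFAULT_FIXED) -> np.ndarray | float:
    """Rectified-linear transduction ``m * max(0, v - T)``."""
    out = params.m * np.maximum(0.0, np.asarray(v, dtype=float) - params.T)
    return out if out.ndim else float(out)


def population_rates(g_e: np.ndarray, g_i: np.ndarray,
                     params: FixedParams = DEFAULT_FIXED) -> np.ndarray:
    """Second-layer rates from conductances (steady state + rectification)."""
    return firing_rate(steady_state_voltage(g_e, g_i, params), params)


# ---------------------------------------------------------------------------
# conductances for the tilt (orientation-only) configuration
# ---------------------------------------------------------------------------
#
# In the tilt configuration the centre and surround gratings share the
# same spatial frequency and (full) contrast, so the SF and contrast
# dimensions collapse into the input amplitude A_{c,s} and only the
# orientation dimension is kept.  Feed-forward weights are iso-oriented
# wrapped Gaussians of width sigma_theta / 2, normalised to unit mass
# over the orientation circle.

def _weight_matrix(orientations: np.ndarray, sigma_cs: float) -> np.ndarray:
    spacing = float(orientations[1] - orientations[0])
    delta = orientations[:, np.newaxis] - orientations[np.newaxis, :]
    return wrapped_gaussian_sum(delta, sigma_cs) * spacing / (_SQRT2PI * sigma_cs)


def conductances_numeric(orientations: np.ndarray, theta_c: float,
                         theta_s: float, sigma_theta: float, I_inh: float,
                         params: FixedParams = DEFAULT_FIXED,
                         centre_amplitude: float | None = None,
                         surround_amplitude: float | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Excitatory/inhibitory conductances by direct summation of the
    first-layer drive over the orientation grid.

    A uniform surround is assumed: every surrounding hypercolumn sees the
    same grating, so the total inhibitory strength is ``n_s * I_inh``.
    ``centre_amplitude``/``surround_amplitude`` default to the
    contrast-weighted input amplitude ``A`` (full contrast).
    """
    if sigma_theta <= 0:
        raise ValueError("sigma_theta must be positive")
    if I_inh < 0:
        raise ValueError("I_inh must be nonnegative")
    amp_c = params.A if centre_amplitude is None else centre_amplitude
    amp_s = params.A if surround_amplitude is None else surround_amplitude
    W = _weight_matrix(orientations, sigma_theta / 2.0)
    r_c = amp_c * orientation_tuning(orientations, theta_c, sigma_theta)
    r_s = amp_s * orientation_tuning(orientations, theta_s, sigma_theta)
    g_e = params.I_c * (W @ r_c)
    g_i = params.n_s * I_inh * (W @ r_s)
    return g_e, g_i


def conductances_closed_form_tilt(orientations: np.ndarray, theta_c: float,
                                  theta_s: float, sigma_theta: float,
                                  I_inh: float,
                                  params: FixedParams = DEFAULT_FIXED,
                                  centre_amplitude: float | None = None,
                                  surround_amplitude: float | None = None,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form tilt-configuration conductances.

    The convolution of the unit-mass connection Gaussian (width
    ``sigma_theta / 2``) with the first-layer tuning Gaussian (width
    ``sigma_theta``) is again a wrapped Gaussian of combined width
    ``sqrt((sigma_theta/2)^2 + sigma_theta^2)``, scaled by
    ``sigma_theta / sigma_combined`` -- i.e. the classic
    ``Sigma_theta / sigma_theta^{c,s}`` prefactor.  Agrees with
    :func:`conductances_numeric` to high relative accuracy because the
    grid sum of a smooth periodic function is spectrally exact.
    """
    if sigma_theta <= 0:
        raise ValueError("sigma_theta must be positive")
    if I_inh < 0:
        raise ValueError("I_inh must be nonnegative")
    amp_c = params.A if centre_amplitude is None else centre_amplitude
    amp_s = params.A if surround_amplitude is None else surround_amplitude
    sigma_cs = sigma_theta / 2.0
    sigma_comb = np.hypot(sigma_cs, sigma_theta)
    # peak of the wrapped first-layer tuning; keeps the tuning normalised
    peak = wrapped_gaussian_sum(0.0, sigma_theta)
    prefactor = (sigma_theta / sigma_comb) / peak
    g_e = params.I_c * amp_c * prefactor * wrapped_gaussian_sum(
        orientations - theta_c, sigma_comb)
    g_i = params.n_s * I_inh * amp_s * prefactor * wrapped_gaussian_sum(
        orientations - theta_s, sigma_comb)
    return np.asarray(g_e), np.asarray(g_i)
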