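"""Simulated observers and full psychophysical sessions.

No human data ship with this package, so every fitting stage is
exercised against simulated subjects with known ground truth.  An
observer is a generative description of one eye: either *descriptive*
(the same logistic forms the fitting module estimates) or *model-based*
(bias and detectability produced by the V1 population model itself).
Sessions reproduce the measurement protocol exactly -- 11-SF detection
staircases with 15 trials each (165 trials), and tilt blocks of seven
surround orientations with two interleaved weighted staircases of 30
trials each (420 trials) -- including the three-key response behaviour
and the random scoring of third-key presses that drives the staircases.

Cohorts emulate the study's group structure: amblyopic eyes (AE) are
drawn with broader orientation tuning than fellow (NAE) and control
(NTE) eyes, amblyopes' eyes span a wide range of lateral inhibition
(which mechanically lowers their generated contrast sensitivity), and
controls' sensitivity differences are driven by the neuronal
sensitivity floor ``c_min`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .csf_model import (
    DEFAULT_CSF_SF_GRID,
    DEFAULT_NOISE,
    DetectionNoise,
    NeuronalSensitivity,
    detection_probability,
    predict_csf,
)
from .psychofit import eval_csf_psychometric, eval_tilt_psychometric
from .staircase import BASE_LOG_STEP, StaircaseConfig, WeightedUpDown
from .tilt_model import TiltParams, predict_bias
from .v1_core import DEFAULT_FIXED, FixedParams

__all__ = [
    "CSF_START_CONTRASTS",
    "CSF_STEP_FAMILIES",
    "TILT_SURROUND_ORIENTATIONS",
    "SuppressionField",
    "AdhocCSFObserver",
    "ModelCSFObserver",
    "AdhocTiltObserver",
    "ModelTiltObserver",
    "ObserverSpec",
    "simulate_csf_session",
    "simulate_tilt_session",
    "make_cohort",
    "simulate_subject",
]

#: Starting contrasts of the 11 detection staircases, alternating high
#: and low so the session brackets the threshold from both sides.
CSF_START_CONTRASTS = np.array(
    [0.5, 0.005, 0.5, 0.005, 0.5, 0.005, 0.5, 0.005, 0.7, 0.05, 0.8])

#: (down, up) step multipliers of the base 10%-contrast log-unit, per SF.
#: Odd-indexed SFs of the ladder use the shallower 1.5/7 family.
CSF_STEP_FAMILIES = [(4.5, 8.0) if i % 2 == 0 else (1.5, 7.0)
                     for i in range(len(DEFAULT_CSF_SF_GRID))]

TILT_SURROUND_ORIENTATIONS = (0.0, 15.0, -15.0, 30.0, -30.0, 75.0, -75.0)

_MIN_LOG10_CONTRAST = np.log10(1e-4)


@dataclass(frozen=True)
class SuppressionField:
    """Probability that the centre target is not seen, as a function of
    surround orientation and SF.

    Iso-oriented surrounds suppress most, and suppression grows with
    SF: ``p = amplitude * exp(-SO^2 / (2 so_width^2)) *
    logistic((log2 f - log2 f_half) / f_slope)``.
    """

    amplitude: float = 0.5
    so_width: float = 30.0
    f_half: float = 6.0
    f_slope: float = 0.7

    def __call__(self, surround_orientation: float, sf: float) -> float:
        if self.amplitude == 0.0:
            return 0.0
        ori = np.exp(-0.5 * (surround_orientation / self.so_width) ** 2)
        sf_term = 1.0 / (1.0 + np.exp(-(np.log2(sf) - np.log2(self.f_half))
                                      / self.f_slope))
        return float(np.clip(self.amplitude * ori * sf_term, 0.0, 0.95))


NO_SUPPRESSION = SuppressionField(amplitude=0.0)


# ---------------------------------------------------------------------------
# observers
# ---------------------------------------------------------------------------

class _CSFObserverBase:
    """Shared response machinery for detection observers.

    A trial unfolds as: lapse (probability ``lapse``) -> random key;
    else the stimulus is seen with probability ``p_seen(c, f)`` ->
    correct key; else the observer is guessing and presses the
    undecided key with probability ``key3_rate``, otherwise picks an
    interval at random.
    """

    lapse: float
    key3_rate: float

    def p_seen(self, c: float, f: float) -> float:  # pragma: no cover
        raise NotImplementedError

    def respond(self, c: float, f: float, rng: np.random.Generator) -> str:
        if rng.random() < self.lapse:
            return "correct" if rng.random() < 0.5 else "incorrect"
        if rng.random() < self.p_seen(c, f):
            return "correct"
        if rng.random() < self.key3_rate:
            return "undecided"
        return "correct" if rng.random() < 0.5 else "incorrect"


@dataclass
class AdhocCSFObserver(_CSFObserverBase):
    """Detection observer governed by the descriptive logistic surface
    with sensitivity shape (M, a, b) and spread sigma."""

    M: float
    a: float
    b: float
    sigma: float
    lapse: float = 0.01
    key3_rate: float = 0.0

    def p_seen(self, c: float, f: float) -> float:
        # the "seen" probability is the logistic core (gamma = 0,
        # lam = 0); guess and lapse behaviour are layered on top
        return float(eval_csf_psychometric(c, f, self.M, self.a, self.b,
                                           self.sigma, gamma=0.0, lam=0.0))


@dataclass
class ModelCSFObserver(_CSFObserverBase):
    """Detection observer whose detectability comes from the V1 model's
    signal-detection stage."""

    sens: NeuronalSensitivity
    I_inh: float
    lapse: float = 0.01
    key3_rate: float = 0.0
    fixed: FixedParams = DEFAULT_FIXED
    noise: DetectionNoise = DEFAULT_NOISE

    def p_seen(self, c: float, f: float) -> float:
        return float(detection_probability(c, f, self.sens, self.I_inh,
                                           gamma=0.0, lam=0.0,
                                           fixed=self.fixed, noise=self.noise))


class _TiltObserverBase:
    """Shared response machinery for tilt observers."""

    lapse: float
    suppression: SuppressionField

    def bias(self, surround_orientation: float) -> float:  # pragma: no cover
        raise NotImplementedError

    def threshold(self, surround_orientation: float) -> float:  # pragma: no cover
        raise NotImplementedError

    def respond(self, theta: float, surround_orientation: float, sf: float,
                rng: np.random.Generator) -> str:
        if rng.random() < self.suppression(surround_orientation, sf):
            return "not_seen"
        p_cw = eval_tilt_psychometric(theta, self.bias(surround_orientation),
                                      self.threshold(surround_orientation),
                                      self.lapse)
        return "cw" if rng.random() < p_cw else "ccw"


@dataclass
class AdhocTiltObserver(_TiltObserverBase):
    """Tilt observer with an explicit bias per surround orientation and
    threshold per |SO|."""

    biases: dict
    thresholds: dict
    lapse: float = 0.01
    suppression: SuppressionField = NO_SUPPRESSION

    def bias(self, surround_orientation: float) -> float:
        return float(self.biases[float(surround_orientation)])

    def threshold(self, surround_orientation: float) -> float:
        return float(self.thresholds[abs(float(surround_orientation))])


@dataclass
class ModelTiltObserver(_TiltObserverBase):
    """Tilt observer whose biases are the V1 model's predictions."""

    params: TiltParams
    lapse: float = 0.01
    suppression: SuppressionField = NO_SUPPRESSION
    fixed: FixedParams = DEFAULT_FIXED
    _bias_cache: dict = field(default_factory=dict, repr=False)

    def bias(self, surround_orientation: float) -> float:
        so = float(surround_orientation)
        if so not in self._bias_cache:
            self._bias_cache[so] = predict_bias(so, self.params, self.fixed)
        return self._bias_cache[so]

    def threshold(self, surround_orientation: float) -> float:
        return self.params.threshold_sigma


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def simulate_csf_session(observer: _CSFObserverBase,
                         seed: int | np.random.Generator,
                         sf_grid: np.ndarray = DEFAULT_CSF_SF_GRID,
                         n_per_sf: int = 15,
                         start_contrasts: np.ndarray = CSF_START_CONTRASTS,
                         step_families=None) -> pd.DataFrame:
    """One contrast-detection session: independent weighted staircases
    per SF, interleaved round-robin, 15 trials each (165 in total).

    Correct responses lower the contrast and incorrect ones raise it,
    in log10-contrast steps expressed as multiples of the base
    10%-contrast log-unit; the down step is tripled for the first four
    trials of each staircase.  Undecided presses are scored at random
    for the staircase update but recorded as undecided.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    families = CSF_STEP_FAMILIES if step_families is None else step_families
    stairs = []
    for i, sf in enumerate(sf_grid):
        down_mult, up_mult = families[i]
        cfg = StaircaseConfig(
            up_step=up_mult * BASE_LOG_STEP,
            down_step=down_mult * BASE_LOG_STEP,
            start_level=float(np.log10(start_contrasts[i])),
            n_trials=n_per_sf, down_boost=3.0, boost_trials=4,
            min_level=_MIN_LOG10_CONTRAST, max_level=0.0)
        stairs.append(WeightedUpDown(cfg))

    rows = []
    for trial in range(n_per_sf):
        for i, sf in enumerate(sf_grid):
            c = 10.0 ** stairs[i].level
            response = observer.respond(c, float(sf), rng)
            if response == "undecided":
                scored_correct = bool(rng.random() < 0.5)
            else:
                scored_correct = response == "correct"
            stairs[i].update(tracked_response=scored_correct)
            rows.append({"measure": "csf", "sf": float(sf),
                         "contrast": c, "response": response,
                         "scored_correct": scored_correct})
    return pd.DataFrame(rows)


def simulate_tilt_session(observer: _TiltObserverBase, sf: float,
                          seed: int | np.random.Generator,
                          surround_orientations=TILT_SURROUND_ORIENTATIONS,
                          n_per_staircase: int = 30,
                          start_offset: float = 10.0) -> pd.DataFrame:
    """One tilt block at a single SF: per surround orientation, two
    strictly alternating weighted staircases (steps Up/Down 2/5 and
    5/2 deg, tracking ~29% and ~71% clockwise responses), 30 trials
    each -- 420 trials for the standard seven surrounds.

    Each staircase starts ``start_offset`` degrees on the far side of
    its convergence point.  Not-seen responses are stepped on a random
    clockwise/counter-clockwise draw but recorded as not seen.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for so in surround_orientations:
        bias = observer.bias(so)
        # track A converges below the bias (29% CW): start above; B mirrors
        track_a = WeightedUpDown(StaircaseConfig(
            up_step=2.0, down_step=5.0, start_level=bias + start_offset,
            n_trials=n_per_staircase))
        track_b = WeightedUpDown(StaircaseConfig(
            up_step=5.0, down_step=2.0, start_level=bias - start_offset,
            n_trials=n_per_staircase))
        for _ in range(n_per_staircase):
            for track in (track_a, track_b):
                theta = track.level
                response = observer.respond(theta, so, sf, rng)
                if response == "not_seen":
                    stepped_cw = bool(rng.random() < 0.5)
                else:
                    stepped_cw = response == "cw"
                track.update(tracked_response=stepped_cw)
                rows.append({"measure": "tilt", "sf": float(sf),
                             "surround_orientation": float(so),
                             "target_orientation": theta,
                             "response": response})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverSpec:
    """Ground-truth generative description of one simulated eye."""

    subject: int
    eye_type: str              # AE, NAE or NTE
    I_inh: float
    sigma_theta: float
    threshold_sigma: float
    c_min: float
    a: float
    b: float
    key3_rate: float
    suppression_amplitude: float
    seed: int

    def tilt_params(self) -> TiltParams:
        return TiltParams(I_inh=self.I_inh, sigma_theta=self.sigma_theta,
                          threshold_sigma=self.threshold_sigma)

    def sensitivity(self) -> NeuronalSensitivity:
        return NeuronalSensitivity(c_min=self.c_min, a=self.a, b=self.b)

    def to_dict(self) -> dict:
        return asdict(self)


#: Generative regimes per eye type.  AE: broad orientation tuning and a
#: wide range of lateral inhibition; NAE: normal tuning but shares the
#: amblyopic system's inhibition range; NTE: normal tuning, mild
#: inhibition, sensitivity differences carried by c_min instead.
COHORT_REGIMES = {
    "AE": {"sigma_theta": (24.0, 4.0), "I_inh": (0.03, 0.20),
           "c_min": (0.018, 0.024), "threshold": (3.0, 7.0)},
    "NAE": {"sigma_theta": (14.0, 2.5), "I_inh": (0.03, 0.20),
            "c_min": (0.018, 0.024), "threshold": (1.5, 4.0)},
    "NTE": {"sigma_theta": (13.0, 2.5), "I_inh": (0.04, 0.10),
            "c_min": (0.012, 0.05), "threshold": (1.0, 3.0)},
}


def make_cohort(n_per_group: int = 4, seed: int = 0,
                regimes: dict | None = None) -> list[ObserverSpec]:
    """Draw a reproducible cohort of simulated eyes.

    Within the amblyopic groups the generated low-SF sensitivity is
    mechanically anti-correlated with ``I_inh`` (stronger inhibition
    lowers the model CSF), and AE orientation tuning widths exceed
    NTE/NAE widths by construction.
    """
    regimes = COHORT_REGIMES if regimes is None else regimes
    rng = np.random.default_rng(seed)
    specs = []
    sid = 0
    for eye_type, reg in regimes.items():
        for _ in range(n_per_group):
            mu, sd = reg["sigma_theta"]
            sigma_theta = float(np.clip(rng.normal(mu, sd), 6.0, 40.0))
            lo, hi = reg["I_inh"]
            I_inh = float(rng.uniform(lo, hi))
            lo, hi = reg["c_min"]
            c_min = float(rng.uniform(lo, hi))
            lo, hi = reg["threshold"]
            threshold = float(rng.uniform(lo, hi))
            specs.append(ObserverSpec(
                subject=sid, eye_type=eye_type, I_inh=I_inh,
                sigma_theta=sigma_theta, threshold_sigma=threshold,
                c_min=c_min, a=1.0, b=2.5,
                key3_rate=float(rng.uniform(0.4, 0.9)),
                suppression_amplitude=float(rng.uniform(0.3, 0.6)),
                seed=int(rng.integers(0, 2**31 - 1))))
            sid += 1
    return specs


def simulate_subject(spec: ObserverSpec,
                     low_sf: float = 2.83, high_sf: float = 8.0,
                     fixed: FixedParams = DEFAULT_FIXED,
                     noise: DetectionNoise = DEFAULT_NOISE) -> dict:
    """Generate the full measurement set of one eye: a CSF session and
    tilt sessions at a low and a high SF."""
    rng = np.random.default_rng(spec.seed)
    csf_obs = ModelCSFObserver(sens=spec.sensitivity(), I_inh=spec.I_inh,
                               key3_rate=spec.key3_rate, fixed=fixed,
                               noise=noise)
    suppression = SuppressionField(amplitude=spec.suppression_amplitude)
    tilt_obs = ModelTiltObserver(params=spec.tilt_params(),
                                 suppression=suppression, fixed=fixed)
    csf = simulate_csf_session(csf_obs, rng)
    tilt_low = simulate_tilt_session(tilt_obs, low_sf, rng)
    tilt_high = simulate_tilt_session(tilt_obs, high_sf, rng)
    truth_csf = predict_csf(spec.sensitivity(), spec.I_inh, fixed=fixed,
                            noise=noise)
    return {"spec": spec, "csf": csf, "tilt_low": tilt_low,
            "tilt_high": tilt_high, "low_sf": low_sf, "high_sf": high_sf,
            "true_csf": truth_csf}
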