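"""Tests of the staircase engine and simulated sessions."""

import numpy as np
import pandas as pd
import pytest

from tiltcsf.observer_sim import (
    CSF_START_CONTRASTS,
    AdhocCSFObserver,
    AdhocTiltObserver,
    ModelTiltObserver,
    SuppressionField,
    make_cohort,
    simulate_csf_session,
    simulate_subject,
    simulate_tilt_session,
)
from tiltcsf.psychofit import eval_tilt_psychometric
from tiltcsf.staircase import BASE_LOG_STEP, StaircaseConfig, WeightedUpDown
from tiltcsf.tilt_model import TiltParams

ZERO_BIASES = {so: 0.0 for so in (0.0, 15.0, -15.0, 30.0, -30.0, 75.0, -75.0)}
FLAT_THRESH = {0.0: 3.0, 15.0: 3.0, 30.0: 3.0, 75.0: 3.0}


class TestStaircaseEngine:
    def test_convergence_probability_formula(self):
        cfg = StaircaseConfig(up_step=2.0, down_step=5.0, start_level=10.0,
                              n_trials=10)
        assert cfg.convergence_probability == pytest.approx(2.0 / 7.0)

    @pytest.mark.parametrize("up,down", [(2.0, 5.0), (5.0, 2.0),
                                         (4.5, 8.0), (1.5, 7.0)])
    def test_tracks_the_weighted_updown_equilibrium(self, up, down, rng):
        """Tracked-response probability at the converged level matches
        up/(up+down) within Monte-Carlo error.

        The probe observer's spread is wide relative to the steps so the
        psychometric function is locally linear over the stationary
        level fluctuations (otherwise the probability at the mean level
        is Jensen-biased below the tracked point)."""
        def p_tracked(level):  # logistic observer, midpoint 0, spread 25
            return eval_tilt_psychometric(level, 0.0, 25.0, lam=0.0)

        stair = WeightedUpDown(StaircaseConfig(
            up_step=up, down_step=down, start_level=8.0, n_trials=10_000))
        while not stair.done:
            stair.update(rng.random() < p_tracked(stair.level))
        converged = np.mean(stair.history[5000:])
        assert p_tracked(converged) == pytest.approx(up / (up + down),
                                                     abs=0.02)

    def test_down_boost_applies_only_to_first_trials(self):
        cfg = StaircaseConfig(up_step=1.0, down_step=1.0, start_level=0.0,
                              n_trials=10, down_boost=3.0, boost_trials=4)
        stair = WeightedUpDown(cfg)
        for _ in range(5):
            stair.update(True)
        # four boosted steps of 3 then one ordinary step of 1
        assert stair.level == pytest.approx(-(4 * 3.0 + 1.0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StaircaseConfig(up_step=0.0, down_step=1.0, start_level=0.0,
                            n_trials=5)


class TestCSFSession:
    def test_session_size_and_layout(self):
        obs = AdhocCSFObserver(M=60, a=1.0, b=2.5, sigma=0.4)
        trials = simulate_csf_session(obs, seed=0)
        assert len(trials) == 165
        assert trials.groupby("sf").size().eq(15).all()
        assert trials.sf.nunique() == 11

    def test_deterministic_under_fixed_seed(self):
        obs = AdhocCSFObserver(M=60, a=1.0, b=2.5, sigma=0.4, key3_rate=0.5)
        a = simulate_csf_session(obs, seed=42)
        b = simulate_csf_session(obs, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_observer_descends_monotonically(self):
        class Perfect(AdhocCSFObserver):
            def p_seen(self, c, f):
                return 1.0
        obs = Perfect(M=1, a=1, b=1, sigma=1, lapse=0.0)
        trials = simulate_csf_session(obs, seed=0)
        for _, grp in trials.groupby("sf"):
            assert np.all(np.diff(np.log10(grp.contrast.to_numpy())) < 1e-12)

    def test_chance_observer_drifts_to_ceiling(self):
        class Blind(AdhocCSFObserver):
            def p_seen(self, c, f):
                return 0.0
        obs = Blind(M=1, a=1, b=1, sigma=1, lapse=0.0)
        trials = simulate_csf_session(obs, seed=0)
        # staircases that started low end far above their start contrast
        last = trials.groupby("sf").contrast.last().to_numpy()
        start = CSF_START_CONTRASTS
        low_start = start < 0.1
        assert np.all(last[low_start] > start[low_start] * 3)

    def test_undecided_recorded_and_scored_randomly(self):
        obs = AdhocCSFObserver(M=60, a=1.0, b=2.5, sigma=0.4, key3_rate=1.0,
                               lapse=0.0)
        trials = simulate_csf_session(obs, seed=1)
        und = trials.loc[trials.response == "undecided"]
        assert len(und) > 0
        assert und.scored_correct.nunique() == 2  # both outcomes occur


class TestTiltSession:
    def test_session_size_and_structure(self):
        obs = AdhocTiltObserver(biases=ZERO_BIASES, thresholds=FLAT_THRESH)
        trials = simulate_tilt_session(obs, sf=2.83, seed=0)
        assert len(trials) == 420
        assert trials.groupby("surround_orientation").size().eq(60).all()

    def test_deterministic_under_fixed_seed(self):
        obs = ModelTiltObserver(params=TiltParams(0.1, 20.0),
                                suppression=SuppressionField(amplitude=0.4))
        a = simulate_tilt_session(obs, sf=2.83, seed=9)
        obs2 = ModelTiltObserver(params=TiltParams(0.1, 20.0),
                                 suppression=SuppressionField(amplitude=0.4))
        b = simulate_tilt_session(obs2, sf=2.83, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_suppression_no_not_seen(self):
        obs = AdhocTiltObserver(biases=ZERO_BIASES, thresholds=FLAT_THRESH)
        trials = simulate_tilt_session(obs, sf=2.83, seed=0)
        assert (trials.response != "not_seen").all()

    def test_suppression_grows_toward_iso_orientation_and_high_sf(self):
        s = SuppressionField(amplitude=0.5)
        assert s(0.0, 8.0) > s(30.0, 8.0) > s(75.0, 8.0)
        assert s(0.0, 16.0) > s(0.0, 2.0)

    def test_staircases_converge_to_their_tracked_points(self):
        """With a zero-bias observer the 2/5 track settles where
        P(CW) ~ 2/7 and the 5/2 track where P(CW) ~ 5/7 (wide-spread
        observer so the mean level is an unbiased readout)."""
        wide = {k: 25.0 for k in FLAT_THRESH}
        obs = AdhocTiltObserver(biases=ZERO_BIASES, thresholds=wide,
                                lapse=0.0)
        trials = simulate_tilt_session(obs, sf=2.83, seed=2,
                                       n_per_staircase=400)
        sub = trials.loc[trials.surround_orientation == 0.0]
        # strict alternation: even rows track A (2/5), odd rows track B
        a_levels = sub.target_orientation.to_numpy()[::2][200:]
        b_levels = sub.target_orientation.to_numpy()[1::2][200:]
        p_a = eval_tilt_psychometric(a_levels.mean(), 0.0, 25.0, lam=0.0)
        p_b = eval_tilt_psychometric(b_levels.mean(), 0.0, 25.0, lam=0.0)
        assert p_a == pytest.approx(2.0 / 7.0, abs=0.04)
        assert p_b == pytest.approx(5.0 / 7.0, abs=0.04)


class TestCohort:
    def test_same_seed_same_cohort(self):
        a = make_cohort(3, seed=5)
        b = make_cohort(3, seed=5)
        assert a == b

    def test_group_structure_by_construction(self):
        specs = make_cohort(6, seed=1)
        by_type = {t: [s for s in specs if s.eye_type == t]
                   for t in ("AE", "NAE", "NTE")}
        assert all(len(v) == 6 for v in by_type.values())
        mean_sigma = {t: np.mean([s.sigma_theta for s in v])
                      for t, v in by_type.items()}
        assert mean_sigma["AE"] > mean_sigma["NTE"]
        assert mean_sigma["AE"] > mean_sigma["NAE"]

    def test_inhibition_anticorrelates_with_generated_sensitivity(self):
        """Within the amblyopic regime, stronger lateral inhibition lowers
        the generated low-SF sensitivity (mechanical consequence of the
        CSF model)."""
        from scipy.stats import spearmanr
        from tiltcsf.csf_model import NeuronalSensitivity, predict_csf
        specs = [s for s in make_cohort(10, seed=2) if s.eye_type == "AE"]
        sens_low = []
        for s in specs:
            csf = predict_csf(NeuronalSensitivity(s.c_min, s.a, s.b), s.I_inh,
                              sf_grid=np.array([2.83]))
            sens_low.append(csf.sensitivity[0])
        rho, _ = spearmanr([s.I_inh for s in specs], sens_low)
        assert rho < -0.5

    def test_subject_bundle_shapes(self):
        spec = make_cohort(1, seed=0)[0]
        data = simulate_subject(spec)
        assert len(data["csf"]) == 165
        assert len(data["tilt_low"]) == 420 and len(data["tilt_high"]) == 420
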