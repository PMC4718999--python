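"""Coordinate transforms, map learning stages, and the choice circuit."""

import numpy as np
import pytest

from saccart.maps import (
    ChoiceParams,
    HeadCenteredTarget,
    MotorErrorVector,
    SaccartModel,
    SpaceConfig,
    choice_circuit,
    multimodal_combine,
    reactive_map_input,
    teaching_signal,
)
from saccart.scenarios import TRAINED_POSITIONS


@pytest.fixture
def space():
    return SpaceConfig()


class TestGeometry:
    def test_default_grid(self, space):
        assert space.n_loci == 41
        assert space.spacing == pytest.approx(2.0)
        assert space.loci[0, 0] == -40.0 and space.loci[-1, 0] == 40.0

    def test_locus_round_trip(self, space):
        for p in (-40.0, -13.0, 0.0, 7.0, 40.0):
            locus = space.locus_of(np.array([p]))
            assert abs(space.position_of(locus)[0] - p) <= space.spacing / 2

    def test_too_coarse_map_rejected(self):
        with pytest.raises(ValueError):
            SpaceConfig(n_cells=5)

    def test_two_dimensional_grid(self):
        sp = SpaceConfig(d=2, n_cells=11)
        assert sp.n_loci == 121
        locus = sp.locus_of(np.array([8.0, -8.0]))
        assert np.allclose(sp.position_of(locus), [8.0, -8.0])


class TestOpponentCoding:
    @pytest.mark.parametrize("v", [-12.5, 0.0, 7.0])
    def test_rectified_pair_and_decode(self, v):
        mev = MotorErrorVector.from_signed(v)
        assert np.all(mev.agonist >= 0) and np.all(mev.antagonist >= 0)
        assert mev.agonist[0] * mev.antagonist[0] == 0  # one side silent
        assert mev.signed[0] == pytest.approx(v)

    def test_opponent_channel_vector(self):
        mev = MotorErrorVector.from_signed(np.array([6.0]))
        assert mev.opponent() == pytest.approx([6.0, 0.0])


class TestReactiveInput:
    def test_foveal_target_hits_center_locus(self, space):
        act = reactive_map_input(0.0, space).activity
        assert np.argmax(act) == space.locus_of(np.array([0.0]))

    def test_topographic_placement_and_salience(self, space):
        m = reactive_map_input(10.0, space, salience=0.7)
        locus = int(np.argmax(m.activity))
        assert space.position_of(locus)[0] == pytest.approx(10.0)
        assert m.activity[locus] == pytest.approx(0.7)
        assert m.activity.sum() == pytest.approx(0.7)  # delta bump

    def test_out_of_extent_clipped_with_warning(self, space):
        with pytest.warns(UserWarning):
            m = reactive_map_input(55.0, space)
        assert np.argmax(m.activity) == space.n_loci - 1


class TestTeachingSignal:
    def test_gaussian_shape(self, space):
        g = teaching_signal(20, space, sigma_g=3.0)
        assert g[20] == pytest.approx(1.0)
        assert g[23] == pytest.approx(np.exp(-0.5), abs=1e-12)  # one sigma out
        assert g[17] == pytest.approx(g[23])  # symmetric


class TestCerebellarGain:
    def test_zero_error_no_change(self):
        model = SaccartModel()
        model.cerebellar_gain_update(10, 0.0)
        assert np.all(model.gain[10] == 0)

    def test_overshoot_decreases_gain(self):
        model = SaccartModel()
        model.cerebellar_gain_update(10, -2.0)
        assert model.gain[10][0] < 0

    def test_landing_error_converges_geometrically(self):
        """Closed-loop scalar iteration: with plant gain 0.8 and rate 0.3
        the landing error contracts by (1 - 0.3*0.8) per trial and falls
        below 0.1 degrees within 50 trials (matches the geometric series)."""
        model = SaccartModel()
        target = 10.0
        locus = model.space.locus_of(np.array([target]))
        lam, plant = 0.3, model.plant_gain
        contraction = 1 - lam * plant
        err0 = target * (1 - plant)
        for n in range(50):
            v = MotorErrorVector.from_signed(np.array([target]))
            landing = plant * model.command(v, locus)
            err = target - landing[0]
            assert err == pytest.approx(err0 * contraction**n, abs=1e-9)
            model.cerebellar_gain_update(locus, err, lam)
        assert abs(err) < 0.1


class TestVAM:
    def test_corollary_subtraction_after_convergence(self):
        model = SaccartModel()
        locus = model.space.locus_of(np.array([10.0]))
        model.vam_w[locus] = 10.0
        v = model.compute_motor_error_vector(locus, 4.0)
        assert v.signed[0] == pytest.approx(6.0)
        assert v.agonist[0] == pytest.approx(6.0) and v.antagonist[0] == 0.0
        assert model.compute_motor_error_vector(locus, 10.0).signed[0] == 0.0

    def test_single_learning_step_is_convex(self):
        model = SaccartModel()
        model.vam_learn(5, 10.0, postural_gate=True, lam=0.5)
        assert model.vam_w[5][0] == pytest.approx(5.0)

    def test_closed_postural_gate_blocks_learning(self):
        model = SaccartModel()
        model.vam_learn(5, 10.0, postural_gate=False)
        assert model.vam_w[5][0] == 0.0

    def test_convergence_within_thirty_accurate_trials(self):
        model = SaccartModel()
        locus = model.space.locus_of(np.array([20.0]))
        for _ in range(30):
            model.vam_learn(locus, 20.0, postural_gate=True, lam=0.5)
        assert abs(model.vam_w[locus][0] - 20.0) < 1e-3

    def test_read_out_interpolates_between_trained_loci(self):
        model = SaccartModel()
        for p in (10.0, 20.0):
            locus = model.space.locus_of(np.array([p]))
            model.vam_w[locus] = p
            model.vam_trained[locus] = True
        assert model.vam_read(np.array([15.0]))[0] == pytest.approx(15.0)
        assert model.vam_read(np.array([10.0]))[0] == pytest.approx(10.0)


class TestVectorToMap:
    def test_rechoosing_fixed_point(self):
        model = SaccartModel()
        v = MotorErrorVector.from_signed(np.array([10.0]))
        w1 = model.vector_to_map_choose_and_learn(v, eta=0.2)
        proto = model.som_proto[w1].copy()
        w2 = model.vector_to_map_choose_and_learn(v, eta=0.2)
        assert w1 == w2
        assert model.som_proto[w2] == pytest.approx(proto)  # already at v

    def test_opposite_vectors_map_to_distinct_winners(self):
        model = SaccartModel()
        up = MotorErrorVector.from_signed(np.array([15.0]))
        down = MotorErrorVector.from_signed(np.array([-15.0]))
        for _ in range(5):
            wu = model.vector_to_map_choose_and_learn(up, eta=0.3)
            wd = model.vector_to_map_choose_and_learn(down, eta=0.3)
        assert wu != wd

    def test_eta_zero_is_choice_only(self):
        model = SaccartModel()
        before = model.som_proto.copy()
        model.vector_to_map_choose_and_learn(
            MotorErrorVector.from_signed(np.array([7.0])), eta=0.0
        )
        assert np.array_equal(model.som_proto, before)


class TestMapToMap:
    def test_teacher_equal_to_row_is_fixed_point(self):
        model = SaccartModel()
        teacher = teaching_signal(25, model.space)
        model.m2m[3] = teacher
        model.map_to_map_learn(3, teacher, eta=0.5)
        assert model.m2m[3] == pytest.approx(teacher)

    def test_repeated_pairing_converges_to_teacher_peak(self):
        model = SaccartModel()
        teacher = teaching_signal(30, model.space)
        for _ in range(40):
            model.map_to_map_learn(7, teacher, eta=0.2)
        assert int(np.argmax(model.m2m[7])) == 30
        assert model.m2m[7][30] == pytest.approx(1.0, abs=1e-3)

    def test_closed_mask_blocks_learning(self):
        model = SaccartModel()
        teacher = teaching_signal(30, model.space)
        model.map_to_map_learn(7, teacher, competition_mask=np.zeros_like(teacher))
        assert np.all(model.m2m[7] == 0)

    def test_mask_suppresses_uncorrelated_loci(self):
        model = SaccartModel()
        teacher = teaching_signal(30, model.space)
        mask = model.competition_mask(30)
        model.map_to_map_learn(7, teacher, competition_mask=mask, eta=1.0)
        assert model.m2m[7][30] == pytest.approx(1.0)
        assert model.m2m[7][0] == 0.0  # outside the winning neighborhood


class TestChoiceCircuit:
    def test_single_input_wins(self, space):
        bu = np.zeros(space.n_loci)
        bu[25] = 1.0
        res = choice_circuit(bu, space)
        assert res.winner == 25
        assert res.winner_activity > 0.2

    def test_stronger_evidence_wins_and_loser_suppressed(self, space):
        bu = np.zeros(space.n_loci)
        bu[25], bu[10] = 1.0, 0.6
        res = choice_circuit(bu, space)
        assert res.winner == 25
        assert res.activity[10] < 1e-6

    def test_equal_inputs_break_to_lowest_index(self, space):
        bu = np.zeros(space.n_loci)
        bu[10] = bu[30] = 1.0
        assert choice_circuit(bu, space).winner == 10

    def test_empty_input_returns_none(self, space):
        assert choice_circuit(np.zeros(space.n_loci), space).winner is None

    def test_winner_matches_argmax_on_random_probes(self, space):
        rng = np.random.default_rng(8)
        for _ in range(10):
            bu = np.zeros(space.n_loci)
            idx = rng.choice(space.n_loci, size=6, replace=False)
            bu[idx] = rng.uniform(0.3, 3.0, size=6)
            assert choice_circuit(bu, space).winner == int(np.argmax(bu))

    def test_total_activity_normalized_below_ceiling(self, space):
        """Divisive normalization: total equilibrium activity stays below
        the shunting ceiling for any number or strength of inputs."""
        B = ChoiceParams().shunt.B
        rng = np.random.default_rng(5)
        probes = [teaching_signal(20, space) + teaching_signal(24, space)]
        for _ in range(5):
            # spatially resolved targets: distinct loci at least 3 cells
            # apart (closer high-salience deltas merge into one target and
            # are the saccadic-averaging regime, probed above)
            idx = rng.permutation(np.arange(0, space.n_loci, 3))[:8]
            bu = np.zeros(space.n_loci)
            bu[idx] = rng.uniform(0.5, 5.0, size=len(idx))
            probes.append(bu)
        for bu in probes:
            assert choice_circuit(bu, space).activity.sum() <= B

    def test_loser_suppression_grows_with_winner_strength(self, space):
        """The divisive surround bites harder as the winner strengthens."""
        loser_acts = []
        for amp in (0.8, 1.2, 1.6, 2.0):
            bu = np.zeros(space.n_loci)
            bu[25], bu[10] = amp, 0.75
            res = choice_circuit(bu, space)
            # track the loser's best transient activity across the settle
            loser_acts.append(res.trace[:, 10].max())
        assert all(np.diff(loser_acts) <= 1e-12)


class TestMultimodal:
    def test_aligned_inputs_enhance_winner(self, space):
        vis = np.zeros(space.n_loci)
        vis[20] = 1.0
        aud = np.zeros(space.n_loci)
        aud[20] = 0.8
        out = multimodal_combine(vis, aud, space)
        assert out["enhanced"]
        assert out["bimodal"].winner == 20

    def test_competing_inputs_suppress_winner(self, space):
        vis = np.zeros(space.n_loci)
        vis[20] = 1.0
        aud = np.zeros(space.n_loci)
        aud[30] = 0.8  # 20 degrees away
        out = multimodal_combine(vis, aud, space)
        assert out["suppressed"]
        assert out["bimodal"].winner == 20

    def test_zero_other_input_reduces_to_unimodal(self, space):
        vis = np.zeros(space.n_loci)
        vis[20] = 1.0
        out = multimodal_combine(vis, np.zeros(space.n_loci), space)
        assert out["bimodal"].winner_activity == pytest.approx(
            out["visual"].winner_activity
        )


class TestSaccadicAveraging:
    def test_overlapping_gaussians_average(self, space):
        """Two equal targets closer than twice the teacher width select a
        winner strictly between the component loci."""
        sigma_g = 3.0
        for sep in (2, 4, 5):
            g = teaching_signal(20, space, sigma_g) + teaching_signal(
                20 + sep, space, sigma_g
            )
            w = choice_circuit(g, space).winner
            assert 20 < w < 20 + sep

    def test_distant_targets_do_not_average(self, space):
        g = teaching_signal(12, space) + 0.9 * teaching_signal(30, space)
        assert choice_circuit(g, space).winner == 12


class TestTrainedModel:
    def test_map_alignment_auditory_and_planned(self, trained_model):
        """After colocated training the non-visual winner equals the visual
        winner at (at least) 90% of trained positions."""
        from saccart.trial import alignment_report

        for modality in ("auditory", "planned"):
            rep = alignment_report(trained_model, TRAINED_POSITIONS, modality)
            assert rep["aligned"].mean() >= 0.9

    def test_control_schedule_stays_near_chance(self, control_model):
        from saccart.trial import alignment_report

        rep = alignment_report(control_model, TRAINED_POSITIONS, "auditory")
        assert rep["aligned"].mean() <= 0.3

    def test_vam_recovers_identity_with_randomized_offsets(self):
        """Dedicated recovery protocol: trials start from randomized
        cell-aligned eye offsets; the learned head-centered read-out
        converges to the identity h -> h within 1e-2 degrees at every
        trained locus, and the motor-error vector is zero at fixation."""
        from saccart.trial import TrialConfig, run_trial

        model = SaccartModel(plant_gain=1.0)  # accurate foveation
        rng = np.random.default_rng(0)
        cfg = TrialConfig()
        offsets = np.array([-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0])
        for _ in range(15):
            for p in TRAINED_POSITIONS:
                e0 = float(rng.choice(offsets))
                run_trial(
                    [
                        HeadCenteredTarget("visual_reactive", p),
                        HeadCenteredTarget("auditory", p),
                    ],
                    model, cfg, eye0=e0,
                )
        for p in TRAINED_POSITIONS:
            locus = model.space.locus_of(np.array([p]))
            assert model.vam_trained[locus]
            assert abs(model.vam_w[locus][0] - p) < 1e-2
            v = model.compute_motor_error_vector(locus, model.vam_w[locus])
            assert abs(v.signed[0]) < 1e-9

    def test_trained_model_vam_close_to_identity(self, trained_model):
        for p in TRAINED_POSITIONS:
            locus = trained_model.space.locus_of(np.array([p]))
            assert trained_model.vam_trained[locus]
            assert abs(trained_model.vam_w[locus][0] - p) < 0.05

    def test_interpolation_within_one_cell(self, trained_model):
        """Untrained positions between trained ones are read out within one
        map cell of the topographically correct locus."""
        for p in (-25.0, -15.0, -5.0, 5.0, 15.0, 25.0):
            res = trained_model.choose([HeadCenteredTarget("auditory", p)])
            correct = trained_model.space.locus_of(np.array([p]))
            assert res.winner is not None
            assert abs(res.winner - correct) <= 1
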