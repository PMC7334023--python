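import dataclasses
import io

import numpy as np
import pytest

from strideloop import pipeline, synthio
from strideloop.recordings_io import ValidationError
from strideloop.stride_metrics import compute_stride_work


class TestSpecValidation:
    def test_defaults_valid(self):
        synthio.CohortSpec().validate()

    @pytest.mark.parametrize("field,value", [
        ("emg_onset_phase", 1.0),
        ("emg_duration_frac", 0.0),
        ("emg_duration_frac", 1.0),
        ("stride_period_s", -0.1),
        ("n_individuals", 0),
        ("obstacle_every", 0),
        ("cohort_label", "other"),
        ("noise_sd", -0.01),
    ])
    def test_invalid_fields_named(self, field, value):
        spec = dataclasses.replace(synthio.CohortSpec(), **{field: value})
        with pytest.raises(ValidationError):
            spec.validate()


class TestDeterminism:
    def test_same_seed_identical_bytes(self):
        spec = synthio.CohortSpec(n_individuals=2, strides_per_trial=4,
                                  sample_rate_hz=1000.0, seed=1)
        outs = []
        for _ in range(2):
            trials, gt = synthio.generate_cohort(spec)
            buf = io.BytesIO()
            for t in trials:
                for ch in sorted(t.channels):
                    buf.write(t.channels[ch].tobytes())
                buf.write(t.foot_contact.tobytes())
            buf.write(gt.table.to_csv().encode())
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_different_seed_differs(self):
        s1 = synthio.CohortSpec(n_individuals=1, strides_per_trial=4,
                                sample_rate_hz=1000.0, seed=1)
        s2 = dataclasses.replace(s1, seed=2)
        t1, _ = synthio.generate_cohort(s1)
        t2, _ = synthio.generate_cohort(s2)
        assert not np.array_equal(t1[0].channels["emg"], t2[0].channels["emg"])


class TestConstruction:
    def test_obstacle_flag_count(self):
        spec = synthio.CohortSpec(n_individuals=1, strides_per_trial=20,
                                  obstacle_every=5, sample_rate_hz=1000.0, seed=0)
        trials, gt = synthio.generate_cohort(spec)
        obs = [t for t in trials if t.meta.terrain == "obstacle"][0]
        assert int(obs.obstacle_contact.sum()) == 4
        assert int(gt.table["obstacle"].sum()) == 4

    def test_obstacle_contact_earlier(self):
        spec = synthio.CohortSpec(n_individuals=1, strides_per_trial=10,
                                  sample_rate_hz=1000.0, seed=0)
        _, gt = synthio.generate_cohort(spec)
        t = gt.table
        s0 = t[t["category"] == "S0"]["contact_phase"]
        lev = t[t["category"] == "L"]["contact_phase"]
        assert (s0 < lev.min()).all()
        assert s0.iloc[0] == pytest.approx(lev.iloc[0] - spec.contact_shift)

    def test_ground_truth_one_row_per_stride(self):
        spec = synthio.CohortSpec(n_individuals=2, strides_per_trial=7,
                                  sample_rate_hz=1000.0, seed=0)
        trials, gt = synthio.generate_cohort(spec)
        assert len(gt.table) == 2 * 2 * 7

    def test_work_target_reached_noise_free(self):
        """True W_net equals the trapezoidal integral of the noise-free power
        trace, which the depth solver pins to the prescribed level."""
        spec = synthio.CohortSpec(n_individuals=1, strides_per_trial=6,
                                  sample_rate_hz=2000.0, noise_sd=0.0,
                                  individual_sd=0.0, force_individual_rel_sd=0.0,
                                  work_level_Jkg=2.0, seed=0)
        trials, gt = synthio.generate_cohort(spec)
        lev = gt.table[gt.table["terrain"] == "level"]
        np.testing.assert_allclose(lev["W_net"], 2.0, rtol=1e-6)
        s0 = gt.table[gt.table["category"] == "S0"]
        np.testing.assert_allclose(s0["W_net"], 2.0 + spec.work_obstacle_delta_Jkg,
                                   rtol=1e-6)

    def test_downstream_work_recovery_2pc(self):
        """Trapezoid oracle: compute_stride_work on a noise-free generated
        level stride returns the prescribed 2.0 J/kg within 2%."""
        spec = synthio.CohortSpec(n_individuals=1, strides_per_trial=5,
                                  sample_rate_hz=2000.0, noise_sd=0.0,
                                  individual_sd=0.0, force_individual_rel_sd=0.0,
                                  work_level_Jkg=2.0, seed=4)
        trials, gt = synthio.generate_cohort(spec)
        lev = trials[0]
        fs, T = spec.sample_rate_hz, spec.stride_period_s
        i0, i1 = int(1 * T * fs), int(2 * T * fs)  # first core stride
        L = lev.channels["fascicle_length"][i0:i1] / gt.L_o_mm["i01"]
        F = lev.channels["tendon_force"][i0:i1]
        w = compute_stride_work(F, L, gt.L_o_mm["i01"], 1 / fs, spec.muscle_mass_g)
        assert w == pytest.approx(2.0, rel=0.02)


class TestTemplate:
    def test_level_template_shapes(self):
        spec = synthio.CohortSpec()
        phi = np.arange(400) / 400
        L, F, env = synthio.stride_template(phi, spec)
        # single swing maximum before contact
        i_pk = np.argmax(L)
        assert phi[i_pk] == pytest.approx(synthio.PHI_PEAK_LENGTH, abs=0.01)
        assert phi[i_pk] < synthio.PHI_CONTACT_LEVEL
        # force zero in mid-swing, unimodal in stance
        assert F[int(0.9 * 400):].max() == 0.0 and F[:int(0.1 * 400)].max() == 0.0
        d = np.diff(F[F > 0])
        sign_changes = np.count_nonzero(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes <= 1
        # envelope is one burst of the requested width
        width = np.trapezoid(env, phi)
        assert width == pytest.approx(spec.emg_duration_frac, abs=0.01)
        # level-terrain fractional length spans roughly 0.9-1.1
        assert 0.85 < L.min() < 0.97 and 1.05 < L.max() <= 1.15

    def test_counter_clockwise_positive_work(self):
        """Stance shortening under force yields a counter-clockwise loop
        with net positive work."""
        spec = synthio.CohortSpec()
        phi = np.arange(400) / 400
        L, F, _ = synthio.stride_template(phi, spec)
        from strideloop.stride_metrics import work_loop_area
        assert work_loop_area(F, L, spec.reference_length_mm) > 0

    def test_zero_force_zero_work(self):
        spec = synthio.CohortSpec()
        phi = np.arange(200) / 200
        L, F, _ = synthio.stride_template(phi, spec)
        w = compute_stride_work(0 * F, L, spec.reference_length_mm,
                                spec.stride_period_s / 200, spec.muscle_mass_g)
        assert w == 0.0

    def test_onset_at_peak_gives_zero_phase(self):
        spec = synthio.CohortSpec(emg_onset_phase=0.0)
        phi = np.arange(400) / 400
        L, _, env = synthio.stride_template(phi, spec)
        # envelope crosses half exactly at the swing peak-length phase
        i = np.flatnonzero(env >= 0.5)[0]
        assert phi[i] == pytest.approx(synthio.PHI_PEAK_LENGTH, abs=0.005)

    def test_non_monotone_grid_rejected(self):
        spec = synthio.CohortSpec()
        with pytest.raises(ValidationError):
            synthio.stride_template(np.array([0.0, 0.2, 0.1]), spec)


class TestMonotonicity:
    def test_work_delta_monotone_in_recovered_difference(self):
        """Increasing the obstacle work increment strictly increases the
        recovered mean (S0 - Level) work difference."""
        diffs = []
        for delta in (1.5, 3.0, 4.5):
            spec = synthio.CohortSpec(n_individuals=2, strides_per_trial=10,
                                      sample_rate_hz=2000.0, noise_sd=0.0,
                                      individual_sd=0.0, force_individual_rel_sd=0.0,
                                      emg_onset_sd=0.0,
                                      work_obstacle_delta_Jkg=delta, seed=9)
            trials, _ = synthio.generate_cohort(spec)
            table, _ = pipeline.build_stride_table(trials)
            diffs.append(table[table.category == "S0"]["W_net"].mean()
                         - table[table.category == "L"]["W_net"].mean())
        assert diffs[0] < diffs[1] < diffs[2]


class TestMetricSimulator:
    def test_balanced_layout(self):
        tab = synthio.simulate_metric_table(n_per_cohort=3, strides_level=8,
                                            strides_obstacle=2, seed=0)
        assert len(tab) == 2 * 3 * (8 + 4 * 2)
        assert set(tab["treatment"]) == {"intact", "reinnervated"}
        assert set(tab["stride_id"]) == {"L", "S-1", "S0", "S+1", "S+2"}

    def test_effects_enter_cell_means(self):
        tab = synthio.simulate_metric_table(
            n_per_cohort=6, strides_level=50, strides_obstacle=50,
            interaction_effects={("intact", "S0"): 3.6}, resid_sd=0.01,
            ind_sd=0.0, seed=1)
        cell = tab.groupby(["treatment", "stride_id"])["y"].mean()
        assert cell["intact", "S0"] - cell["intact", "L"] == pytest.approx(3.6, abs=0.01)
        assert cell["reinnervated", "S0"] - cell["reinnervated", "L"] == pytest.approx(0.0, abs=0.01)
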