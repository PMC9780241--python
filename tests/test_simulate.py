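"""Ground-truth fidelity of the synthetic ERP and sleep-EEG generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nadsleep import erp, filters, simulate, spindles
from nadsleep.errors import ConfigurationError, GenerationError, InputError
from nadsleep.recording import (ERP_MONTAGE, NONREM_STAGES, Recording,
                                read_edf, read_float_container,
                                read_hypnogram, write_edf,
                                write_float_container, write_hypnogram)
from nadsleep.schedule import generate_trial_schedule
from nadsleep.simulate import (EffectSpec, EvokedComponent, NoiseSpec,
                               SpindleSimSpec, default_effect_spec,
                               generate_erp_dataset, generate_sleep_eeg)


@pytest.fixture(scope="module")
def schedule():
    return generate_trial_schedule(1, 7)


def single_component_spec(amp=-2.0):
    comp = EvokedComponent("probe", "test", ("CZ",), 300.0, 200.0,
                           "regularity",
                           {"regular": amp, "irregular": amp})
    return EffectSpec([comp])


class TestErpGenerator:
    def test_noise_free_bump_peak_identity(self, schedule):
        """With zero noise, the averaged evoked bump peaks at exactly the
        injected amplitude on the component's centre electrode, and every
        trial carries the identical waveform."""
        noise = NoiseSpec(rms_uv=0.0, artifact_prob=0.0)
        subs = generate_erp_dataset(schedule, single_component_spec(-2.0),
                                    noise, 1, seed=0,
                                    subject_amp_sd_uv=0.0)
        rec = subs[0].recordings["test"]
        ev = subs[0].events["test"]
        epochs = erp.epoch_suffix_locked(rec, ev)
        cz = epochs.ch_names.index("CZ")
        trials = epochs.samples[:, cz, :]
        np.testing.assert_array_equal(
            trials, np.broadcast_to(trials[0], trials.shape))
        avg = erp.average_condition(epochs, {"regularity": "regular"})
        peak_idx = np.argmin(avg.data[cz])
        assert avg.data[cz, peak_idx] == pytest.approx(-2.0, abs=1e-6)
        assert epochs.times_ms[peak_idx] == pytest.approx(300.0, abs=2.1)

    def test_zero_artifact_probability_keeps_all_trials(self, schedule):
        noise = NoiseSpec(rms_uv=10.0, artifact_prob=0.0)
        subs = generate_erp_dataset(schedule, default_effect_spec(), noise,
                                    1, seed=1)
        rec = erp.rereference_to_mastoids(subs[0].recordings["test"])
        epochs = erp.reject_artifacts(
            erp.epoch_suffix_locked(rec, subs[0].events["test"]))
        assert epochs.mask.all()

    def test_injected_artifacts_are_rejected(self, schedule):
        noise = NoiseSpec(rms_uv=10.0, artifact_prob=1.0)
        subs = generate_erp_dataset(schedule, default_effect_spec(), noise,
                                    1, seed=1)
        rec = erp.rereference_to_mastoids(subs[0].recordings["test"])
        epochs = erp.reject_artifacts(
            erp.epoch_suffix_locked(rec, subs[0].events["test"]))
        # every trial received a 400 µV square (a few fall on mastoids,
        # whose subtraction still leaves a 200 µV excursion on all channels)
        assert (~epochs.mask).mean() > 0.95

    def test_unknown_electrode_rejected(self, schedule):
        bad = EffectSpec([EvokedComponent(
            "x", "test", ("XX",), 300.0, 200.0, "regularity",
            {"regular": 1.0, "irregular": 1.0})])
        with pytest.raises(ConfigurationError, match="XX"):
            generate_erp_dataset(schedule, bad, NoiseSpec(), 1, seed=0)

    def test_group_assignment_and_determinism(self, schedule):
        noise = NoiseSpec()
        a = generate_erp_dataset(schedule, default_effect_spec(), noise, 2,
                                 seed=9, groups=["nap", "wake"])
        b = generate_erp_dataset(schedule, default_effect_spec(), noise, 2,
                                 seed=9, groups=["nap", "wake"])
        assert a[0].group == "nap" and a[1].group == "wake"
        np.testing.assert_array_equal(a[1].recordings["test"].data,
                                      b[1].recordings["test"].data)

    def test_ground_truth_table_covers_contrasts(self, schedule):
        subs = generate_erp_dataset(schedule, default_effect_spec(),
                                    NoiseSpec(), 1, seed=0, groups=["nap"])
        gt = subs[0].ground_truth
        assert set(gt.contrast) == {"familiarity", "memory"}
        probe = gt.query("contrast=='memory' and region=='frontal' and "
                         "window=='early'")
        # +1.5 µV peak difference -> positive injected window mean, with the
        # filtered value attenuated relative to the unfiltered one
        assert probe.true_uv_unfiltered.iloc[0] > 0.5
        assert 0 < probe.true_uv.iloc[0] < probe.true_uv_unfiltered.iloc[0]


class TestNullEffects:
    def test_zero_injected_effect_centered_on_zero(self, schedule):
        """With no injected contrast, group-mean effect values across
        repeated simulated datasets are centred on zero (two-sided sign
        test not rejected at alpha = 0.01)."""
        from scipy.stats import binomtest

        null_spec = single_component_spec(1.0)  # same amplitude, no contrast
        signs = []
        for sim in range(40):
            subs = generate_erp_dataset(schedule, null_spec,
                                        NoiseSpec(artifact_prob=0.0), 4,
                                        seed=3000 + sim)
            vals = []
            for s in subs:
                rec = erp.bandpass_erp(
                    erp.rereference_to_mastoids(s.recordings["test"]))
                ep = erp.epoch_suffix_locked(rec, s.events["test"])
                wa = erp.roi_waveforms(
                    erp.average_condition(ep, {"regularity": "irregular"}))
                wb = erp.roi_waveforms(
                    erp.average_condition(ep, {"regularity": "regular"}))
                vals.append(erp.effect_value(wa["frontal"], wb["frontal"],
                                             "early",
                                             "frontal").amplitude_uv)
            signs.append(np.mean(vals) > 0)
        p = binomtest(int(np.sum(signs)), len(signs), 0.5).pvalue
        assert p > 0.01


class TestSleepGenerator:
    def test_zero_density_empty_everywhere(self):
        spec = SpindleSimSpec(density_per_min=0.0)
        rec, hyp, gt = generate_sleep_eeg(spec, seed=3)
        assert gt.empty
        events, _, _ = spindles.run_spindle_analysis(rec, hyp,
                                                     channels=("F3",))
        # only noise-level false alarms possible; no planted events
        assert len(events) < 40

    def test_poisson_count_within_99_interval(self):
        """density 5/min on 20 min NonREM: realised counts inside the
        Poisson(100) 99% interval."""
        lo, hi = sps.poisson.ppf([0.005, 0.995], 100.0)
        for seed in range(5):
            _, _, gt = generate_sleep_eeg(SpindleSimSpec(), seed=seed)
            assert lo <= len(gt) <= hi

    def test_noise_free_p2p_identity(self):
        """background RMS 0, one event of p2p 40 µV: the band-passed signal
        inside the event spans ~40 µV."""
        spec = SpindleSimSpec(density_per_min=0.5, background_rms_uv=0.0,
                              mastoid_rms_uv=0.0, p2p_sd_uv=0.0,
                              duration_range_s=(1.5, 1.5),
                              hypnogram=(("W", 1), ("N2", 4), ("W", 1)))
        for seed in range(10):
            rec, hyp, gt = generate_sleep_eeg(spec, seed=seed)
            if len(gt) == 1:
                break
        assert len(gt) == 1
        x = rec.get("F3")
        fs = rec.sfreq
        raw_seg = x[int(gt.onset_s[0] * fs):int(gt.offset_s[0] * fs)]
        assert raw_seg.max() - raw_seg.min() == pytest.approx(40.0,
                                                              abs=1e-9)
        taps = filters.design_lowpass(32.0, fs, transition=6.0)
        low = filters.apply_zero_phase(x, taps)
        seg = low[int(gt.onset_s[0] * fs):int(gt.offset_s[0] * fs)]
        assert seg.max() - seg.min() == pytest.approx(40.0, rel=0.10)

    def test_ground_truth_confined_to_nonrem(self):
        for seed in range(3):
            rec, hyp, gt = generate_sleep_eeg(SpindleSimSpec(), seed=seed)
            stages = hyp.stage.to_numpy()
            for row in gt.itertuples():
                for t in (row.onset_s, row.offset_s - 1e-9):
                    assert stages[int(t // 30.0)] in NONREM_STAGES

    def test_minimum_gap_respected(self):
        _, _, gt = generate_sleep_eeg(SpindleSimSpec(), seed=11)
        g = gt.sort_values("onset_s")
        gaps = g.onset_s.to_numpy()[1:] - g.offset_s.to_numpy()[:-1]
        assert (gaps >= 0.6 - 1e-9).all()

    def test_infeasible_density_raises(self):
        spec = SpindleSimSpec(density_per_min=25.0,
                              duration_range_s=(4.0, 5.0))
        with pytest.raises(GenerationError, match="density"):
            generate_sleep_eeg(spec, seed=0)

    def test_invalid_durations_rejected(self):
        with pytest.raises(ConfigurationError):
            SpindleSimSpec(duration_range_s=(0.5, 6.0))


class TestDiskFormats:
    def test_float_container_roundtrip(self, rng, tmp_path):
        rec = Recording(rng.normal(size=(21, 5000)).astype(np.float32),
                        500.0, ERP_MONTAGE)
        write_float_container(rec, tmp_path / "sub000_test")
        back = read_float_container(tmp_path / "sub000_test")
        assert back.ch_names == rec.ch_names and back.sfreq == 500.0
        np.testing.assert_allclose(back.data, rec.data, rtol=1e-6)

    def test_missing_sidecar_raises(self, tmp_path):
        with pytest.raises(InputError, match="sidecar"):
            read_float_container(tmp_path / "nothing")

    def test_edf_roundtrip_via_mne(self, tmp_path):
        """Our EDF writer produces files mne reads back to within the
        16-bit quantisation error."""
        rec, hyp, _ = generate_sleep_eeg(SpindleSimSpec(
            hypnogram=(("W", 1), ("N2", 4), ("REM", 1))), seed=2)
        write_edf(rec, tmp_path / "nap.edf")
        back = read_edf(tmp_path / "nap.edf")
        assert back.ch_names == rec.ch_names
        assert back.sfreq == rec.sfreq
        span = rec.data.max() - rec.data.min()
        np.testing.assert_allclose(back.data[:, :rec.n_samples], rec.data,
                                   atol=span / 60000.0)

    def test_hypnogram_roundtrip_and_validation(self, tmp_path):
        hyp = pd.DataFrame(dict(epoch_index=[0, 1], stage=["W", "N2"],
                                artifact=[0, 0]))
        write_hypnogram(hyp, tmp_path / "h.tsv")
        assert read_hypnogram(tmp_path / "h.tsv").equals(hyp)
        bad = hyp.assign(stage=["W", "XX"])
        write_hypnogram(bad, tmp_path / "bad.tsv")
        with pytest.raises(InputError, match="XX"):
            read_hypnogram(tmp_path / "bad.tsv")
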