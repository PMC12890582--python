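"""Synthetic cohort generator: timing, acoustics, epidemiology, determinism."""

import numpy as np
import pytest
from scipy import stats

from cardioscreen.cohort import EchoReport, Rhythm, SeverityGrade, Site
from cardioscreen.simulate import (
    SimConfig,
    murmur_audible,
    simulate_cohort,
    simulate_cycle_times,
    synthesize_recording,
)

from conftest import band_rms


class TestCycleTimes:
    def test_sinus_60bpm_gives_one_cycle_per_second(self):
        cycles = simulate_cycle_times(60, Rhythm.SINUS, 3.0, seed=3)
        assert len(cycles) == 3
        for k, (s1, s2) in enumerate(cycles):
            assert abs(s1 - k) < 0.05  # < 5% of the RR interval
            assert s1 < s2

    def test_zero_duration_gives_empty_list(self):
        assert simulate_cycle_times(80, Rhythm.SINUS, 0.0, seed=0) == []

    def test_af_rr_variability_exceeds_sinus(self):
        af = simulate_cycle_times(75, Rhythm.ATRIAL_FIBRILLATION, 60.0, seed=1)
        rr_af = np.diff([c[0] for c in af])
        assert rr_af.std() / rr_af.mean() >= 0.15
        si = simulate_cycle_times(75, Rhythm.SINUS, 60.0, seed=1)
        rr_si = np.diff([c[0] for c in si])
        assert rr_si.std() / rr_si.mean() <= 0.05

    def test_onsets_strictly_interleaved(self):
        cycles = simulate_cycle_times(120, Rhythm.ATRIAL_FIBRILLATION, 10.0, seed=9)
        flat = [t for pair in cycles for t in pair]
        assert all(a < b for a, b in zip(flat, flat[1:]))

    def test_out_of_range_heart_rate_rejected(self):
        with pytest.raises(ValueError, match="heart rate"):
            simulate_cycle_times(20, Rhythm.SINUS, 5.0)


class TestSynthesizeRecording:
    CFG = SimConfig()

    def test_clean_echo_has_low_frequency_spectrum_and_no_murmur(self):
        echo = EchoReport.from_grades()
        rec, flag = synthesize_recording(echo, Site.M, self.CFG, seed=4, heart_rate=70)
        assert flag is False
        total = band_rms(rec.samples, rec.fs, 0, rec.fs / 2) ** 2
        low = band_rms(rec.samples, rec.fs, 0, 150) ** 2
        assert low / total >= 0.80

    def test_severe_as_adds_murmur_band_energy(self):
        clean = EchoReport.from_grades()
        diseased = EchoReport.from_grades(AS=3)
        kw = dict(seed=4, heart_rate=70, stethoscope=0)
        rec0, _ = synthesize_recording(clean, Site.A, self.CFG, **kw)
        rec1, flag = synthesize_recording(diseased, Site.A, self.CFG, **kw)
        assert flag is True
        e0 = band_rms(rec0.samples, rec0.fs, 150, 400)
        e1 = band_rms(rec1.samples, rec1.fs, 150, 400)
        assert 20 * np.log10(e1 / e0) >= 6.0

    def test_seeded_determinism_bit_identical(self):
        echo = EchoReport.from_grades(MR=2)
        a, _ = synthesize_recording(echo, Site.M, self.CFG, seed=11, heart_rate=80)
        b, _ = synthesize_recording(echo, Site.M, self.CFG, seed=11, heart_rate=80)
        assert np.array_equal(a.samples, b.samples)

    def test_amplitude_bounded(self):
        echo = EchoReport.from_grades(AS=3, MR=3, TR=3)
        rec, _ = synthesize_recording(echo, Site.A, self.CFG, seed=2)
        assert np.abs(rec.samples).max() <= 1.0

    @pytest.mark.parametrize("lesion,band,loud_site,quiet_site", [
        ("AS", (150, 400), Site.A, Site.M),
        ("MR", (100, 400), Site.M, Site.A),
    ])
    def test_radiation_pattern(self, lesion, band, loud_site, quiet_site):
        echo = EchoReport.from_grades(**{lesion: 3})
        kw = dict(seed=6, heart_rate=72, stethoscope=0)
        loud, _ = synthesize_recording(echo, loud_site, self.CFG, **kw)
        quiet, _ = synthesize_recording(echo, quiet_site, self.CFG, **kw)
        assert band_rms(loud.samples, loud.fs, *band) >= band_rms(quiet.samples, quiet.fs, *band)

    def test_murmur_band_rms_monotone_in_grade(self):
        kw = dict(seed=8, heart_rate=75, stethoscope=0)
        rms = []
        for g in range(4):
            echo = EchoReport.from_grades(AS=g)
            rec, _ = synthesize_recording(echo, Site.A, self.CFG, **kw)
            rms.append(band_rms(rec.samples, rec.fs, 150, 400))
        assert all(a <= b + 1e-12 for a, b in zip(rms, rms[1:]))


class TestCohort:
    def test_empty_cohort(self):
        assert simulate_cohort(SimConfig(n_patients=0)) == []

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            simulate_cohort(SimConfig(n_patients=1, prevalence_significant=1.5))

    def test_prevalence_within_exact_binomial_99_interval(self):
        n, prev = 1000, 0.45
        cohort = simulate_cohort(SimConfig(n_patients=n, prevalence_significant=prev, seed=17),
                                 render_audio=False)
        k = sum(p.significant for p in cohort)
        lo = stats.binom.ppf(0.005, n, prev)
        hi = stats.binom.ppf(0.995, n, prev)
        assert lo <= k <= hi

    def test_atm_site_presence_matches_configured_99pct(self):
        cfg = SimConfig()
        p_joint = np.prod([cfg.site_presence[s] for s in (Site.A, Site.T, Site.M)])
        assert abs(p_joint - 0.99) < 2e-3  # defaults target the 99% A/T/M convention
        n = 200
        audio = simulate_cohort(SimConfig(n_patients=n, seed=23))
        k = sum(all(p.recordings[s] for s in (Site.A, Site.T, Site.M)) for p in audio)
        lo = stats.binom.ppf(0.005, n, 0.99)
        hi = stats.binom.ppf(0.995, n, 0.99)
        assert lo <= k <= hi

    def test_label_consistency_and_murmur_implication(self, tiny_cohort):
        from cardioscreen.cohort import classify_significance
        for p in tiny_cohort:
            assert p.significant == classify_significance(p.echo)
            if any(p.murmur_truth.values()):
                assert any(g >= SeverityGrade.MILD for g in p.echo.grades.values())

    def test_cohort_determinism_bit_identical(self):
        cfg = SimConfig(n_patients=4, seed=77)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for pa, pb in zip(a, b):
            assert pa.id == pb.id and pa.echo.grades == pb.echo.grades
            for s in Site:
                ra, rb = pa.recordings[s], pb.recordings[s]
                assert len(ra) == len(rb)
                for x, y in zip(ra, rb):
                    assert np.array_equal(x.samples, y.samples)

    def test_murmur_audible_matches_rendered_flag(self, tiny_cohort):
        cfg = SimConfig()
        for p in tiny_cohort[:8]:
            for s in Site:
                if p.recordings[s]:
                    assert p.murmur_truth[s] == murmur_audible(p.echo, s, cfg)
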