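import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wavescan.detect import (DetectionConfig, ParameterBox, WaveTrain,
                             detect_wavetrains, events_to_frame, filter_short,
                             find_local_maxima, measure_wavetrain,
                             rate_per_second, select_box)
from wavescan.preprocess import SignalRecord
from wavescan.synth import BurstSpec, _add_burst
from wavescan.tfr import MorletParams, Spectrogram, wavelet_widths

FS = 125.0


def make_sg(psd, fmin=5.0, fstep=0.1, smoothed=True, mask=None):
    nf, nt = psd.shape
    freqs = fmin + fstep * np.arange(nf)
    if mask is None:
        mask = np.ones((nf, nt), bool)
    return Spectrogram(psd=psd, freqs=freqs, times=np.arange(nt) / FS, fs=FS,
                       params=MorletParams(), smoothed=smoothed,
                       valid_mask=mask, duration_s=nt / FS,
                       valid_duration_s=nt / FS)


def gaussian_blob(nf, nt, i0, j0, s_i=4.0, s_j=12.0, height=1.0):
    ii = (np.arange(nf) - i0)[:, None]
    jj = (np.arange(nt) - j0)[None, :]
    return height * np.exp(-0.5 * (ii / s_i) ** 2 - 0.5 * (jj / s_j) ** 2)


class TestLocalMaxima:
    def test_single_blob_gives_single_peak_at_center(self):
        sg = make_sg(gaussian_blob(60, 300, 30, 150))
        peaks = find_local_maxima(sg)
        assert peaks.shape == (1, 2)
        assert tuple(peaks[0]) == (30, 150)

    def test_constant_field_has_no_peaks(self):
        sg = make_sg(np.ones((40, 100)))
        assert len(find_local_maxima(sg)) == 0

    def test_two_separated_blobs_give_two_peaks(self):
        psd = (gaussian_blob(80, 400, 20, 100)
               + gaussian_blob(80, 400, 60, 300, height=0.7))
        peaks = find_local_maxima(make_sg(psd))
        assert len(peaks) == 2

    def test_plateau_is_not_a_peak(self):
        psd = np.zeros((20, 20))
        psd[10, 10] = psd[10, 11] = 1.0
        assert len(find_local_maxima(make_sg(psd))) == 0

    def test_masked_region_excluded(self):
        psd = gaussian_blob(60, 300, 30, 150)
        mask = np.ones_like(psd, bool)
        mask[:, 100:200] = False
        assert len(find_local_maxima(make_sg(psd, mask=mask))) == 0

    def test_unsmoothed_rejected(self):
        with pytest.raises(ValueError):
            find_local_maxima(make_sg(np.ones((10, 10)), smoothed=False))


class TestMeasure:
    def test_gaussian_slices_give_fwhm(self):
        s_j = 15.0   # samples
        s_i = 5.0    # frequency bins
        sg = make_sg(gaussian_blob(80, 500, 40, 250, s_i=s_i, s_j=s_j))
        ev = measure_wavetrain(sg, (40, 250))
        assert ev.rejected_code is None
        fwhm = 2 * math.sqrt(2 * math.log(2))
        assert abs(ev.duration_s - fwhm * s_j / FS) / (fwhm * s_j / FS) < 0.02
        assert abs(ev.bandwidth - fwhm * s_i * 0.1) / (fwhm * s_i * 0.1) < 0.02
        assert abs(ev.duration_periods - ev.duration_s * ev.f_central) < 1e-12

    def test_blob_truncated_by_record_edge_is_rejected(self):
        sg = make_sg(gaussian_blob(60, 120, 30, 10, s_j=30.0))
        ev = measure_wavetrain(sg, tuple(find_local_maxima(sg)[0]))
        assert ev.rejected_code == "EDGE"

    def test_peak_on_stronger_shoulder_is_rejected_as_engulfed(self):
        # a small ripple on the shoulder of a dominant train: the valley
        # between them stays above the ripple's half-maximum
        psd = gaussian_blob(60, 600, 30, 300, s_j=40.0, height=10.0)
        psd += gaussian_blob(60, 600, 30, 250, s_j=6.0, height=3.0)
        sg = make_sg(psd)
        peaks = {tuple(p) for p in find_local_maxima(sg)}
        small = [p for p in peaks if abs(p[1] - 250) < 12]
        assert small
        ev = measure_wavetrain(sg, small[0])
        assert ev.rejected_code == "ENGULFED"

    def test_injected_burst_duration_matches_convolution_oracle(self):
        # the worked-example train: 15.2 Hz, 3 periods
        f0, d = 15.2, 3.0
        n = int(12 * FS)
        x = np.zeros(n)
        _add_burst(x, BurstSpec(f0=f0, amplitude=5.0, duration_periods=d,
                                onset=6.0), FS, "gaussian")
        from wavescan.tfr import adaptive_smooth, cwt_spectrogram
        sg = adaptive_smooth(cwt_spectrogram(x + 10.0, fs=FS, fmin=5.0,
                                             fmax=30.0, fstep=0.1))
        best = max((measure_wavetrain(sg, p) for p in find_local_maxima(sg)),
                   key=lambda e: -np.inf if e.rejected_code else e.psd_max)
        st_, sf = wavelet_widths(f0)
        s = d / (2 * f0 * math.sqrt(math.log(2)))
        want = (2 * math.sqrt(2 * math.log(2))
                * math.sqrt((s * s + st_ * st_) / 2 + (st_ / 2) ** 2))
        assert abs(best.f_central - f0) <= 0.4
        assert abs(best.duration_s - want) / want < 0.1
        # the oracle predicts the broadening of the nominal 3-period duration
        assert abs(best.duration_periods - want * f0) / (want * f0) < 0.1


class TestFilterAndBox:
    def _ev(self, **kw):
        base = dict(t_peak=1.0, f_central=10.0, psd_max=5.0, duration_s=0.2,
                    duration_periods=2.0, bandwidth=3.0)
        base.update(kw)
        return WaveTrain(**base)

    def test_short_train_rule_boundary(self):
        evs = [self._ev(duration_periods=0.05), self._ev(duration_periods=0.1),
               self._ev(duration_periods=0.5)]
        kept = filter_short(evs)
        assert [e.duration_periods for e in kept] == [0.1, 0.5]
        assert filter_short([]) == []

    def test_box_intervals_are_closed(self):
        evs = [self._ev(f_central=f) for f in (5.0, 8.0, 10.0, 20.0, 25.0)]
        box = ParameterBox(min_freq=8.0, max_freq=20.0)
        assert [e.f_central for e in select_box(evs, box)] == [8.0, 10.0, 20.0]

    def test_unbounded_box_is_identity(self):
        evs = [self._ev(f_central=f) for f in (1.0, 30.0)]
        assert select_box(evs, ParameterBox()) == evs

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            ParameterBox(min_freq=10.0, max_freq=5.0)

    @given(st.lists(st.tuples(st.floats(0, 50), st.floats(0, 100),
                              st.floats(0.1, 10), st.floats(0, 20)),
                    max_size=20),
           st.tuples(st.floats(0, 25), st.floats(0, 25)),
           st.tuples(st.floats(0, 25), st.floats(0, 25)))
    def test_successive_selection_equals_intersection(self, rows, fa, fb):
        evs = [self._ev(f_central=f, psd_max=p, duration_periods=d, bandwidth=b)
               for f, p, d, b in rows]
        box_a = ParameterBox(min_freq=min(fa), max_freq=max(fa))
        box_b = ParameterBox(min_freq=min(fb), max_freq=max(fb))
        both = select_box(select_box(evs, box_a), box_b)
        assert both == select_box(evs, box_a.intersect(box_b))
        assert len(both) <= len(select_box(evs, box_a))

    def test_rate_arithmetic(self):
        evs = [self._ev()] * 45
        assert rate_per_second(evs, 90.0) == 0.5
        assert rate_per_second([], 90.0) == 0.0
        assert rate_per_second(evs, 45.0) == 2 * rate_per_second(evs, 90.0)
        with pytest.raises(ValueError):
            rate_per_second(evs, 0.0)


class TestDetect:
    def _record(self, seed=5):
        rng = np.random.default_rng(seed)
        n = int(20 * FS)
        x = 10.0 + rng.normal(0, 1.0, n)
        _add_burst(x, BurstSpec(10.0, 8.0, 3.0, 8.0), FS, "gaussian")
        np.maximum(x, 0, out=x)
        return SignalRecord(x, FS, subject_id="s1", group="patient",
                            stage="decimated_envelope")

    CFG = DetectionConfig(fmin=1.0, fmax=30.0, fstep=0.2)

    def test_detection_is_deterministic_and_sorted(self):
        rec = self._record()
        a = detect_wavetrains(rec, self.CFG)
        b = detect_wavetrains(rec, self.CFG)
        assert a.events == b.events
        t = [e.t_peak for e in a.events]
        assert t == sorted(t)

    def test_injected_burst_found_and_all_events_valid(self):
        rec = self._record()
        out = detect_wavetrains(rec, self.CFG)
        assert any(abs(e.f_central - 10.0) < 1.0 and abs(e.t_peak - 8.0) < 0.5
                   for e in out.events)
        for e in out.events:
            assert e.duration_periods >= 0.1
            assert e.psd_max > 0 and e.bandwidth > 0 and e.duration_s > 0
            assert self.CFG.fmin <= e.f_central <= self.CFG.fmax

    def test_event_frame_schema(self):
        out = detect_wavetrains(self._record(), self.CFG)
        frame = events_to_frame(out)
        assert list(frame.columns) == [
            "subject_id", "group", "arm", "muscle", "t_peak_s", "f_central_hz",
            "psd_max", "duration_s", "duration_periods", "bandwidth_hz",
            "rejected_code"]
        assert (frame.subject_id == "s1").all()
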