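import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgsubband as e
from ecgsubband.errors import (
    DegenerateSignalError,
    EmptySignalError,
    MissingFileError,
    ParseError,
    WFDBFormatError,
)


class TestReadRecord:
    def test_single_row_csv(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("0.1,0.2,0.3\n")
        sig = e.read_record(p, fs=250)
        assert len(sig) == 3
        np.testing.assert_allclose(sig.samples, [0.1, 0.2, 0.3])
        assert sig.fs == 250

    def test_one_sample_per_row(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("1.0\n2.0\n-3.5\n")
        np.testing.assert_allclose(e.read_record(p).samples, [1.0, 2.0, -3.5])

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingFileError):
            e.read_record(tmp_path / "absent.csv")

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1.0\n2.0\nbogus\n")
        with pytest.raises(ParseError, match="line 3"):
            e.read_record(p)

    def test_empty_signal(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(EmptySignalError):
            e.read_record(p)

    def test_roundtrip_lossless(self, tmp_path, rng):
        sig = e.ECGSignal(rng.standard_normal(100), fs=250)
        e.write_csv(sig, tmp_path / "x.csv")
        back = e.read_record(tmp_path / "x.csv")
        np.testing.assert_array_equal(back.samples, sig.samples)


class TestWFDB:
    def _write_record(self, tmp_path, data, fs=360, gain=200, baseline=0, fmt=16):
        """Synthetic WFDB pair written at test time (no shipped binary fixture)."""
        n_sig = data.shape[1]
        hea = tmp_path / "rec.hea"
        sig_lines = "\n".join(
            f"rec.dat {fmt} {gain}({baseline})" for _ in range(n_sig)
        )
        hea.write_text(f"rec {n_sig} {fs} {data.shape[0]}\n{sig_lines}\n")
        if fmt == 16:
            data.astype("<i2").tofile(tmp_path / "rec.dat")
        else:
            raise NotImplementedError
        return tmp_path / "rec"

    def test_format16_two_channels(self, tmp_path):
        adc = np.array([[100, -100], [200, -200], [300, -300]])
        rec = self._write_record(tmp_path, adc, gain=200)
        sig0 = e.read_record(rec, format="wfdb", channel=0)
        sig1 = e.read_record(rec, format="wfdb", channel=1)
        np.testing.assert_allclose(sig0.samples, [0.5, 1.0, 1.5])
        np.testing.assert_allclose(sig1.samples, [-0.5, -1.0, -1.5])
        assert sig0.fs == 360

    def test_format212(self, tmp_path):
        # pack the pairs (4, -4), (2047, -2048) by hand
        def pack(a, b):
            a &= 0xFFF
            b &= 0xFFF
            return bytes([a & 0xFF, ((b >> 8) << 4) | (a >> 8), b & 0xFF])

        (tmp_path / "r.hea").write_text("r 2 250 2\nr.dat 212 1(0)\nr.dat 212 1(0)\n")
        (tmp_path / "r.dat").write_bytes(pack(4, -4) + pack(2047, -2048))
        s0 = e.read_record(tmp_path / "r.hea", format="wfdb", channel=0)
        s1 = e.read_record(tmp_path / "r.hea", format="wfdb", channel=1)
        np.testing.assert_array_equal(s0.samples, [4, 2047])
        np.testing.assert_array_equal(s1.samples, [-4, -2048])

    def test_bad_channel(self, tmp_path):
        rec = self._write_record(tmp_path, np.array([[1], [2]]))
        with pytest.raises(WFDBFormatError):
            e.read_record(rec, format="wfdb", channel=3)


class TestResample:
    def test_halving_length(self, rng):
        x = e.ECGSignal(rng.standard_normal(1000), fs=500)
        y = e.resample(x, 250)
        assert len(y) == 500 and y.fs == 250

    def test_identity(self, rng):
        x = e.ECGSignal(rng.standard_normal(100), fs=250)
        y = e.resample(x, 250)
        np.testing.assert_array_equal(y.samples, x.samples)

    def test_spectral_peak_preserved(self):
        t = np.arange(500) / 500
        x = e.ECGSignal(np.sin(2 * np.pi * 5 * t), fs=500)
        y = e.resample(x, 250)
        spec = np.abs(np.fft.rfft(y.samples))
        freqs = np.fft.rfftfreq(len(y), d=1 / 250)
        assert abs(freqs[np.argmax(spec)] - 5.0) < 0.5

    def test_bad_rate(self, rng):
        x = e.ECGSignal(rng.standard_normal(10), fs=250)
        with pytest.raises(ValueError):
            e.resample(x, 0)


class TestSegment:
    def test_non_overlapping(self, rng):
        x = e.ECGSignal(rng.standard_normal(1500), fs=250, label="NSR", record_id="r")
        segs = e.segment(x, window_s=2.0, hop_s=2.0)
        assert len(segs) == 3
        assert all(len(s) == 500 for s in segs)
        assert all(s.label == "NSR" for s in segs)

    def test_too_short_returns_empty(self, rng, caplog):
        x = e.ECGSignal(rng.standard_normal(499), fs=250)
        with caplog.at_level("WARNING", logger="ecgsubband"):
            assert e.segment(x, window_s=2.0) == []
        assert any("shorter" in r.message for r in caplog.records)

    def test_overlapping_starts(self, rng):
        x = e.ECGSignal(rng.standard_normal(1250), fs=250)
        segs = e.segment(x, window_s=2.0, hop_s=1.0)
        assert len(segs) == 4
        for i, start in enumerate([0, 250, 500, 750]):
            np.testing.assert_array_equal(segs[i].samples, x.samples[start : start + 500])


class TestNormalize:
    @pytest.mark.parametrize(
        "x, expected",
        [([0.0, 2.0], [-1.0, 1.0]), ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0])],
    )
    def test_examples(self, x, expected):
        z = e.normalize(e.ECGSignal(np.array(x), fs=250))
        np.testing.assert_array_equal(z.samples, expected)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            e.normalize(e.ECGSignal(np.array([5.0, 5.0, 5.0]), fs=250))

    def test_max_abs_exactly_one(self, rng):
        for _ in range(20):
            z = e.normalize(rng.standard_normal(50))
            assert np.max(np.abs(z.samples)) == 1.0
            assert abs(z.samples.mean()) < 1e-9

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50).filter(
        lambda xs: max(xs) - min(xs) > 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent(self, xs):
        z1 = e.normalize(np.array(xs))
        z2 = e.normalize(z1.samples)
        np.testing.assert_allclose(z2.samples, z1.samples, atol=1e-12)

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30).filter(
            lambda xs: max(xs) - min(xs) > 1e-2),
        st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
        st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_scale_invariance(self, xs, a, b):
        x = np.array(xs)
        z = e.normalize(x)
        z2 = e.normalize(a * x + b)
        np.testing.assert_allclose(z2.samples, np.sign(a) * z.samples, atol=1e-7)
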