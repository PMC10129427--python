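"""Recording I/O, montage handling and the preprocessing chain."""

import json

import numpy as np
import pytest
from scipy import signal as sps

from qeegconn.errors import (
    EmptyResultError,
    FormatError,
    ParameterError,
    TooShortError,
)
from qeegconn.signal_io import (
    CANONICAL_1020,
    RegionMap,
    Recording,
    epoch_and_reject,
    normalize_label,
    preprocess,
    read_recording,
    write_recording,
)


# ---------------------------------------------------------------------------
# Labels and regions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "raw, expected",
    [("FP1", "Fp1"), ("cz", "Cz"), ("T7", "T3"), ("p8", "T6"), ("  O2 ", "O2"),
     ("EKG", "EKG")],
)
def test_label_normalization(raw, expected):
    assert normalize_label(raw) == expected


def test_default_region_assignment_matches_montage():
    rm = RegionMap.default()
    assert set(rm.channels_in("frontal")) == {"Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8"}
    assert set(rm.channels_in("central")) == {"C3", "Cz", "C4"}
    assert set(rm.channels_in("temporal")) == {"T3", "T4", "T5", "T6"}
    assert set(rm.channels_in("parietal")) == {"P3", "Pz", "P4"}
    assert set(rm.channels_in("occipital")) == {"O1", "Oz", "O2"}
    assert set(rm.assignment) == set(CANONICAL_1020)


@pytest.mark.parametrize(
    "label, hemi",
    [("C3", "left"), ("C4", "right"), ("Cz", "midline"), ("Fp1", "left"),
     ("T6", "right"), ("Oz", "midline")],
)
def test_hemisphere_from_label_suffix(label, hemi):
    assert RegionMap.hemisphere_of(label) == hemi


# ---------------------------------------------------------------------------
# Recording invariants and file round-trips
# ---------------------------------------------------------------------------


def test_recording_invariants(rng):
    with pytest.raises(FormatError):
        Recording(samples=rng.normal(size=(2, 10)), rate=0, labels=["C3", "C4"])
    with pytest.raises(FormatError):
        Recording(samples=rng.normal(size=(2, 10)), rate=100, labels=["C3"])
    bad = rng.normal(size=(2, 10))
    bad[0, 0] = np.nan
    with pytest.raises(FormatError):
        Recording(samples=bad, rate=100, labels=["C3", "C4"])


def test_matrix_roundtrip(tmp_path, rng, recording_factory):
    rec = recording_factory(rng.normal(size=(3, 200)), rate=128.0,
                            labels=["C3", "Cz", "C4"])
    path = tmp_path / "rec.tsv"
    write_recording(rec, path, format="matrix")
    back = read_recording(path, format="matrix")
    assert back.rate == rec.rate
    assert back.labels == rec.labels
    np.testing.assert_allclose(back.samples, rec.samples, rtol=1e-7)


def test_matrix_inline_header(tmp_path):
    path = tmp_path / "two.tsv"
    path.write_text("# rate=100; labels=C3,C4\n0.0\t1.0\t2.0\n3.0\t4.0\t5.0\n")
    rec = read_recording(path, format="matrix")
    assert rec.rate == 100
    assert rec.labels == ["C3", "C4"]
    assert rec.samples.shape == (2, 3)


def test_matrix_missing_rate_error(tmp_path):
    path = tmp_path / "norate.tsv"
    path.write_text("0.0\t1.0\n2.0\t3.0\n")
    with pytest.raises(FormatError):
        read_recording(path, format="matrix")


def test_duplicate_labels_error(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("# rate=100; labels=C3,C3\n0.0\t1.0\n2.0\t3.0\n")
    with pytest.raises(FormatError):
        read_recording(path, format="matrix")


def test_missing_file_error(tmp_path):
    from qeegconn.errors import InputError

    with pytest.raises(InputError):
        read_recording(tmp_path / "nope.tsv")


def test_edf_roundtrip(tmp_path, rng):
    """A 19-channel EDF written by the package reads back via mne."""
    labels = CANONICAL_1020[:19]
    samples = 50.0 * rng.normal(size=(19, 250 * 4))
    rec = Recording(samples=samples, rate=250.0, labels=labels, meta={})
    path = tmp_path / "rec.edf"
    write_recording(rec, path, format="edf")
    back = read_recording(path, format="edf")
    assert back.rate == 250.0
    assert back.n_channels == 19
    assert back.labels == labels
    # 16-bit quantization over the physical range bounds the error
    qstep = (samples.max() - samples.min()) / 65535
    np.testing.assert_allclose(back.samples, samples, atol=2 * qstep)


def test_unknown_labels_flagged(tmp_path, rng):
    path = tmp_path / "x.tsv"
    path.write_text("# rate=100; labels=C3,EKG\n0.0\t1.0\n2.0\t3.0\n")
    rec = read_recording(path)
    assert rec.meta["unknown_labels"] == ["EKG"]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _tone(freq, rate, dur):
    t = np.arange(int(rate * dur)) / rate
    return np.sin(2 * np.pi * freq * t)[None, :]


def test_notch_attenuates_line_noise():
    """A pure 50 Hz tone loses >= 30 dB at the notch bin."""
    rate = 500.0
    rec = Recording(samples=_tone(50, rate, 20), rate=rate, labels=["C3"], meta={})
    out = preprocess(rec, notch_hz=50.0, band=(0.5, 40.0))
    f, p_in = sps.periodogram(rec.samples[0], fs=rate)
    _, p_out = sps.periodogram(out.samples[0], fs=rate)
    k = np.argmin(np.abs(f - 50.0))
    atten_db = 10 * np.log10(p_in[k] / p_out[k])
    assert atten_db >= 30


def test_passband_tone_preserved():
    """In-band RMS change matches the filter's frequency response (< 5%)."""
    rate = 500.0
    rec = Recording(samples=_tone(10, rate, 20), rate=rate, labels=["C3"], meta={})
    out = preprocess(rec, notch_hz=50.0, band=(0.5, 40.0))
    # discard filter edge transients before comparing RMS
    sl = slice(int(rate), -int(rate))
    rms_in = np.sqrt(np.mean(rec.samples[0, sl] ** 2))
    rms_out = np.sqrt(np.mean(out.samples[0, sl] ** 2))
    assert abs(rms_out - rms_in) / rms_in < 0.05
    # oracle: evaluate the band-pass magnitude response at 10 Hz directly
    sos = sps.butter(4, [0.5, 40.0], btype="bandpass", output="sos", fs=rate)
    _, h = sps.sosfreqz(sos, worN=[10.0], fs=rate)
    gain = np.abs(h[0]) ** 2  # forward-backward squares the magnitude
    assert abs(rms_out / rms_in - gain) < 0.05


def test_preprocess_band_order_error(rng, recording_factory):
    rec = recording_factory(rng.normal(size=(1, 1000)), rate=250.0, labels=["C3"])
    with pytest.raises(ParameterError):
        preprocess(rec, band=(30.0, 10.0))
    with pytest.raises(ParameterError):
        preprocess(rec, band=(0.5, 200.0))  # beyond Nyquist
    with pytest.raises(ParameterError):
        preprocess(rec, notch_hz=300.0)


def test_preprocess_too_short_error():
    rec = Recording(samples=np.zeros((1, 20)), rate=250.0, labels=["C3"], meta={})
    with pytest.raises(TooShortError):
        preprocess(rec)


def test_preprocess_idempotent_in_passband():
    """Filtering twice changes an in-band tone's RMS by < 1% vs once."""
    rate = 500.0
    rec = Recording(samples=_tone(10, rate, 20), rate=rate, labels=["C3"], meta={})
    once = preprocess(rec)
    twice = preprocess(once)
    sl = slice(int(rate), -int(rate))
    r1 = np.sqrt(np.mean(once.samples[0, sl] ** 2))
    r2 = np.sqrt(np.mean(twice.samples[0, sl] ** 2))
    assert abs(r2 - r1) / r1 < 0.01


def test_preprocess_output_shape_and_rate(rng, recording_factory):
    rec = recording_factory(rng.normal(size=(3, 2000)), rate=250.0,
                            labels=["C3", "Cz", "C4"])
    out = preprocess(rec)
    assert out.samples.shape == rec.samples.shape
    assert out.rate == rec.rate
    assert out.labels == rec.labels


# ---------------------------------------------------------------------------
# Epoching and artifact rejection
# ---------------------------------------------------------------------------


def test_epoching_clean_recording(rng, recording_factory):
    rec = recording_factory(10 * rng.normal(size=(2, 2500)), rate=250.0,
                            labels=["C3", "C4"])
    rec.samples = np.clip(rec.samples, -99, 99)
    es = epoch_and_reject(rec, epoch_length_s=2.0, amplitude_limit_uv=100.0)
    assert es.n_epochs == 5
    assert es.kept_mask.all()
    assert es.concatenate().shape == (2, 5 * 500)


def test_epoch_with_spike_rejected(rng, recording_factory):
    samples = np.clip(10 * rng.normal(size=(2, 2500)), -99, 99)
    samples[1, 1200] = 500.0  # spike inside epoch index 2
    rec = recording_factory(samples, rate=250.0, labels=["C3", "C4"])
    es = epoch_and_reject(rec, epoch_length_s=2.0, amplitude_limit_uv=100.0)
    assert es.n_epochs == 4
    assert not es.kept_mask[2]
    assert es.kept_mask.sum() == 4


def test_all_epochs_rejected_error(rng, recording_factory):
    rec = recording_factory(rng.normal(size=(2, 2500)), rate=250.0,
                            labels=["C3", "C4"])
    with pytest.raises(EmptyResultError):
        epoch_and_reject(rec, epoch_length_s=2.0, amplitude_limit_uv=0.001)


def test_epoch_parameter_errors(rng, recording_factory):
    rec = recording_factory(rng.normal(size=(1, 2500)), rate=250.0, labels=["C3"])
    with pytest.raises(ParameterError):
        epoch_and_reject(rec, epoch_length_s=0.001)
    with pytest.raises(ParameterError):
        epoch_and_reject(rec, amplitude_limit_uv=-1.0)
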