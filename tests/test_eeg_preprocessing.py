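"""Re-referencing, filtering, resampling, epoching, channel selection."""

import numpy as np
import pytest

from biodimred import (
    ChannelConfig,
    P300Config,
    SignalRecord,
    epoch_stimulus_locked,
    generate_p300_record,
    preprocess_record,
    select_and_concatenate,
)
from biodimred.eeg import EXCLUDED_CHANNELS, REFERENCE_CHANNELS
from biodimred.synth_eeg import MONTAGE_32


def _sine_record(freq, fs=512.0, seconds=10.0):
    t = np.arange(int(seconds * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    data = np.vstack([x, np.zeros_like(x), np.zeros_like(x), np.zeros_like(x)])
    return SignalRecord(data, fs=fs, channel_names=["CZ", "O1", "OZ", "O2"])


def _central_rms(x, frac=0.8):
    n = x.size
    lo = int((1 - frac) / 2 * n)
    return np.sqrt(np.mean(x[lo:n - lo] ** 2))


def test_stop_band_attenuation():
    rec = _sine_record(20.0)
    out = preprocess_record(rec, order=7, cutoff=9.0, out_fs=128.0)
    assert _central_rms(out.channel("CZ")) < 0.05 * _central_rms(rec.channel("CZ"))


def test_pass_band_preserved():
    rec = _sine_record(2.0)
    out = preprocess_record(rec, order=7, cutoff=9.0, out_fs=128.0)
    assert abs(_central_rms(out.channel("CZ")) - _central_rms(rec.channel("CZ"))) \
        < 0.1 * _central_rms(rec.channel("CZ"))


def test_rereferencing_identity_gives_zero():
    """If every channel equals the O-channel average, output is all-zero."""
    t = np.arange(2048) / 512.0
    x = np.sin(2 * np.pi * 3 * t)
    data = np.vstack([x] * 4)
    rec = SignalRecord(data, fs=512.0, channel_names=["CZ", "O1", "OZ", "O2"])
    out = preprocess_record(rec, out_fs=128.0)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-10)


def test_rereferencing_idempotent():
    """After one pass the O-channel average is zero, so subtracting it
    again changes nothing."""
    rng = np.random.default_rng(0)
    data = rng.normal(size=(4, 4096))
    rec = SignalRecord(data, fs=512.0, channel_names=["CZ", "O1", "OZ", "O2"])
    once = preprocess_record(rec, out_fs=128.0)
    ref = np.mean([once.channel(c) for c in REFERENCE_CHANNELS], axis=0)
    np.testing.assert_allclose(ref, 0.0, atol=1e-9)
    np.testing.assert_allclose(once.data - ref[None, :], once.data, atol=1e-9)


def test_chain_commutes_with_gain():
    rng = np.random.default_rng(1)
    data = rng.normal(size=(4, 4096))
    mk = lambda d: SignalRecord(d, fs=512.0,
                                channel_names=["CZ", "O1", "OZ", "O2"])
    a = preprocess_record(mk(data), out_fs=128.0)
    b = preprocess_record(mk(3.0 * data), out_fs=128.0)
    np.testing.assert_allclose(b.data, 3.0 * a.data, rtol=1e-9, atol=1e-9)


def test_missing_reference_channel_named():
    rec = SignalRecord(np.zeros((2, 4096)), fs=512.0,
                       channel_names=["CZ", "O1"])
    with pytest.raises(ValueError, match="OZ"):
        preprocess_record(rec)


def test_epochs_are_128_samples(p300_record):
    out = preprocess_record(p300_record)
    assert out.fs == 128.0
    epochs = epoch_stimulus_locked(out, duration=1.0)
    assert set(epochs) == set(MONTAGE_32)
    for pm in epochs.values():
        assert pm.n_features == 128
    labels = epochs["PZ"].labels
    assert set(labels) <= {"target", "nontarget"}


def test_epoch_count_and_order(p300_record):
    out = preprocess_record(p300_record)
    epochs = epoch_stimulus_locked(out, duration=1.0)
    # every event leaves room for a 1 s epoch by construction
    assert epochs["CZ"].n_patterns == len(p300_record.events)
    assert list(epochs["CZ"].labels) == [c for _, c in out.events]


def test_epoch_degenerate_duration(p300_record):
    out = preprocess_record(p300_record)
    with pytest.raises(ValueError, match="positive"):
        epoch_stimulus_locked(out, duration=0.0)


def test_channel_config_presets():
    assert len(ChannelConfig.preset("cfg4")) == 4
    assert len(ChannelConfig.preset("cfg8")) == 8
    assert len(ChannelConfig.preset("cfg23")) == 23
    for name in ("cfg4", "cfg8", "cfg23"):
        cfg = ChannelConfig.preset(name)
        assert not set(cfg.channels) & set(EXCLUDED_CHANNELS)
    with pytest.raises(ValueError, match="reference"):
        ChannelConfig("bad", ("O1", "CZ"))
    with pytest.raises(ValueError, match="montage"):
        ChannelConfig("bad", ("XX",))


def test_concatenation_block_structure(p300_record):
    out = preprocess_record(p300_record)
    epochs = epoch_stimulus_locked(out, duration=1.0)
    cfg8 = ChannelConfig.preset("cfg8")
    trials = select_and_concatenate(epochs, cfg8)
    assert trials.n_features == 8 * 128

    single = select_and_concatenate(epochs, ChannelConfig("one", ("PZ",)))
    np.testing.assert_array_equal(single.X, epochs["PZ"].X)

    permuted = ChannelConfig("perm", cfg8.channels[::-1])
    tp = select_and_concatenate(epochs, permuted)
    np.testing.assert_array_equal(tp.X[:, :128], trials.X[:, -128:])

    with pytest.raises(ValueError, match="absent"):
        select_and_concatenate({"PZ": epochs["PZ"]}, cfg8)
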