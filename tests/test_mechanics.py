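import dataclasses

import numpy as np
import pytest

from perchsense.config import load_config
from perchsense.estimation import xcorr_delay
from perchsense.exceptions import InvalidArgumentError, UnstableSystemWarning
from perchsense.mechanics import (
    MechanicalParams,
    SensorRecording,
    add_sensor_noise,
    parse_trial_label,
    run_trial,
    simulate_chain,
    trial_grid,
    trial_label,
)
from perchsense.protocol import PerturbationProtocol, generate_protocol


def test_zero_protocol_gives_silent_traces():
    proto = generate_protocol(n_moves=5, radius_m=0.01, seed=0)
    proto.platform_pos[:] = 0
    proto.platform_vel[:] = 0
    rec = simulate_chain(proto, MechanicalParams())
    for site in ("foot", "hip", "head"):
        assert np.all(rec.channels(site) == 0)


def test_foot_acceleration_is_second_difference_of_platform():
    proto = generate_protocol(n_moves=5, radius_m=0.01, seed=1)
    rec = simulate_chain(proto, MechanicalParams())
    p = proto.platform_pos
    expected = (p[2:] - 2 * p[1:-1] + p[:-2]) * proto.rate_hz**2
    assert np.allclose(rec.foot[1:-1], expected, rtol=0, atol=1e-12)


def test_rigid_neck_limit_head_matches_hip():
    # the stiffened neck mode (~2.4 kHz) must stay below Nyquist for the
    # discretized chain to resolve it, hence the raised sampling rate
    proto = generate_protocol(n_moves=10, radius_m=0.01, seed=2, rate_hz=10_000.0)
    params = MechanicalParams()
    rigid = dataclasses.replace(params, k_neck=params.k_neck * 1e6, c_neck=params.c_neck * 1e3)
    rec = simulate_chain(proto, rigid)
    start = proto.events[1][0]  # after the first event has settled in
    diff = rec.head[start:] - rec.hip[start:]
    nrmsd = np.sqrt(np.mean(diff**2)) / np.sqrt(np.mean(rec.hip[start:] ** 2))
    assert nrmsd < 0.01


def test_causality_silence_before_first_event():
    base = generate_protocol(n_moves=5, radius_m=0.01, seed=3)
    pad = 500
    proto = PerturbationProtocol(
        rate_hz=base.rate_hz,
        radius_m=base.radius_m,
        n_moves=base.n_moves,
        events=[(s + pad, d) for s, d in base.events],
        platform_pos=np.vstack([np.zeros((pad, 3)), base.platform_pos]),
        platform_vel=np.vstack([np.zeros((pad, 3)), base.platform_vel]),
    )
    rec = simulate_chain(proto, MechanicalParams())
    first = proto.events[0][0]
    assert np.all(rec.hip[:first] == 0)
    assert np.all(rec.head[:first] == 0)


def test_linearity_radius_doubling_doubles_traces():
    p1 = generate_protocol(n_moves=8, radius_m=0.005, seed=4)
    p2 = generate_protocol(n_moves=8, radius_m=0.010, seed=4)
    params = MechanicalParams()
    r1, r2 = simulate_chain(p1, params), simulate_chain(p2, params)
    for site in ("foot", "hip", "head"):
        a, b = r1.channels(site), r2.channels(site)
        assert np.allclose(2.0 * a, b, rtol=1e-9, atol=1e-12 * np.abs(b).max())


def test_zero_damping_flags_unstable():
    proto = generate_protocol(n_moves=2, radius_m=0.01, seed=5)
    params = MechanicalParams(c_leg=[0, 0, 0], c_neck=0.0)
    with pytest.warns(UnstableSystemWarning):
        rec = simulate_chain(proto, params)
    assert rec.meta["unstable"]


def test_parameter_validation():
    with pytest.raises(InvalidArgumentError):
        MechanicalParams(m_body=0)
    with pytest.raises(InvalidArgumentError):
        MechanicalParams(k_neck=-1)
    with pytest.raises(InvalidArgumentError):
        MechanicalParams(c_neck=-0.1)


def test_high_preset_is_stiffer_than_low():
    low = MechanicalParams.from_config(neck_preset="low")
    high = MechanicalParams.from_config(neck_preset="high")
    assert high.k_neck > low.k_neck


class TestSensorNoise:
    def _zero_recording(self, n=12_000, rate=1000.0):
        z = np.zeros((n, 3))
        return SensorRecording(rate_hz=rate, t=np.arange(n) / rate, foot=z, hip=z.copy(), head=z.copy())

    def test_zero_sd_is_identity(self, recording):
        out = add_sensor_noise(recording, 0.0, seed=1)
        assert np.array_equal(out.hip, recording.hip)

    def test_noise_standard_deviation_matches(self):
        out = add_sensor_noise(self._zero_recording(), 0.05, seed=2)
        for site in ("foot", "hip", "head"):
            sd = out.channels(site).std(axis=0)
            assert np.all(np.abs(sd - 0.05) < 0.03 * 0.05)

    def test_seeded_determinism(self):
        rec = self._zero_recording(n=1000)
        a = add_sensor_noise(rec, 0.1, seed=3)
        b = add_sensor_noise(rec, 0.1, seed=3)
        assert np.array_equal(a.head, b.head)

    def test_negative_sd_rejected(self, recording):
        with pytest.raises(InvalidArgumentError):
            add_sensor_noise(recording, -0.01)

    def test_noiseless_provenance_kept(self, recording):
        assert "noiseless" in recording.meta
        assert recording.meta["noiseless"]["hip"].shape == recording.hip.shape


def test_serial_propagation_and_neck_effect(cfg):
    """Hip leads head on every axis, and a stiffer neck does not lengthen
    the foot-to-head delay (medians over 20 seeds)."""
    hip_d = {ax: [] for ax in range(3)}
    head_d = {"low": [], "high": []}
    for seed in range(20):
        recs = {
            neck: run_trial(radius_m=0.01, neck_preset=neck, n_moves=40, seed=seed, config=cfg)
            for neck in ("low", "high")
        }
        for ax in range(3):
            rec = recs["low"]
            dh = xcorr_delay(rec.foot[:, ax], rec.hip[:, ax], rec.rate_hz).delay_s
            dd = xcorr_delay(rec.foot[:, ax], rec.head[:, ax], rec.rate_hz).delay_s
            hip_d[ax].append(dd - dh)
        for neck in ("low", "high"):
            rec = recs[neck]
            head_d[neck].append(
                np.median(
                    [
                        xcorr_delay(rec.foot[:, ax], rec.head[:, ax], rec.rate_hz).delay_s
                        for ax in range(3)
                    ]
                )
            )
    for ax in range(3):
        assert np.median(hip_d[ax]) > 0  # foot->hip < foot->head on each axis
    assert np.median(head_d["high"]) <= np.median(head_d["low"])


def test_trial_labels_roundtrip():
    assert trial_label("high", 0.020) == "Trial_HS_20"
    assert parse_trial_label("Trial_LS_2") == ("low", 0.002)
    with pytest.raises(InvalidArgumentError):
        parse_trial_label("Trial_XX_2")


def test_run_trial_determinism_and_grid(cfg):
    a = run_trial("Trial_LS_2", n_moves=10, seed=11, config=cfg)
    b = run_trial("Trial_LS_2", n_moves=10, seed=11, config=cfg)
    assert np.array_equal(a.hip, b.hip)
    assert a.meta["trial_label"] == "Trial_LS_2"
    with pytest.raises(InvalidArgumentError):
        run_trial(radius_m=0.01, neck_preset="medium", n_moves=5, config=cfg)
    grid = trial_grid(master_seed=0, config=cfg, n_moves=5)
    assert len(grid) == 8
    assert set(grid) == {
        f"Trial_{code}_{mm}" for code in ("LS", "HS") for mm in (2, 5, 10, 20)
    }
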