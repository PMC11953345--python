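"""CSD estimation, DICS/LCMV beamforming, FIR filtering, ROI averaging."""

import numpy as np
import pytest

from thetadircomm.beamforming import (CrossSpectralDensity, SourcePowerMap,
                                      VirtualSeries, apply_filter_power,
                                      bandpass_fir, common_filter,
                                      compute_csd, dics_power,
                                      design_bandpass_fir,
                                      lcmv_virtual_series, pool_csd,
                                      roi_average)
from thetadircomm.synthetic import (ToyHeadModel, TrialSet,
                                    generate_trial_dataset)


def noise_trials(n_trials=40, n_channels=8, fs=128.0, n_times=512, seed=0,
                 data=None):
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_trials, n_channels, n_times))
    n = data.shape[0]
    return TrialSet(data, fs, n_times // 2,
                    np.array(["NOGO"] * n),
                    np.array(["compatible", "incompatible"] * n)[:n])


class TestComputeCsd:
    def test_identical_channels_rank_one(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((30, 1, 512))
        data = np.repeat(base, 2, axis=1)
        csd = compute_csd(noise_trials(data=data), band=(4, 7))
        ev = np.linalg.eigvalsh(csd.matrix)
        assert ev[0] < 1e-8 * ev[-1]

    def test_independent_noise_small_off_diagonal(self):
        csd = compute_csd(noise_trials(n_trials=400, seed=2), band=(4, 7),
                          window=(-1.5, 1.5))
        C = np.abs(csd.matrix)
        off = C[~np.eye(C.shape[0], dtype=bool)]
        assert off.max() < 0.1 * np.diag(C).min()

    def test_single_source_rank_one_subspace(self, head):
        ts = generate_trial_dataset(head, [14], n_trials=40, noise_sd=0.0,
                                    seed=3, condition_effects={})
        csd = compute_csd(ts, band=(4, 7))
        _, vecs = np.linalg.eigh(np.real(csd.matrix))
        principal = vecs[:, -1]
        a = head.leadfield[:, 14]
        cos = abs(principal @ a) / np.linalg.norm(a)
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5

    def test_window_shorter_than_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            compute_csd(noise_trials(), band=(4, 7), window=(0.3, 0.4))


def orthonormal_head(n=6):
    lf = np.eye(n)
    pos = np.arange(n * 3, dtype=float).reshape(n, 3)
    coords = np.stack([np.arange(n)] * 3, axis=1)
    return ToyHeadModel(pos, pos.copy(), coords, lf, 1.0)


class TestDics:
    def test_identity_csd_orthonormal_leadfield_equal_power(self):
        head = orthonormal_head()
        csd = CrossSpectralDensity(np.eye(6, dtype=complex), (4, 7),
                                   (0.3, 0.6), 10)
        pmap, _ = dics_power(csd, head, lam_frac=0.0, normalize=False)
        assert np.allclose(pmap.power, pmap.power[0])

    def test_localizes_single_source(self, head):
        hits = 0
        rng = np.random.default_rng(4)
        for _ in range(10):
            v = int(rng.integers(0, head.n_voxels))
            ts = generate_trial_dataset(head, [v], n_trials=30,
                                        noise_sd=0.05, seed=int(v),
                                        condition_effects={})
            pmap, _ = dics_power(compute_csd(ts), head)
            hits += int(np.argmax(pmap.power) == v)
        assert hits >= 9

    def test_unit_gain_and_inverse_square_scaling(self, head):
        rng = np.random.default_rng(5)
        C = rng.standard_normal((head.n_sensors, head.n_sensors))
        C = C @ C.T / head.n_sensors
        csd = CrossSpectralDensity(C.astype(complex), (4, 7), (0.3, 0.6), 10)
        pmap, filt = dics_power(csd, head, normalize=False)
        gains = np.einsum("vs,sv->v", filt.weights, head.leadfield)
        assert np.allclose(gains, 1.0, atol=1e-8)
        # scaling a leadfield column by c scales unnormalized power by 1/c^2
        import dataclasses
        lf2 = head.leadfield.copy()
        lf2[:, 10] *= 2.0
        head2 = dataclasses.replace(head, leadfield=lf2)
        pmap2, _ = dics_power(csd, head2, normalize=False)
        assert pmap2.power[10] == pytest.approx(pmap.power[10] / 4, rel=1e-8)

    def test_power_nonnegative_for_random_psd_csd(self, head):
        rng = np.random.default_rng(6)
        for _ in range(100):
            A = rng.standard_normal((head.n_sensors, head.n_sensors)) \
                + 1j * rng.standard_normal((head.n_sensors, head.n_sensors))
            C = A @ A.conj().T / head.n_sensors
            csd = CrossSpectralDensity(C, (4, 7), (0.3, 0.6), 10)
            pmap, _ = dics_power(csd, head)
            assert np.all(pmap.power >= 0)

    def test_noise_normalization_keeps_argmax_under_white_noise(self, head):
        ts = generate_trial_dataset(head, [25], n_trials=60, noise_sd=0.2,
                                    seed=7, condition_effects={})
        csd = compute_csd(ts)
        raw, _ = dics_power(csd, head, normalize=False)
        norm, _ = dics_power(csd, head, normalize=True)
        assert np.argmax(norm.power) == np.argmax(raw.power) == 25


class TestCommonFilter:
    def test_identical_conditions_identical_maps(self, head):
        ts = generate_trial_dataset(head, [12], n_trials=30, noise_sd=0.2,
                                    seed=8, condition_effects={})
        csd = compute_csd(ts)
        filt = common_filter(pool_csd(csd, csd), head)
        m1 = apply_filter_power(filt, csd)
        m2 = apply_filter_power(filt, csd)
        assert np.array_equal(m1.power, m2.power)
        gains = np.einsum("vs,sv->v", filt.weights, head.leadfield)
        assert np.allclose(gains, 1.0, atol=1e-8)

    def test_pooled_filter_same_argmax_as_own_filter(self, head):
        a = generate_trial_dataset(head, [30], n_trials=30, noise_sd=0.1,
                                   seed=9, condition_effects={"GO": 1.5})
        b = generate_trial_dataset(head, [30], n_trials=30, noise_sd=0.1,
                                   seed=10, condition_effects={})
        csd_a, csd_b = compute_csd(a), compute_csd(b)
        own, _ = dics_power(csd_a, head)
        pooled = apply_filter_power(common_filter(pool_csd(csd_a, csd_b),
                                                  head), csd_a)
        assert np.argmax(own.power) == np.argmax(pooled.power)


class TestLcmv:
    def test_zero_data_zero_series(self, head):
        ts = noise_trials(n_channels=head.n_sensors)
        ts.data[:] = 0.0
        virt, _ = lcmv_virtual_series(ts, head, [3, 4], lam_frac=0.05,
                                      cov_window=(-1.0, 1.0))
        assert np.all(virt.data == 0)

    def test_reconstructs_noiseless_source(self, head):
        v = 21
        ts = generate_trial_dataset(head, [v], n_trials=6, noise_sd=0.0,
                                    seed=11, condition_effects={})
        virt, _ = lcmv_virtual_series(ts, head, [v], lam_frac=1e-8)
        sel = (ts.times >= 0.35) & (ts.times <= 0.55)
        source = head.leadfield[:, v] @ ts.data[0]
        c = np.corrcoef(virt.data[0, 0, sel], source[sel])[0, 1]
        assert abs(c) > 0.99

    def test_deterministic(self, head):
        ts = noise_trials(n_channels=head.n_sensors, seed=12)
        a, _ = lcmv_virtual_series(ts, head, [0, 5])
        b, _ = lcmv_virtual_series(ts, head, [0, 5])
        assert np.array_equal(a.data, b.data)


class TestBandpassFir:
    def test_passband_and_stopband(self):
        fs = 128.0
        t = np.arange(4096) / fs
        mid = slice(1000, 3000)
        y5 = bandpass_fir(np.sin(2 * np.pi * 5 * t), fs=fs)
        assert y5[mid].std() * np.sqrt(2) == pytest.approx(1.0, rel=0.05)
        y20 = bandpass_fir(np.sin(2 * np.pi * 20 * t), fs=fs)
        atten = 20 * np.log10(y20[mid].std() * np.sqrt(2))
        assert atten <= -40
        ydc = bandpass_fir(np.ones(4096), fs=fs)
        assert np.max(np.abs(ydc[mid])) < 1e-3

    def test_designed_response_ripple_and_attenuation(self):
        fs = 128.0
        taps = design_bandpass_fir((4, 7), fs, order=256)
        from scipy import signal
        w, h = signal.freqz(taps, worN=4096, fs=fs)
        passband = (w >= 4.5) & (w <= 6.5)
        stop = (w <= 2.0) | (w >= 12.0)
        ripple_db = 20 * np.log10(np.abs(h[passband]))
        assert ripple_db.max() - ripple_db.min() < 1.0
        assert 20 * np.log10(np.abs(h[stop]).max()) <= -40

    def test_validation(self):
        with pytest.raises(ValueError, match="even"):
            design_bandpass_fir(order=33)
        with pytest.raises(ValueError, match="order"):
            design_bandpass_fir((0.5, 7), fs=128, order=64)


class TestRoiAverage:
    def make_virt(self, arrays):
        data = np.stack(arrays, axis=0)[None, :, :]
        return VirtualSeries(data, 128.0, 0, names=list(range(len(arrays))))

    def test_single_voxel_identity(self):
        s = np.sin(np.arange(100) / 7)
        virt = self.make_virt([s])
        out = roi_average(virt, {"AC1": [0]})
        assert np.array_equal(out.data[0, 0], s)

    def test_opposite_series_cancel(self):
        s = np.random.default_rng(0).normal(size=100)
        out = roi_average(self.make_virt([s, -s]), {"AC1": [0, 1]})
        assert np.allclose(out.data, 0.0)

    def test_arithmetic_mean(self):
        out = roi_average(self.make_virt([np.full(10, 1.0), np.full(10, 2.0),
                                          np.full(10, 6.0)]),
                          {"AC1": [0, 1, 2]})
        assert np.allclose(out.data, 3.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_average(self.make_virt([np.zeros(10)]), {"AC1": []})
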