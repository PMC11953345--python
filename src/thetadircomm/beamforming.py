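"""Frequency-domain (DICS) and time-domain (LCMV) beamforming on a toy grid.

DICS maps band-limited source power from a sensor cross-spectral density
(CSD); LCMV extracts per-voxel "virtual channel" time series from the
sensor covariance. Both use the unit-gain minimum-variance filter

    w_v = (l_v' C_r^-1 l_v)^-1 l_v' C_r^-1,   C_r = C + lambda I,

with lambda = lambda_frac * mean(diag C) (default 5%), and DICS power is
noise-normalised by a spatially inhomogeneous estimate built from the
smallest CSD eigenvalue: power_v / (s_min * w_v w_v').
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal.windows import hann

from .synthetic import ToyHeadModel, TrialSet


@dataclass
class CrossSpectralDensity:
    """Trial-averaged sensor cross-spectrum accumulated over a band."""

    matrix: np.ndarray
    band: tuple[float, float]
    window: tuple[float, float]
    n_trials: int
    taper: str = "hanning"

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, complex)
        if np.max(np.abs(M - M.conj().T)) > 1e-10 * max(np.abs(M).max(), 1e-30):
            raise ValueError("CSD must be Hermitian")
        self.matrix = (M + M.conj().T) / 2

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    def smallest_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


@dataclass
class SpatialFilterSet:
    """Beamformer weights, one row per voxel."""

    weights: np.ndarray  # (n_voxels, n_sensors)
    regularization: float
    mode: str  # "dics" | "lcmv"
    common_filter: bool = False


@dataclass
class SourcePowerMap:
    """Per-voxel band power on the head-model grid (>= 0)."""

    power: np.ndarray
    normalized: bool
    noise_estimate: float


@dataclass
class VirtualSeries:
    """Per-voxel (or per-ROI) source time series per trial.

    ``data`` has shape (n_trials, n_series, n_times); ``names`` identifies
    each series (voxel index or ROI id).
    """

    data: np.ndarray
    sampling_rate: float
    time_zero: int
    names: list
    band: tuple[float, float] | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.data.shape[2]) - self.time_zero) \
            / self.sampling_rate


def compute_csd(trials: TrialSet, band=(4.0, 7.0), window=(0.3, 0.6),
                taper: str = "hanning") -> CrossSpectralDensity:
    """Hanning-tapered cross-spectral density over a band and time window.

    The window (seconds relative to stimulus onset) must contain at least
    one full cycle of the band's low edge. Cross-spectra are averaged over
    the band's DFT bins and over trials, then Hermitian-symmetrised.
    """
    if taper != "hanning":
        raise ValueError("only the hanning taper is supported")
    fs = trials.sampling_rate
    if band[1] >= fs / 2:
        raise ValueError("band extends to/above Nyquist")
    dur = window[1] - window[0]
    if dur < 1.0 / band[0]:
        raise ValueError(
            f"window of {dur:.3f}s is shorter than one cycle of "
            f"{band[0]} Hz")
    times = trials.times
    sel = (times >= window[0]) & (times < window[1])
    if not sel.any():
        raise ValueError("window lies outside the epoch")
    seg = trials.data[:, :, sel]
    nwin = seg.shape[2]
    win = hann(nwin, sym=False)
    freqs = np.fft.rfftfreq(nwin, 1 / fs)
    bins = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if len(bins) == 0:
        bins = np.array([np.argmin(np.abs(freqs - np.mean(band)))])
    X = np.fft.rfft(seg * win, axis=2)[:, :, bins]  # (trial, chan, bin)
    X *= np.sqrt(2.0 / (fs * np.sum(win ** 2)))  # density-style scaling
    C = np.einsum("tcb,tdb->cd", X, X.conj()) / (trials.n_trials * len(bins))
    return CrossSpectralDensity((C + C.conj().T) / 2, tuple(band),
                                tuple(window), trials.n_trials, taper)


def _mv_filters(C: np.ndarray, leadfield: np.ndarray, lam_frac: float):
    """Unit-gain minimum-variance filter rows for every leadfield column."""
    lam = lam_frac * np.mean(np.diag(C))
    if lam <= 0:  # degenerate (e.g. all-zero) covariance: unit-gain filters
        lam = 1e-12 # reduce to w = l / (l'l)
    Cr = C + lam * np.eye(C.shape[0])
    try:
        Cinv = np.linalg.inv(Cr)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; increase lambda_frac"
        ) from e
    G = Cinv @ leadfield                      # (sensor, voxel)
    denom = np.einsum("sv,sv->v", leadfield, G)
    if np.any(np.abs(denom) < 1e-300):
        raise np.linalg.LinAlgError(
            "degenerate leadfield/covariance pair; increase lambda_frac")
    return (G / denom).T                      # (voxel, sensor)


def dics_power(csd: CrossSpectralDensity, head: ToyHeadModel,
               lam_frac: float = 0.05, normalize: bool = True
               ) -> tuple[SourcePowerMap, SpatialFilterSet]:
    """DICS source power map from a band CSD.

    Filters are computed on the real part of the (regularised) CSD;
    power_v = w_v Re(CSD) w_v'. With ``normalize``, power is divided by the
    projected noise s_min * ||w_v||^2 where s_min is the smallest eigenvalue
    of the CSD — the centre-of-head noise-bias correction.
    """
    if csd.n_sensors != head.n_sensors:
        raise ValueError("CSD dimension must equal the sensor count")
    C = np.real(csd.matrix)
    W = _mv_filters(C, head.leadfield, lam_frac)
    power = np.einsum("vs,st,vt->v", W, C, W)
    power = np.maximum(power, 0.0)
    s_min = max(csd.smallest_eigenvalue(), 0.0)
    if normalize:
        noise = np.maximum(s_min, 1e-300) * np.einsum("vs,vs->v", W, W)
        power = power / noise
    return (SourcePowerMap(power, normalize, s_min),
            SpatialFilterSet(W, lam_frac, "dics"))


def common_filter(csd_pooled: CrossSpectralDensity, head: ToyHeadModel,
                  lam_frac: float = 0.05) -> SpatialFilterSet:
    """DICS filter from a condition-pooled CSD, to be applied per condition."""
    if csd_pooled.n_sensors != head.n_sensors:
        raise ValueError("CSD dimension must equal the sensor count")
    W = _mv_filters(np.real(csd_pooled.matrix), head.leadfield, lam_frac)
    return SpatialFilterSet(W, lam_frac, "dics", common_filter=True)


def pool_csd(*csds: CrossSpectralDensity) -> CrossSpectralDensity:
    """Trial-weighted average of per-condition CSDs (same band/window)."""
    n = sum(c.n_trials for c in csds)
    M = sum(c.matrix * c.n_trials for c in csds) / n
    return CrossSpectralDensity(M, csds[0].band, csds[0].window, n,
                                csds[0].taper)


def apply_filter_power(filters: SpatialFilterSet,
                       csd: CrossSpectralDensity,
                       normalize: bool = True) -> SourcePowerMap:
    """Apply an existing (e.g. common) filter to a per-condition CSD."""
    C = np.real(csd.matrix)
    W = filters.weights
    power = np.maximum(np.einsum("vs,st,vt->v", W, C, W), 0.0)
    s_min = max(csd.smallest_eigenvalue(), 0.0)
    if normalize:
        power = power / (np.maximum(s_min, 1e-300)
                         * np.einsum("vs,vs->v", W, W))
    return SourcePowerMap(power, normalize, s_min)


def lcmv_virtual_series(trials: TrialSet, head: ToyHeadModel, voxels,
                        lam_frac: float = 0.05,
                        cov_window: tuple[float, float] = (0.3, 0.6)
                        ) -> tuple[VirtualSeries, SpatialFilterSet]:
    """LCMV virtual-channel time series for the requested voxels.

    The sensor covariance is estimated over ``cov_window`` (seconds,
    stimulus-locked) pooled across trials; the unit-gain filter is applied
    to the full epoch, yielding one series per voxel per trial.
    """
    voxels = list(voxels)
    if not voxels:
        raise ValueError("voxel list must be nonempty")
    times = trials.times
    sel = (times >= cov_window[0]) & (times < cov_window[1])
    if not sel.any():
        raise ValueError("covariance window lies outside the epoch")
    seg = trials.data[:, :, sel]
    X = seg - seg.mean(axis=2, keepdims=True)
    C = np.einsum("tcn,tdn->cd", X, X) / max(X.shape[0] * X.shape[2] - 1, 1)
    W = _mv_filters(C, head.leadfield[:, voxels], lam_frac)
    virt = np.einsum("vs,tsn->tvn", W, trials.data)
    return (VirtualSeries(virt, trials.sampling_rate, trials.time_zero,
                          names=voxels),
            SpatialFilterSet(W, lam_frac, "lcmv"))


def design_bandpass_fir(band=(4.0, 7.0), fs: float = 128.0,
                        order: int = 256, window: str = "hamming"
                        ) -> np.ndarray:
    """Windowed-sinc FIR band-pass coefficients (order must be even)."""
    if order % 2 != 0 or order < 4:
        raise ValueError("order must be even and >= 4")
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    # hamming windowed-sinc transition width ~ 3.3 / order cycles/sample
    trans = 3.3 / order * fs
    if band[0] - trans / 2 <= 0 or band[1] + trans / 2 >= fs / 2:
        raise ValueError(
            f"band edges within half a transition width ({trans / 2:.2f} Hz) "
            f"of 0/Nyquist; increase the order")
    return signal.firwin(order + 1, band, pass_zero=False, window=window,
                         fs=fs)


def bandpass_fir(series: np.ndarray, band=(4.0, 7.0), fs: float = 128.0,
                 order: int = 256, window: str = "hamming") -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    The windowed-sinc FIR is applied forward-backward (filtfilt), which
    doubles the attenuation and leaves no group delay — time alignment of
    post-stimulus windows is preserved.
    """
    taps = design_bandpass_fir(band, fs, order, window)
    x = np.asarray(series, float)
    if x.shape[-1] <= 3 * (order + 1):
        raise ValueError("series too short for the filter order")
    return signal.filtfilt(taps, [1.0], x, axis=-1)


def bandpass_virtual(virt: VirtualSeries, band=(4.0, 7.0),
                     order: int = 256) -> VirtualSeries:
    out = bandpass_fir(virt.data, band, virt.sampling_rate, order)
    return VirtualSeries(out, virt.sampling_rate, virt.time_zero,
                         list(virt.names), tuple(band))


def roi_average(virt: VirtualSeries, roi_voxels: dict) -> VirtualSeries:
    """Average virtual series across each ROI's member voxels.

    ``roi_voxels`` maps ROI name -> list of voxel ids, which must all be
    present in ``virt.names``. Returns one series per ROI (per trial).
    """
    index = {name: i for i, name in enumerate(virt.names)}
    out = []
    names = []
    for roi, members in roi_voxels.items():
        members = list(members)
        if not members:
            raise ValueError(f"ROI {roi!r} is empty")
        missing = [v for v in members if v not in index]
        if missing:
            raise ValueError(f"ROI {roi!r} references voxels not present in "
                             f"the virtual series: {missing}")
        rows = [index[v] for v in members]
        out.append(virt.data[:, rows, :].mean(axis=1))
        names.append(roi)
    return VirtualSeries(np.stack(out, axis=1), virt.sampling_rate,
                         virt.time_zero, names, virt.band)
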