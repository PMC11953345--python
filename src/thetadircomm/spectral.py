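"""Time-frequency decomposition and the sensor-level cluster permutation test.

The permutation test is the standard nonparametric contrast for
multichannel time-frequency data: a paired t at every (channel, frequency,
time) point, clustering of suprathreshold points under a combined
channel-adjacency x (frequency, time) 4-connectivity neighbourhood, the
max summed-t cluster statistic, and a subject-level sign-flip null. An
exhaustive enumeration mode covers all 2^n sign patterns for small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats
from scipy.signal.windows import hann

from .synthetic import TrialSet


@dataclass
class TFRepresentation:
    """Per-trial short-time tapered Fourier power.

    ``power`` has shape (n_trials, n_channels, n_freqs, n_times) in squared
    signal units; ``freqs`` (Hz) and ``times`` (s, 0 = stimulus onset) are
    strictly increasing grids.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    taper: str = "hanning"

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        for g in (self.freqs, self.times):
            if np.any(np.diff(g) <= 0):
                raise ValueError("frequency/time grids must be increasing")

    def average(self) -> np.ndarray:
        """Trial-average power (n_channels, n_freqs, n_times)."""
        return self.power.mean(axis=0)

    def band_window_mask(self, band=None, window=None):
        fmask = np.ones(len(self.freqs), bool) if band is None else \
            (self.freqs >= band[0]) & (self.freqs <= band[1])
        tmask = np.ones(len(self.times), bool) if window is None else \
            (self.times >= window[0]) & (self.times <= window[1])
        return fmask, tmask


def tf_decompose(trials: TrialSet, freqs, window_len: float = 0.5,
                 step: float = 0.05, taper: str = "hanning") -> TFRepresentation:
    """Short-time Hanning-tapered Fourier power per trial.

    ``freqs`` are mapped to the nearest DFT bins of the ``window_len``-second
    analysis window, which must span at least two cycles of the lowest
    requested frequency. Window centres advance by ``step`` seconds.
    """
    if taper != "hanning":
        raise ValueError("only the hanning taper is supported")
    freqs = np.asarray(freqs, float)
    fs = trials.sampling_rate
    if np.any(freqs >= fs / 2):
        raise ValueError("requested frequencies at/above Nyquist")
    if window_len < 2.0 / freqs.min():
        raise ValueError(
            f"window_len {window_len}s is under two cycles of "
            f"{freqs.min()} Hz")
    nwin = int(round(window_len * fs))
    hop = max(1, int(round(step * fs)))
    win = hann(nwin, sym=False)
    fft_freqs = np.fft.rfftfreq(nwin, 1 / fs)
    bins = np.unique([np.argmin(np.abs(fft_freqs - f)) for f in freqs])
    centers = np.arange(nwin // 2, trials.n_times - (nwin - nwin // 2) + 1, hop)
    segs = np.stack([trials.data[:, :, c - nwin // 2:
                                 c - nwin // 2 + nwin] for c in centers],
                    axis=2)  # (trial, chan, time, nwin)
    spec = np.fft.rfft(segs * win, axis=3)[..., bins]
    # amplitude-consistent normalisation: a unit sinusoid at a bin centre
    # gives power ~0.25 (|A|^2/4) irrespective of window length
    scale = 2.0 / np.sum(win)
    power = np.abs(spec * scale) ** 2 / 4.0
    power = np.moveaxis(power, 3, 2)  # (trial, chan, freq, time)
    times = (centers - trials.time_zero) / fs
    return TFRepresentation(power, fft_freqs[bins], times, taper)


def build_adjacency(sensor_positions, factor: float = 1.3) -> np.ndarray:
    """Channel adjacency by distance threshold on sensor positions.

    Two channels are neighbours when their distance is below ``factor``
    times the median nearest-neighbour distance. Symmetric, irreflexive.
    """
    pos = np.asarray(sensor_positions, float)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    thresh = factor * np.median(d.min(axis=1))
    adj = d <= thresh
    np.fill_diagonal(adj, False)
    if np.any(adj.sum(axis=1) == 0):
        import warnings
        warnings.warn("some channels have no neighbours under the distance "
                      "threshold", stacklevel=2)
    return adj


def validate_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj)):
        raise ValueError("adjacency must be irreflexive")
    return adj


@dataclass
class ClusterResult:
    """Clusters of (channel, freq-index, time-index) points with their
    summed-t statistics and Monte-Carlo p-values."""

    clusters: list[list[tuple[int, int, int]]]
    stats: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    t_map: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def significant(self, alpha: float = 0.05):
        return [c for c, p in zip(self.clusters, self.p_values) if p < alpha]


def _find_clusters(mask: np.ndarray, signs: np.ndarray, adj: np.ndarray):
    """Connected components of suprathreshold points sharing a t sign.

    ``mask``/``signs`` are (n_chan, n_freq, n_time). Neighbourhood: channel
    adjacency at the same (f, t) plus 4-connectivity over (f, t) within a
    channel.
    """
    n_chan, n_freq, n_time = mask.shape
    labels = -np.ones(mask.shape, dtype=int)
    clusters = []
    pts = np.argwhere(mask)
    neighbors = [np.flatnonzero(adj[c]) for c in range(n_chan)]
    for c0, f0, t0 in pts:
        if labels[c0, f0, t0] >= 0:
            continue
        cid = len(clusters)
        stack = [(c0, f0, t0)]
        labels[c0, f0, t0] = cid
        members = []
        s0 = signs[c0, f0, t0]
        while stack:
            c, f, t = stack.pop()
            members.append((c, f, t))
            cand = [(c, f - 1, t), (c, f + 1, t), (c, f, t - 1), (c, f, t + 1)]
            cand += [(cn, f, t) for cn in neighbors[c]]
            for cc, ff, tt in cand:
                if 0 <= ff < n_freq and 0 <= tt < n_time and \
                        mask[cc, ff, tt] and labels[cc, ff, tt] < 0 and \
                        signs[cc, ff, tt] == s0:
                    labels[cc, ff, tt] = cid
                    stack.append((cc, ff, tt))
        clusters.append(members)
    return clusters


def _max_cluster_stat(t_map, thresh, adj) -> float:
    mask = np.abs(t_map) > thresh
    if not mask.any():
        return 0.0
    clusters = _find_clusters(mask, np.sign(t_map), adj)
    return max(abs(sum(t_map[c, f, t] for c, f, t in cl)) for cl in clusters)


def cluster_permutation_test(tfr_a, tfr_b, adjacency, band=None, window=None,
                             n_perm: int | str = 1000,
                             cluster_alpha: float = 0.05,
                             seed: int = 0) -> ClusterResult:
    """Paired cluster-based permutation test between two conditions.

    ``tfr_a``/``tfr_b`` are per-subject (or per-trial-average) power arrays
    of shape (n_subjects, n_channels, n_freqs, n_times) — either
    :class:`TFRepresentation` objects on a common grid or bare arrays, paired
    along the first axis. A paired t is computed at every point inside
    ``band`` x ``window``; points with |t| above the two-sided t critical
    value at ``cluster_alpha`` are clustered (same-sign, channel adjacency +
    (f,t) 4-connectivity); each cluster's statistic is its summed t. The
    null is the max |cluster stat| over subject-level sign flips:
    ``n_perm`` random flips (p = (b+1)/(n_perm+1)) or, with
    ``n_perm="all"``, exhaustive enumeration of all 2^n sign patterns
    (p = exact rank including the identity).

    An empty cluster list (no suprathreshold points) is a valid outcome.
    """
    if isinstance(tfr_a, TFRepresentation):
        fmask, tmask = tfr_a.band_window_mask(band, window)
        freqs, times = tfr_a.freqs[fmask], tfr_a.times[tmask]
        A = tfr_a.power[:, :, fmask][:, :, :, tmask]
        B = tfr_b.power[:, :, fmask][:, :, :, tmask]
    else:
        A, B = np.asarray(tfr_a, float), np.asarray(tfr_b, float)
        freqs = np.arange(A.shape[2], dtype=float)
        times = np.arange(A.shape[3], dtype=float)
    if A.shape != B.shape:
        raise ValueError("paired design requires identically shaped inputs")
    n = A.shape[0]
    D = A - B  # (subjects, chan, freq, time)
    thresh = stats.t.ppf(1 - cluster_alpha / 2, n - 1)
    adj = validate_adjacency(adjacency)

    sum_sq = np.sum(D ** 2, axis=0)  # invariant under sign flips

    def t_of(flips):
        m = np.tensordot(flips, D, axes=(0, 0)) / n
        var = (sum_sq - n * m ** 2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        return np.nan_to_num(t)

    t_obs = t_of(np.ones(n))
    mask = np.abs(t_obs) > thresh
    if mask.any():
        clusters = _find_clusters(mask, np.sign(t_obs), adj)
        cstats = np.array([sum(t_obs[c, f, t] for c, f, t in cl)
                           for cl in clusters])
    else:
        clusters, cstats = [], np.array([])

    if n_perm == "all":
        null = np.array([_max_cluster_stat(t_of(np.array(fl)), thresh, adj)
                         for fl in product((1.0, -1.0), repeat=n)])
        n_used = len(null)
        p = np.array([np.mean(null >= abs(s) - 1e-12) for s in cstats])
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 (or 'all')")
        rng = np.random.default_rng(seed)
        null = np.array([_max_cluster_stat(
            t_of(rng.choice((1.0, -1.0), size=n)), thresh, adj)
            for _ in range(n_perm)])
        n_used = n_perm
        p = np.array([(np.sum(null >= abs(s) - 1e-12) + 1) / (n_perm + 1)
                      for s in cstats])
    order = np.argsort(p) if len(p) else np.array([], int)
    return ClusterResult([clusters[i] for i in order], cstats[order],
                         p[order], n_used, t_obs, freqs, times)
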