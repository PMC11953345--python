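"""Nonlinear MVAR connectivity with a neural-network estimator.

The generating model for an M-channel series is

    x(n) = f(x_p) + sigma(n),      f = f_lin + f_nonlin,

where x_p = [x_1(n-1), ..., x_M(n-1), ..., x_1(n-p), ..., x_M(n-p)] stacks
the p past samples. The estimator makes the linear/nonlinear split
structural: a linear shortcut W_lin x_p + b houses f_lin, and a single
hidden tanh layer V tanh(U x_p + c) houses f_nonlin. By construction the
prediction is exactly the sum of the two parts.

Directed connectivity is read off the fitted parts:

* linear connectivity  lC[i->j] = sum_k |W_lin[j, (i, lag k)]|
* nonlinear connectivity NC[i->j] = mean over evaluation samples and lags of
  |d f_nonlin_j / d x_i(n-k)| — the average absolute input sensitivity of
  the nonlinear pathway.

Significance is assessed against phase-randomised surrogates (amplitude
spectra preserved exactly, cross-channel temporal structure destroyed),
re-fitting the model identically per surrogate; per-subject values are
normalised to [0, 1] by the maximum over both task conditions per measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(series: np.ndarray, p: int,
                 boundaries=None) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix Z and targets Y for one-step-ahead prediction.

    ``series`` is (M, N). Column order of Z is lag-major: channels at lag 1,
    then lag 2, ... ``boundaries`` optionally lists segment start indices of
    a trial concatenation (0-based, first segment starts at 0); predictor
    windows crossing a segment boundary are excluded, so fitting on a
    concatenation equals fitting on the pooled valid within-trial windows.
    """
    x = np.asarray(series, float)
    M, N = x.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if N <= p:
        raise ValueError("series shorter than the model order")
    segment = np.zeros(N, int)
    if boundaries is not None:
        for b in sorted(boundaries):
            if b > 0:
                segment[b:] += 1
    valid = np.array([segment[n] == segment[n - p] for n in range(p, N)])
    idx = np.arange(p, N)[valid]
    Z = np.concatenate([x[:, idx - k].T for k in range(1, p + 1)], axis=1)
    return Z, x[:, idx].T


def concatenate_trials(data: np.ndarray, times: np.ndarray | None = None,
                       window: tuple[float, float] | None = (0.3, 0.6)
                       ) -> tuple[np.ndarray, list[int]]:
    """Concatenate (n_trials, M, n_times) trial data into one long series.

    If ``window`` (seconds) and ``times`` are given, only samples inside the
    window enter. Returns the (M, total) series and the per-trial segment
    start indices to pass to :func:`build_design`.
    """
    data = np.asarray(data, float)
    if window is not None and times is not None:
        sel = (times >= window[0]) & (times < window[1])
        data = data[:, :, sel]
    n_trials, _, n_times = data.shape
    series = np.concatenate(list(data), axis=1)
    return series, [i * n_times for i in range(n_trials)]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class NmvarModel:
    """Fitted nMVAR model with a structural linear/nonlinear split."""

    n_channels: int
    order: int
    mean_: np.ndarray
    sd_: np.ndarray
    W_lin: np.ndarray  # (M, M*p)
    b: np.ndarray      # (M,)
    U: np.ndarray      # (H, M*p)
    c: np.ndarray      # (H,)
    V: np.ndarray      # (M, H)
    meta: dict = field(default_factory=dict)

    def standardize(self, series: np.ndarray) -> np.ndarray:
        return (np.asarray(series, float) - self.mean_[:, None]) / self.sd_[:, None]

    def linear_part(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.W_lin.T

    def nonlinear_part(self, Z: np.ndarray) -> np.ndarray:
        return np.tanh(Z @ self.U.T + self.c) @ self.V.T

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """One-step prediction (standardized units); exactly the sum of the
        linear part, the nonlinear part, and the bias."""
        return self.linear_part(Z) + self.nonlinear_part(Z) + self.b


def _adam_fit(Z, Y, H, seed, epochs, lr, val_frac, patience, warm_start):
    N, D = Z.shape
    M = Y.shape[1]
    n_train = max(int(round(N * (1 - val_frac))), D + 1)
    Zt, Yt = Z[:n_train], Y[:n_train]
    Zv, Yv = Z[n_train:], Y[n_train:]
    if len(Zv) == 0:
        Zv, Yv = Zt, Yt
    rng = np.random.default_rng(seed)

    if warm_start:  # least-squares VAR solution for the shortcut
        G = Zt.T @ Zt + 1e-8 * len(Zt) * np.eye(D)
        W = np.linalg.solve(G, Zt.T @ Yt).T
    else:
        W = np.zeros((M, D))
    b = np.zeros(M)
    U = rng.normal(0.0, 1.0 / np.sqrt(D), size=(H, D))
    c = rng.normal(0.0, 0.5, size=H)  # offsets break odd symmetry
    # tiny random output weights: near-zero nonlinear pathway at the start,
    # but no point mass at exactly zero in the fitted sensitivities (which
    # would make surrogate percentile thresholds degenerate)
    V = rng.normal(0.0, 1e-2, size=(M, H))

    params = [W, b, U, c, V]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def val_loss(ps):
        W, b, U, c, V = ps
        pred = Zv @ W.T + b + np.tanh(Zv @ U.T + c) @ V.T
        return float(np.mean((pred - Yv) ** 2))

    best = [p.copy() for p in params]
    best_loss = val_loss(params)
    train_loss = np.nan
    since_best = 0
    step = 0
    for epoch in range(epochs):
        W, b, U, c, V = params
        Hpre = Zt @ U.T + c
        Hact = np.tanh(Hpre)
        pred = Zt @ W.T + b + Hact @ V.T
        err = pred - Yt
        train_loss = float(np.mean(err ** 2))
        if not np.isfinite(train_loss):
            raise FloatingPointError(
                "training loss diverged; lower the learning rate")
        E = (2.0 / err.size) * err
        dW = E.T @ Zt
        db = E.sum(axis=0)
        dV = E.T @ Hact
        dH = (E @ V) * (1.0 - Hact ** 2)
        dU = dH.T @ Zt
        dc = dH.sum(axis=0)
        step += 1
        for i, g in enumerate((dW, db, dU, dc, dV)):
            p = (W, b, U, c, V)[i]
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mh = m[i] / (1 - beta1 ** step)
            vh = v[i] / (1 - beta2 ** step)
            p -= lr * mh / (np.sqrt(vh) + eps)
        loss = val_loss(params)
        if loss < best_loss - 1e-12:
            best_loss = loss
            best = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return best, {"epochs_run": epoch + 1, "train_loss": train_loss,
                  "val_loss": best_loss, "n_train": n_train,
                  "n_val": len(Zv)}


def fit_nmvar_ann(series: np.ndarray, p: int, hidden_units: int | None = None,
                  seed: int = 0, epochs: int = 400, lr: float = 0.02,
                  val_frac: float = 0.2, patience: int = 60,
                  boundaries=None, standardize: bool = True,
                  warm_start: bool = True) -> NmvarModel:
    """Fit the nMVAR model by seeded full-batch Adam on one-step MSE.

    Channels are z-scored internally; the linear shortcut is warm-started at
    the least-squares VAR solution and the hidden-layer output weights start
    at zero, so the nonlinear pathway only learns structure the linear part
    leaves in the residual. Training early-stops on a held-out tail split
    (last ``val_frac`` of samples). Same data and seed give identical
    weights.
    """
    x = np.asarray(series, float)
    if x.ndim != 2:
        raise ValueError("series must be (M, N)")
    M, N = x.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if N < 50 * M * p:
        warnings.warn(f"series length {N} below the recommended "
                      f"50*M*p = {50 * M * p}", stacklevel=2)
    mean = x.mean(axis=1) if standardize else np.zeros(M)
    sd = x.std(axis=1) if standardize else np.ones(M)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mean[:, None]) / sd[:, None]
    Z, Y = build_design(xs, p, boundaries)
    H = hidden_units if hidden_units is not None else M * p
    (W, b, U, c, V), meta = _adam_fit(Z, Y, H, seed, epochs, lr,
                                      val_frac, patience, warm_start)
    meta.update(seed=seed, lr=lr, epochs_max=epochs, hidden_units=H)
    return NmvarModel(M, p, mean, sd, W, b, U, c, V, meta)


# ---------------------------------------------------------------------------
# connectivity extraction
# ---------------------------------------------------------------------------

def linear_connectivity(model: NmvarModel) -> np.ndarray:
    """lC[i, j] = sum over lags of |linear shortcut weight| for i -> j."""
    M, p = model.n_channels, model.order
    W = model.W_lin.reshape(M, p, M)  # (target, lag, source)
    return np.abs(W).sum(axis=1).T    # (source, target)


def nonlinear_connectivity(model: NmvarModel, series: np.ndarray,
                           boundaries=None,
                           max_samples: int = 20000) -> np.ndarray:
    """NC[i, j] = mean absolute sensitivity of the nonlinear part of channel
    j to x_i at any lag, evaluated at the observed predictor windows."""
    xs = model.standardize(series)
    Z, _ = build_design(xs, model.order, boundaries)
    if len(Z) > max_samples:  # deterministic thinning for long series
        Z = Z[:: int(np.ceil(len(Z) / max_samples))]
    T = 1.0 - np.tanh(Z @ model.U.T + model.c) ** 2  # (N, H)
    # J[n, j, m] = sum_h V[j,h] T[n,h] U[h,m]
    J = np.einsum("jh,nh,hm->njm", model.V, T, model.U, optimize=True)
    M, p = model.n_channels, model.order
    J = np.abs(J).mean(axis=0).reshape(M, p, M)  # (target, lag, source)
    return J.mean(axis=1).T                      # (source, target)


@dataclass
class ConnectivityMatrices:
    """Directed lC/NC matrices, [source, target] indexed, with masks."""

    lc: np.ndarray
    nc: np.ndarray
    lc_mask: np.ndarray | None = None
    nc_mask: np.ndarray | None = None
    normalized: bool = False
    condition: str = ""
    node_names: list | None = None

    def __post_init__(self) -> None:
        if np.any(self.lc < 0) or np.any(self.nc < 0):
            raise ValueError("connectivity values must be nonnegative")

    def masked(self, measure: str) -> np.ndarray:
        vals = getattr(self, measure)
        mask = getattr(self, f"{measure}_mask")
        return vals if mask is None else np.where(mask, vals, 0.0)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd
        M = self.lc.shape[0]
        names = self.node_names or [f"AC{i + 1}" for i in range(M)]
        rows = []
        for measure in ("lc", "nc"):
            vals = getattr(self, measure)
            msk = self.masked(measure)
            for i in range(M):
                for j in range(M):
                    rows.append({"condition": self.condition,
                                 "measure": measure,
                                 "source": names[i], "target": names[j],
                                 "raw": vals[i, j], "masked": msk[i, j],
                                 "normalized": self.normalized})
        return pd.DataFrame(rows)


@dataclass
class SurrogateEnsemble:
    """Per-connection null samples from phase-randomised surrogates."""

    lc_null: np.ndarray  # (n_surrogates, M, M)
    nc_null: np.ndarray
    percentile: float

    @property
    def n_surrogates(self) -> int:
        return self.lc_null.shape[0]


def select_model_order(series: np.ndarray, p_max: int = 10,
                       criteria=("aic", "bic")) -> dict:
    """Linear-VAR order selection by Akaike and Schwarz (BIC) criteria.

    Fits least-squares VARs for p = 1..p_max on a common sample and returns
    the criterion-minimising order for each criterion plus ``selected`` (BIC
    breaks disagreement). Orders below 1 are never returned.
    """
    x = np.asarray(series, float)
    M, N = x.shape
    if p_max >= N / (2 * M):
        raise ValueError("p_max too large for the series length")
    if N < 20 * M * p_max:
        raise ValueError(f"series length {N} below 20*M*p_max")
    from statsmodels.tsa.api import VAR
    sel = VAR(x.T).select_order(maxlags=p_max)
    out = {crit: max(1, int(sel.selected_orders[crit])) for crit in criteria}
    out["selected"] = out.get("bic", next(iter(out.values())))
    return out


# ---------------------------------------------------------------------------
# surrogates and significance
# ---------------------------------------------------------------------------

def phase_randomize(series: np.ndarray, seed: int = 0) -> np.ndarray:
    """Phase-randomised surrogate, per channel independently.

    Fourier phases of all non-DC (and non-Nyquist, for even length) bins are
    replaced by i.i.d. uniform phases; amplitudes are untouched, so each
    channel's periodogram — and its mean — is preserved exactly while
    cross-channel temporal structure is destroyed.
    """
    x = np.asarray(series, float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    rng = np.random.default_rng(seed)
    M, N = x.shape
    X = np.fft.rfft(x, axis=1)
    nf = X.shape[1]
    out = X.copy()
    lo, hi = 1, nf - 1 if N % 2 == 0 else nf
    phases = rng.uniform(0, 2 * np.pi, size=(M, hi - lo))
    out[:, lo:hi] = np.abs(X[:, lo:hi]) * np.exp(1j * phases)
    y = np.fft.irfft(out, n=N, axis=1)
    return y[0] if squeeze else y


def surrogate_test(series: np.ndarray, p: int, n_surrogates: int = 100,
                   percentile: float = 95.0, seed: int = 0,
                   boundaries=None, condition: str = "", node_names=None,
                   **fit_kwargs
                   ) -> tuple[ConnectivityMatrices, SurrogateEnsemble]:
    """Connectivity with phase-randomisation significance masks.

    The model is fitted to the original series and, with identical
    hyperparameters, to each surrogate. A connection is retained when its
    lC (resp. NC) exceeds the given percentile of its own surrogate null;
    non-retained entries are zeroed in the masked view while raw values are
    kept alongside. ``n_surrogates=0`` skips significance (all-true mask,
    with a warning).
    """
    model = fit_nmvar_ann(series, p, seed=seed, boundaries=boundaries,
                          **fit_kwargs)
    lc = linear_connectivity(model)
    nc = nonlinear_connectivity(model, series, boundaries)
    M = lc.shape[0]
    if n_surrogates == 0:
        warnings.warn("n_surrogates=0: significance testing skipped, "
                      "all connections retained", stacklevel=2)
        ens = SurrogateEnsemble(np.zeros((0, M, M)), np.zeros((0, M, M)),
                                percentile)
        cm = ConnectivityMatrices(lc, nc, np.ones_like(lc, bool),
                                  np.ones_like(nc, bool),
                                  condition=condition, node_names=node_names)
        return cm, ens
    lc_null = np.empty((n_surrogates, M, M))
    nc_null = np.empty((n_surrogates, M, M))
    for s in range(n_surrogates):
        try:
            surr = phase_randomize(series, seed=seed + 104729 * (s + 1))
            m_s = fit_nmvar_ann(surr, p, seed=seed, boundaries=boundaries,
                                **fit_kwargs)
        except Exception as e:
            raise RuntimeError(f"surrogate {s} failed: {e}") from e
        lc_null[s] = linear_connectivity(m_s)
        nc_null[s] = nonlinear_connectivity(m_s, surr, boundaries)
    lc_thr = np.percentile(lc_null, percentile, axis=0)
    nc_thr = np.percentile(nc_null, percentile, axis=0)
    cm = ConnectivityMatrices(lc, nc, lc > lc_thr, nc > nc_thr,
                              condition=condition, node_names=node_names)
    return cm, SurrogateEnsemble(lc_null, nc_null, percentile)


# ---------------------------------------------------------------------------
# normalisation and summaries
# ---------------------------------------------------------------------------

def normalize_connectivity(cond_a: ConnectivityMatrices,
                           cond_b: ConnectivityMatrices
                           ) -> tuple[ConnectivityMatrices,
                                      ConnectivityMatrices]:
    """Per-subject [0, 1] normalisation across two conditions.

    For each measure separately, every entry of both conditions is divided
    by the maximum entry over both conditions, so the maximum becomes
    exactly 1. lC and NC are scaled independently.
    """
    if cond_a.lc.shape != cond_b.lc.shape:
        raise ValueError("conditions must have the same node set")
    out = []
    scales = {}
    for measure in ("lc", "nc"):
        mx = max(getattr(cond_a, measure).max(),
                 getattr(cond_b, measure).max())
        if mx == 0:
            raise ValueError(f"all-zero {measure}: normalisation undefined")
        scales[measure] = mx
    for cm in (cond_a, cond_b):
        out.append(ConnectivityMatrices(
            cm.lc / scales["lc"], cm.nc / scales["nc"],
            cm.lc_mask, cm.nc_mask, normalized=True,
            condition=cm.condition, node_names=cm.node_names))
    return out[0], out[1]


def network_average(matrix: np.ndarray, include_self: bool = False) -> float:
    """Mean connectivity over directed pairs (off-diagonal by default)."""
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if include_self:
        return float(m.mean())
    if m.shape[0] < 2:
        raise ValueError("network average over non-self pairs needs M >= 2")
    mask = ~np.eye(m.shape[0], dtype=bool)
    return float(m[mask].mean())
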