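"""MVAR modelling and the directed transfer function (DTF).

The multichannel signal X(t) is modelled per epoch as a vector
autoregression of order p,

    X(t) = sum_{n=1..p} A_n X(t-n) + e(t),

estimated by ordinary least squares on stacked lagged regressors.  In the
frequency domain, with Abar(f) = I - sum_n A_n exp(-i 2 pi f n / fs), the
spectral transfer matrix is H(f) = Abar(f)^{-1} and the normalized DTF is

    gamma2[i, j](f) = |H[i, j](f)|^2 / sum_m |H[i, m](f)|^2,

the share of the total inflow into target channel i that originates from
source channel j; every target row sums to 1 at every frequency.  The scalar
edge weight DTF_Mean is gamma2 averaged over the in-band frequencies and
over epochs.

Significance of an edge is assessed against a surrogate-data null: each
channel is independently phase-randomized (amplitude spectrum preserved),
the MVAR/DTF computation is repeated, and the observed DTF_Mean must exceed
the (1 - alpha) quantile of the surrogate distribution — with 1000
surrogates and alpha = 0.05, the 950th sorted value.  Edges at or below the
threshold are set to 0.

Array axis convention: gamma2 and H are indexed [frequency, target, source].

Note: common-average-referenced data are exactly rank deficient (channels
sum to zero), making the normal equations singular.  The pipeline entry
points therefore apply a tiny relative ridge (1e-10) to the Gram matrix;
the public :func:`fit_mvar` defaults to ridge=0 and raises a singular-fit
error instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .preprocess import preprocess_recording
from .recording import EEGRecording, EpochSet
from .spectral import Band, DEFAULT_BANDS

__all__ = [
    "MVARModel",
    "SpectralTransfer",
    "SurrogateNull",
    "SingularFitError",
    "OrderSelectionError",
    "IllConditionedTransferError",
    "SurrogateFailureError",
    "fit_mvar",
    "select_order_bic",
    "simulate_mvar",
    "transfer_function",
    "dtf",
    "dtf_mean",
    "phase_randomize",
    "rank_index",
    "observed_dtf_mean",
    "surrogate_threshold",
    "threshold_network",
    "frequency_grid",
    "subject_connectivity",
    "cohort_connectivity_table",
]

_PIPELINE_RIDGE = 1e-10


class SingularFitError(RuntimeError):
    """Rank-deficient regressor matrix in the MVAR least squares."""


class OrderSelectionError(RuntimeError):
    """No candidate order produced a stable fit."""


class IllConditionedTransferError(RuntimeError):
    """Abar(f) numerically singular at some frequency."""


class SurrogateFailureError(RuntimeError):
    """Too many failed surrogate fits."""


# ---------------------------------------------------------------------------
# MVAR estimation


@dataclass
class MVARModel:
    """Order-p vector autoregression: coefficient matrices and residual
    covariance (maximum-likelihood normalization)."""

    order: int
    coeffs: List[np.ndarray]  # p matrices, each k x k
    resid_cov: np.ndarray
    n_samples_used: int
    stable: bool = True

    @property
    def n_channels(self) -> int:
        return self.coeffs[0].shape[0]

    def companion_spectral_radius(self) -> float:
        k, p = self.n_channels, self.order
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = np.hstack(self.coeffs)
        if p > 1:
            comp[k:, : k * (p - 1)] = np.eye(k * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _lagged_design(data: np.ndarray, p: int) -> Tuple[np.ndarray, np.ndarray]:
    """Y (k x M) and stacked lagged regressors Z (k*p x M), M = N - p."""
    N = data.shape[1]
    Y = data[:, p:]
    Z = np.vstack([data[:, p - n : N - n] for n in range(1, p + 1)])
    return Y, Z


def fit_mvar(data: np.ndarray, p: int, ridge: float = 0.0) -> MVARModel:
    """Least-squares MVAR(p) fit of one epoch (channels x samples).

    ``ridge`` is a relative Tikhonov term on the Gram matrix (fraction of its
    mean diagonal); leave at 0 for exact OLS, which raises
    :class:`SingularFitError` on rank-deficient data such as
    common-average-referenced channels.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    if p < 1:
        raise ValueError("model order p must be >= 1")
    k, N = data.shape
    M = N - p
    if M <= k * p:
        raise ValueError(f"need more than {k * p + p} samples for k={k}, p={p}; got {N}")
    Y, Z = _lagged_design(data, p)
    G = Z @ Z.T
    C = Z @ Y.T
    if ridge > 0:
        G = G + ridge * (np.trace(G) / G.shape[0]) * np.eye(G.shape[0])
    else:
        # exact OLS: detect rank deficiency before solving
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularFitError(
                f"rank-deficient regressor matrix (cond={cond:.2e}); "
                "consider a small ridge for average-referenced data"
            )
    try:
        B = np.linalg.solve(G, C)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError(str(exc)) from exc
    A = B.T  # k x (k*p)
    resid = Y - A @ Z
    sigma = resid @ resid.T / M
    coeffs = [A[:, (n - 1) * k : n * k].copy() for n in range(1, p + 1)]
    model = MVARModel(order=p, coeffs=coeffs, resid_cov=sigma, n_samples_used=M)
    model.stable = model.companion_spectral_radius() < 1.0
    return model


def select_order_bic(
    data: np.ndarray,
    p_candidates: Sequence[int],
    ridge: float = 0.0,
) -> int:
    """Smallest candidate order minimizing
    BIC(p) = ln det(resid_cov) + k^2 p ln(N) / N  (N = usable samples).

    Unstable fits are excluded; if every candidate is unstable an
    :class:`OrderSelectionError` is raised.
    """
    cands = sorted(set(int(p) for p in p_candidates))
    if not cands:
        raise ValueError("p_candidates must be non-empty")
    best_p, best_bic = None, np.inf
    k = np.asarray(data).shape[0]
    for p in cands:
        model = fit_mvar(data, p, ridge=ridge)
        if not model.stable:
            continue
        N = model.n_samples_used
        sigma = model.resid_cov
        # jitter guards against exactly singular covariance (referenced data)
        jitter = 1e-12 * np.trace(sigma) / k
        sign, logdet = np.linalg.slogdet(sigma + jitter * np.eye(k))
        if sign <= 0:
            continue
        bic = logdet + (k * k * p) * np.log(N) / N
        if bic < best_bic:
            best_p, best_bic = p, bic
    if best_p is None:
        raise OrderSelectionError(f"no stable fit among candidate orders {cands}")
    return best_p


def simulate_mvar(
    coeffs: Sequence[np.ndarray],
    n: int,
    rng: np.random.Generator,
    noise_cov: Optional[np.ndarray] = None,
    burn_in: int = 500,
) -> np.ndarray:
    """Simulate n samples from an MVAR process with the given coefficient
    matrices and (default identity) innovation covariance."""
    coeffs = [np.asarray(a, dtype=float) for a in coeffs]
    k = coeffs[0].shape[0]
    p = len(coeffs)
    chol = None if noise_cov is None else np.linalg.cholesky(noise_cov)
    total = n + burn_in
    eps = rng.standard_normal((total, k))
    if chol is not None:
        eps = eps @ chol.T
    X = np.zeros((total, k))
    for t in range(p, total):
        acc = eps[t].copy()
        for lag, A in enumerate(coeffs, start=1):
            acc += A @ X[t - lag]
        X[t] = acc
    return X[burn_in:].T  # channels x samples


# ---------------------------------------------------------------------------
# Spectral transfer and DTF


@dataclass
class SpectralTransfer:
    """H(f) = Abar(f)^{-1} on a frequency grid; axes [freq, target, source]."""

    freqs: np.ndarray
    H: np.ndarray
    sample_rate: float


def _abar(coeffs_stacked: np.ndarray, p: int, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Abar(f) for a batch: coeffs_stacked (..., k, k*p) -> (..., F, k, k)."""
    k = coeffs_stacked.shape[-2]
    A = coeffs_stacked.reshape(*coeffs_stacked.shape[:-1], p, k).swapaxes(-3, -2)
    # A now (..., p, k, k) with lag axis third from the end
    phase = np.exp(-2j * np.pi * np.outer(np.asarray(freqs), np.arange(1, p + 1)) / fs)
    lagsum = np.einsum("fp,...pij->...fij", phase, A)
    return np.eye(k) - lagsum


def transfer_function(model: MVARModel, freqs: np.ndarray, fs: float) -> SpectralTransfer:
    """Spectral transfer matrix H(f) = (I - sum_n A_n e^{-i2pifn/fs})^{-1}."""
    freqs = np.asarray(freqs, dtype=float)
    k, p = model.n_channels, model.order
    stacked = np.hstack(model.coeffs)  # k x (k*p)
    Abar = _abar(stacked, p, freqs, fs)  # F x k x k
    conds = np.linalg.cond(Abar)
    bad = np.where(~np.isfinite(conds) | (conds > 1e12))[0]
    if bad.size:
        raise IllConditionedTransferError(
            f"Abar(f) numerically singular at f={freqs[bad[0]]:.3g} Hz"
        )
    H = np.linalg.inv(Abar)
    return SpectralTransfer(freqs=freqs, H=H, sample_rate=fs)


def dtf(H: Union[SpectralTransfer, np.ndarray]) -> np.ndarray:
    """Normalized DTF gamma2[f, i, j] = |H_ij|^2 / sum_m |H_im|^2.

    Rows (fixed target i) sum to exactly 1 at every frequency.
    """
    arr = H.H if isinstance(H, SpectralTransfer) else np.asarray(H)
    g = np.abs(arr) ** 2
    denom = g.sum(axis=-1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("degenerate normalization: a target row of H is all zero")
    return g / denom


def dtf_mean(
    gamma2: np.ndarray,
    freqs: np.ndarray,
    band: Band,
) -> np.ndarray:
    """Average gamma2 over in-band frequencies and (if present) epochs.

    ``gamma2`` is (F, k, k) for a single epoch or (E, F, k, k) for several;
    returns a (k, k) [target, source] matrix.
    """
    freqs = np.asarray(freqs)
    mask = band.mask(freqs)
    if not mask.any():
        raise ValueError(f"no grid frequencies inside band {band.name}")
    g = np.asarray(gamma2)
    if g.ndim == 3:
        return g[mask].mean(axis=0)
    if g.ndim == 4:
        return g[:, mask].mean(axis=(0, 1))
    raise ValueError("gamma2 must be (F,k,k) or (E,F,k,k)")


def frequency_grid(f_lo: float = 1.0, f_hi: float = 30.0, step: float = 0.5) -> np.ndarray:
    """Analysis grid, inclusive of both edges (1-30 Hz in 0.5 Hz steps)."""
    n = int(round((f_hi - f_lo) / step))
    return f_lo + step * np.arange(n + 1)


# ---------------------------------------------------------------------------
# Surrogate-data significance testing


def phase_randomize(data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent per-channel phase randomization preserving the amplitude
    spectrum exactly.

    Works on any (..., samples) array; each leading slice (channel, epoch)
    receives independent uniform phases; the DC and (even-length) Nyquist
    bins are kept real so the output is exactly real.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    n = data.shape[-1]
    spec = np.fft.rfft(data, axis=-1)
    nb = spec.shape[-1]
    hi = nb - 1 if n % 2 == 0 else nb  # exclude Nyquist bin for even n
    if hi > 1:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape[:-1] + (hi - 1,))
        spec[..., 1:hi] = np.abs(spec[..., 1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n, axis=-1)


def rank_index(n_surrogates: int, alpha: float) -> int:
    """1-based rank of the surrogate order statistic used as threshold:
    ceil((1 - alpha) * n).  1000 surrogates at alpha=0.05 -> 950."""
    return int(np.ceil((1.0 - alpha) * n_surrogates))


@dataclass
class SurrogateNull:
    """Sorted surrogate DTF_Mean distributions and per-edge thresholds."""

    thresholds: Dict[str, np.ndarray]  # band -> (k, k)
    distributions: Dict[str, np.ndarray]  # band -> (n_surrogates, k, k), sorted
    n_surrogates: int
    alpha: float

    @property
    def rank(self) -> int:
        return rank_index(self.n_surrogates, self.alpha)


def _fit_epochs_batch(epochs: np.ndarray, p: int, ridge: float) -> np.ndarray:
    """OLS coefficients for every epoch at once: (E, k, N) -> (E, k, k*p)."""
    E, k, N = epochs.shape
    Y = epochs[:, :, p:]
    Z = np.concatenate([epochs[:, :, p - n : N - n] for n in range(1, p + 1)], axis=1)
    G = Z @ Z.transpose(0, 2, 1)
    C = Z @ Y.transpose(0, 2, 1)
    if ridge > 0:
        lam = ridge * np.trace(G, axis1=1, axis2=2) / G.shape[1]
        G = G + lam[:, None, None] * np.eye(G.shape[1])
    B = np.linalg.solve(G, C)  # (E, k*p, k)
    return B.transpose(0, 2, 1)


def _gamma2_batch(coeffs: np.ndarray, p: int, freqs: np.ndarray, fs: float) -> np.ndarray:
    """gamma2 for a batch of stacked coefficient matrices: (E, k, k*p) ->
    (E, F, k, k)."""
    Abar = _abar(coeffs, p, freqs, fs)
    H = np.linalg.inv(Abar)
    g = np.abs(H) ** 2
    return g / g.sum(axis=-1, keepdims=True)


def _epoch_array(eps: Union[EpochSet, np.ndarray]) -> np.ndarray:
    arr = eps.epochs if isinstance(eps, EpochSet) else np.asarray(eps, dtype=float)
    if arr.ndim != 3:
        raise ValueError("epochs must be (epoch, channel, sample)")
    return arr


def observed_dtf_mean(
    eps: Union[EpochSet, np.ndarray],
    bands: Iterable[Band],
    order: int = 2,
    sample_rate: Optional[float] = None,
    grid_step: float = 0.5,
    f_lo: float = 1.0,
    f_hi: float = 30.0,
    ridge: float = _PIPELINE_RIDGE,
) -> Dict[str, np.ndarray]:
    """Per-band epoch-averaged DTF_Mean matrices for one subject."""
    arr = _epoch_array(eps)
    fs = sample_rate if sample_rate is not None else eps.sample_rate
    freqs = frequency_grid(f_lo, f_hi, grid_step)
    coeffs = _fit_epochs_batch(arr, order, ridge)
    out: Dict[str, np.ndarray] = {}
    for band in bands:
        mask = band.mask(freqs)
        if not mask.any():
            raise ValueError(f"no grid frequencies inside band {band.name}")
        g = _gamma2_batch(coeffs, order, freqs[mask], fs)
        out[band.name] = g.mean(axis=(0, 1))
    return out


def surrogate_threshold(
    eps: Union[EpochSet, np.ndarray],
    bands: Iterable[Band],
    order: int = 2,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    sample_rate: Optional[float] = None,
    grid_step: float = 0.5,
    f_lo: float = 1.0,
    f_hi: float = 30.0,
    ridge: float = _PIPELINE_RIDGE,
    max_retries: int = 20,
) -> SurrogateNull:
    """Empirical null for DTF_Mean by per-channel phase randomization.

    Every surrogate replicate phase-randomizes all channels of all epochs
    independently, refits the MVAR per epoch, and recomputes the
    epoch-averaged DTF_Mean; the per-edge threshold is the order statistic
    at rank ceil((1-alpha) * n_surrogates).  Replicates whose fit comes out
    non-finite are redrawn, up to ``max_retries`` times in total.
    """
    if n_surrogates < 20:
        raise ValueError("n_surrogates must be >= 20")
    arr = _epoch_array(eps)
    fs = sample_rate if sample_rate is not None else eps.sample_rate
    rng = rng if rng is not None else np.random.default_rng()
    bands = tuple(bands)
    freqs = frequency_grid(f_lo, f_hi, grid_step)
    masks = {b.name: b.mask(freqs) for b in bands}
    for b in bands:
        if not masks[b.name].any():
            raise ValueError(f"no grid frequencies inside band {b.name}")
    union = np.zeros(len(freqs), dtype=bool)
    for m in masks.values():
        union |= m
    ufreqs = freqs[union]
    sub = {name: m[union] for name, m in masks.items()}

    E, k, N = arr.shape
    dists = {b.name: np.empty((n_surrogates, k, k)) for b in bands}
    failures = 0
    s = 0
    # fixed chunk size keeps the rng stream (and hence results) independent
    # of how many surrogates are requested at once
    chunk = 20
    while s < n_surrogates:
        c = min(chunk, n_surrogates - s)
        surro = phase_randomize(np.broadcast_to(arr, (c, E, k, N)), rng)
        coeffs = _fit_epochs_batch(surro.reshape(c * E, k, N), order, ridge)
        g = _gamma2_batch(coeffs, order, ufreqs, fs)
        g = g.reshape(c, E, len(ufreqs), k, k)
        ok = np.isfinite(g).all(axis=(1, 2, 3, 4))
        for ci in np.where(ok)[0]:
            if s >= n_surrogates:
                break
            for b in bands:
                dists[b.name][s] = g[ci][:, sub[b.name]].mean(axis=(0, 1))
            s += 1
        failures += int((~ok).sum())
        if failures > max_retries:
            raise SurrogateFailureError(
                f"{failures} failed surrogate fits (budget {max_retries})"
            )

    rank = rank_index(n_surrogates, alpha)
    thresholds: Dict[str, np.ndarray] = {}
    for name, d in dists.items():
        d.sort(axis=0)
        thresholds[name] = d[rank - 1]
    return SurrogateNull(
        thresholds=thresholds, distributions=dists,
        n_surrogates=n_surrogates, alpha=alpha,
    )


def threshold_network(dtf_mean_mat: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Zero out edges not strictly above their surrogate threshold; the
    diagonal is always zero.  Ties go to non-significant (conservative)."""
    dtf_mean_mat = np.asarray(dtf_mean_mat, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if dtf_mean_mat.shape != thresholds.shape:
        raise ValueError(
            f"shape mismatch: {dtf_mean_mat.shape} vs {thresholds.shape}"
        )
    out = np.where(dtf_mean_mat > thresholds, dtf_mean_mat, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Subject- and cohort-level pipelines


def subject_connectivity(
    eps: EpochSet,
    bands: Iterable[Band] = DEFAULT_BANDS,
    order: Union[int, str] = 2,
    order_candidates: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    grid_step: float = 0.5,
    f_lo: float = 1.0,
    f_hi: float = 30.0,
    ridge: float = _PIPELINE_RIDGE,
) -> Dict[str, object]:
    """DTF_Mean, surrogate thresholds and thresholded networks per band for
    one epoched subject.  ``order='auto'`` selects p by BIC on the first
    epoch; the default fixed order is 2."""
    bands = tuple(bands)
    if order == "auto":
        p = select_order_bic(eps.epochs[0], order_candidates, ridge=ridge)
    else:
        p = int(order)
        if p < 1:
            raise ValueError("order must be >= 1 or 'auto'")
    observed = observed_dtf_mean(
        eps, bands, order=p, grid_step=grid_step, f_lo=f_lo, f_hi=f_hi, ridge=ridge
    )
    null = surrogate_threshold(
        eps, bands, order=p, n_surrogates=n_surrogates, alpha=alpha, rng=rng,
        grid_step=grid_step, f_lo=f_lo, f_hi=f_hi, ridge=ridge,
    )
    thresholded = {
        name: threshold_network(observed[name], null.thresholds[name])
        for name in observed
    }
    return {
        "order": p,
        "dtf_mean": observed,
        "null": null,
        "thresholded": thresholded,
    }


def cohort_connectivity_table(
    recordings: Sequence[EEGRecording],
    bands: Iterable[Band] = DEFAULT_BANDS,
    order: Union[int, str] = 2,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    grid_step: float = 0.5,
    f_lo: float = 1.0,
    f_hi: float = 30.0,
    lo: float = 1.0,
    hi: float = 30.0,
    epoch_length_s: float = 5.0,
) -> pd.DataFrame:
    """Preprocess every subject and tabulate directed edges in long format.

    Columns: subject_id, group, moca, band, source, target, dtf_mean,
    threshold, significant, value (DTF_Mean with sub-threshold edges set to
    0).  Diagonal entries are excluded.
    """
    bands = tuple(bands)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(recordings))
    rows: List[dict] = []
    for rec, child in zip(recordings, children):
        eps = preprocess_recording(rec, lo=lo, hi=hi, epoch_length_s=epoch_length_s)
        res = subject_connectivity(
            eps, bands, order=order, n_surrogates=n_surrogates, alpha=alpha,
            rng=np.random.default_rng(child), grid_step=grid_step,
            f_lo=f_lo, f_hi=f_hi,
        )
        labels = rec.channel_labels
        for band in bands:
            obs = res["dtf_mean"][band.name]
            thr = res["null"].thresholds[band.name]
            kept = res["thresholded"][band.name]
            for i, tgt in enumerate(labels):  # target
                for j, src in enumerate(labels):  # source
                    if i == j:
                        continue
                    rows.append({
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "moca": rec.moca,
                        "band": band.name,
                        "source": src,
                        "target": tgt,
                        "dtf_mean": float(obs[i, j]),
                        "threshold": float(thr[i, j]),
                        "significant": bool(obs[i, j] > thr[i, j]),
                        "value": float(kept[i, j]),
                    })
    return pd.DataFrame(rows)
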