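"""Multichannel post-processing chain for dynamic 13C EPI data.

The chain is: estimate the channel noise covariance from signal-free
samples, prewhiten via its Cholesky factor, combine channels with
complex matched-filter weights derived from the time-summed pyruvate
signal, apply a zero-order phase per voxel, denoise with a truncated
higher-order SVD, and form SNR-thresholded area-under-the-curve maps.

The fixed operation order (prewhiten -> combine -> phase -> denoise) is
a pipeline convention; denoising operates on the real-valued combined
data as a 5-mode tensor (metabolite, time, slice, row, column).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .containers import AcquisitionParams, MetaboliteSeries, NoiseModel, RawDynamic, METABOLITES

__all__ = [
    "estimate_noise_covariance",
    "prewhiten",
    "combine_channels",
    "phase_correct",
    "hosvd_denoise",
    "auc_maps",
    "AUCMaps",
]


# ---------------------------------------------------------------------------
# noise covariance and prewhitening
# ---------------------------------------------------------------------------

def _noise_samples(raw: RawDynamic) -> np.ndarray:
    """Signal-free samples as a (n_channels, n_samples) complex matrix."""
    if not raw.noise_frames:
        raise ValueError("no noise frames designated in the raw data")
    cols = []
    for m in METABOLITES:
        a = raw.data[m]
        for f in raw.noise_frames:
            cols.append(a[:, f].reshape(a.shape[0], -1))
    return np.concatenate(cols, axis=1)


def estimate_noise_covariance(raw: RawDynamic, eps: float = 1e-9) -> NoiseModel:
    """Sample channel covariance of the designated signal-free samples.

    The estimate ``C = X X^H / (N-1)`` (mean-subtracted) is Hermitian
    positive-semidefinite; if it is not positive-definite (e.g. a
    duplicated channel), ``eps * trace/n`` is added to the diagonal,
    escalating tenfold until the Cholesky factorization succeeds.
    """
    x = _noise_samples(raw)
    n_ch, n_s = x.shape
    if n_s < 10 * n_ch:
        raise ValueError(
            f"need >= {10 * n_ch} signal-free samples for {n_ch} channels, got {n_s}"
        )
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.conj().T) / (n_s - 1)
    cov = (cov + cov.conj().T) / 2.0
    bump = eps * np.trace(cov).real / n_ch
    for _ in range(12):
        try:
            np.linalg.cholesky(cov)
            break
        except np.linalg.LinAlgError:
            cov = cov + bump * np.eye(n_ch)
            bump *= 10.0
    return NoiseModel(channel_covariance=cov, noise_scale=1.0)


def prewhiten(raw: RawDynamic, noise: NoiseModel) -> RawDynamic:
    """Decorrelate channels with the inverse Cholesky factor of the covariance.

    With ``cov = L L^H`` the channels are multiplied by ``L^-1``, after
    which the noise covariance of signal-free samples is the identity.
    """
    if noise.n_channels != raw.n_channels:
        raise ValueError(
            f"covariance is {noise.n_channels}-channel, data has {raw.n_channels}"
        )
    L = noise.cholesky()
    data = {}
    for m, a in raw.data.items():
        flat = a.reshape(a.shape[0], -1)
        white = solve_triangular(L, flat, lower=True)
        data[m] = white.reshape(a.shape)
    return RawDynamic(
        data=data, acq=raw.acq,
        noise_frames=list(raw.noise_frames),
        appended_noise_frame=raw.appended_noise_frame,
    )


# ---------------------------------------------------------------------------
# channel combination and phasing
# ---------------------------------------------------------------------------

def combine_channels(raw: RawDynamic) -> MetaboliteSeries:
    """Matched-filter channel combination with pyruvate-derived weights.

    Per voxel, the complex weight of each channel is the conjugate of
    its time-summed pyruvate signal (dynamic frames only), normalized to
    unit norm across channels; the same weights are applied to every
    metabolite.  Voxels with an all-zero pyruvate signal have undefined
    weights: their output is zero and they are flagged in
    ``invalid_mask``.  The combined noise standard deviation (real
    channel, per sample) is estimated from the noise frames.
    """
    n_t = raw.n_timepoints
    pyr = raw.data["pyr"][:, :n_t]  # exclude an appended noise frame
    ref = pyr.sum(axis=1)  # (channel, slice, row, col)
    norm = np.sqrt((np.abs(ref) ** 2).sum(axis=0))
    invalid = norm == 0
    weights = np.where(invalid, 0.0, ref.conj() / np.where(invalid, 1.0, norm))

    combined = {}
    for m in METABOLITES:
        combined[m] = np.einsum("czyx,ctzyx->tzyx", weights, raw.data[m])

    # noise level of the combined data, from the designated noise frames
    noise_vals = np.concatenate(
        [combined[m][f].ravel() for m in METABOLITES for f in raw.noise_frames]
    ) if raw.noise_frames else np.array([])
    noise_sd = None
    if noise_vals.size:
        # circular noise: Var(Re) == Var(Im) == E|n|^2 / 2
        sd = float(np.sqrt(np.mean(np.abs(noise_vals) ** 2) / 2.0))
        noise_sd = sd if sd > 0 else None

    return MetaboliteSeries(
        pyr=combined["pyr"][:n_t],
        lac=combined["lac"][:n_t],
        bic=combined["bic"][:n_t],
        time=raw.acq.time_axis(),
        acq=raw.acq,
        noise_sd=noise_sd,
        invalid_mask=invalid,
    )


def phase_correct(series: MetaboliteSeries) -> MetaboliteSeries:
    """Zero-order per-voxel phasing from the peak-pyruvate timepoint.

    The phase of the pyruvate signal at its per-voxel magnitude peak is
    removed from all metabolites, and the real part is kept.  On
    noiseless data whose timepoints share that phase, the real output
    equals the magnitude.
    """
    if not np.iscomplexobj(series.pyr):
        return series
    peak = np.abs(series.pyr).argmax(axis=0)
    idx = np.indices(series.volume_shape)
    phase = np.angle(series.pyr[(peak,) + tuple(idx)])
    rot = np.exp(-1j * phase)
    return MetaboliteSeries(
        pyr=(series.pyr * rot).real,
        lac=(series.lac * rot).real,
        bic=(series.bic * rot).real,
        time=series.time,
        acq=series.acq,
        noise_sd=series.noise_sd,
        invalid_mask=series.invalid_mask,
    )


# ---------------------------------------------------------------------------
# HOSVD denoising
# ---------------------------------------------------------------------------

def _unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def _mode_multiply(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    out = matrix @ _unfold(tensor, mode)
    shape = list(tensor.shape)
    shape[mode] = matrix.shape[0]
    return np.moveaxis(
        out.reshape([matrix.shape[0]] + [s for i, s in enumerate(tensor.shape) if i != mode]),
        0, mode,
    )


def hosvd(tensor: np.ndarray, ranks: tuple[int, ...]):
    """Truncated higher-order SVD: per-mode factors and the core tensor."""
    factors = []
    for mode, r in enumerate(ranks):
        if r > tensor.shape[mode]:
            raise ValueError(
                f"rank {r} exceeds mode-{mode} dimension {tensor.shape[mode]}"
            )
        u, _, _ = np.linalg.svd(_unfold(tensor, mode), full_matrices=False)
        factors.append(u[:, :r])
    core = tensor
    for mode, u in enumerate(factors):
        core = _mode_multiply(core, u.conj().T, mode)
    return core, factors


def _scree_ranks(tensor: np.ndarray, energy: float) -> tuple[int, ...]:
    """Smallest per-mode ranks whose singular values cover ``energy`` of each
    mode's total squared spectrum."""
    ranks = []
    for mode in range(tensor.ndim):
        s = np.linalg.svd(_unfold(tensor, mode), compute_uv=False)
        cum = np.cumsum(s**2) / np.sum(s**2)
        ranks.append(int(np.searchsorted(cum, energy) + 1))
    return tuple(ranks)


def hosvd_denoise(
    series: MetaboliteSeries,
    rank_spec: tuple[int, ...] | float | None = None,
) -> MetaboliteSeries:
    """Denoise the stacked dynamic data by truncated HOSVD reconstruction.

    ``rank_spec`` is either explicit per-mode ranks for the 5-mode
    tensor (metabolite, time, slice, row, column), a mode-energy
    fraction in (0, 1) for the scree criterion, or None for the default
    0.999 energy criterion.  The default is deliberately conservative:
    the metabolite mode is dominated by pyruvate, and aggressive
    truncation there mixes metabolites and biases downstream kinetics.
    At full ranks the reconstruction is the identity; retaining fewer
    ranks removes the weakest mode components, which on low-rank-plus-
    noise data suppresses noise.
    """
    tensor = series.stack()
    if rank_spec is None:
        ranks = _scree_ranks(tensor, 0.999)
    elif isinstance(rank_spec, float):
        if not 0 < rank_spec <= 1:
            raise ValueError("energy fraction must lie in (0, 1]")
        ranks = _scree_ranks(tensor, rank_spec)
    else:
        ranks = tuple(int(r) for r in rank_spec)
        if len(ranks) != tensor.ndim:
            raise ValueError(f"need {tensor.ndim} per-mode ranks, got {len(ranks)}")
    core, factors = hosvd(tensor, ranks)
    recon = core
    for mode, u in enumerate(factors):
        recon = _mode_multiply(recon, u, mode)
    return series.replace_data(recon)


# ---------------------------------------------------------------------------
# AUC maps
# ---------------------------------------------------------------------------

@dataclass
class AUCMaps:
    """Per-metabolite AUC volumes with SNR and validity masks."""

    auc: dict[str, np.ndarray]
    snr: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    snr_threshold: float


def auc_maps(series: MetaboliteSeries, snr_threshold: float = 5.0) -> AUCMaps:
    """Time-summed metabolite images thresholded at AUC SNR > threshold.

    AUC is the plain sum over timepoints; its noise standard deviation
    is ``noise_sd * sqrt(n_timepoints)`` (independent per-frame noise
    adds in quadrature), so SNR = AUC / (noise_sd * sqrt(n)).  The mask
    keeps voxels with SNR strictly above the threshold.
    """
    if series.noise_sd is None:
        raise ValueError("series has no noise estimate; run channel combination first")
    n = series.pyr.shape[0]
    auc = {m: series[m].sum(axis=0) for m in METABOLITES}
    denom = series.noise_sd * np.sqrt(n)
    snr = {m: auc[m] / denom for m in METABOLITES}
    mask = {m: snr[m] > snr_threshold for m in METABOLITES}
    return AUCMaps(auc=auc, snr=snr, mask=mask, snr_threshold=snr_threshold)
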