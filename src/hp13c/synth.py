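"""Synthetic dynamic hyperpolarized-13C data generation.

Provides seeded generators for a digital brain phantom with NAWM /
T2-lesion / tumor ROIs, a gamma-variate pyruvate bolus, the two-site
exchange forward model (pyruvate -> lactate, pyruvate -> bicarbonate)
sampled with per-metabolite flip angles, and multichannel complex data
with correlated channel noise.  These serve both as test fixtures and as
ground truth for parameter-recovery studies.

Forward model
-------------
Magnetization evolves by the linear system

    dP/dt = -(1/T1_P + k_PL + k_PB) P + u(t)
    dL/dt = k_PL P - L/T1_L
    dB/dt = k_PB P - B/T1_B

with u(t) the bolus input.  At each sample time t_i the recorded signal
is S_X(i) = M_X(t_i) sin(alpha_X) and the magnetization loses a factor
cos(alpha_X), once per metabolite per timepoint.  Propagation between
samples uses the closed-form solution of the (lower-triangular) linear
system on a fine substep grid with piecewise-constant input, so the
integration is exact up to the input discretization.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import (
    AcquisitionParams,
    BolusParams,
    KineticParams,
    MetaboliteSeries,
    NoiseModel,
    PhantomROISet,
    RawDynamic,
)

__all__ = [
    "make_phantom",
    "simulate_bolus",
    "simulate_two_site",
    "synthesize_multichannel",
    "default_coil_profiles",
]


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

def make_phantom(shape: tuple[int, int, int], seed: int) -> PhantomROISet:
    """Build a mirror-symmetric brain phantom with nested tissue ROIs.

    Parameters
    ----------
    shape
        Voxel counts ``(n_slices, n_rows, n_columns)``; every dimension
        must be at least 8.
    seed
        Seed for the lesion placement; identical seeds give identical
        masks.

    Returns
    -------
    PhantomROISet
        Brain mask symmetric about the column-axis midplane; a gray
        matter shell; a T2 lesion (sphere) placed in the left hemisphere
        with a smaller tumor core; NAWM = brain interior minus gray
        matter and lesion.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError(f"phantom shape must have 3 dims, all >= 8, got {shape}")
    rng = np.random.default_rng(seed)
    ns, nr, nc = shape
    zc, rc, cc = (ns - 1) / 2.0, (nr - 1) / 2.0, (nc - 1) / 2.0
    z, r, c = np.ogrid[:ns, :nr, :nc]
    # ellipsoidal brain, symmetric in the column axis by construction
    az, ar, ac = 0.46 * ns, 0.46 * nr, 0.46 * nc
    brain = ((z - zc) / az) ** 2 + ((r - rc) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0

    interior = ndimage.binary_erosion(brain, iterations=1)
    gm = brain & ~interior  # cortical shell

    # lesion: a small sphere in the left hemisphere (columns < center)
    lesion_radius = max(1.5, 0.12 * min(shape))
    interior_idx = np.argwhere(interior[:, :, : int(np.floor(cc))])
    # keep candidates away from the midline so the lesion stays lateralized
    lateral = interior_idx[interior_idx[:, 2] < cc - lesion_radius]
    if len(lateral) == 0:
        lateral = interior_idx
    center = lateral[rng.integers(len(lateral))]
    dist2 = (z - center[0]) ** 2 + (r - center[1]) ** 2 + (c - center[2]) ** 2
    lesion = (dist2 <= lesion_radius**2) & brain
    tumor = (dist2 <= max(1.0, lesion_radius - 1.0) ** 2) & brain

    nawm = interior & ~gm & ~lesion
    return PhantomROISet(
        brain_mask=brain,
        nawm_mask=nawm,
        gm_mask=gm,
        t2_lesion_mask=lesion,
        tumor_mask=tumor,
    )


# ---------------------------------------------------------------------------
# bolus
# ---------------------------------------------------------------------------

def simulate_bolus(params: BolusParams, t: np.ndarray) -> np.ndarray:
    """Gamma-variate pyruvate input evaluated on a time grid.

    The trace is ``A * x^alpha * exp(-x/beta)`` with ``x = t - arrival``
    (zero for ``t < arrival``), normalized so its maximum equals
    ``params.amplitude``; the peak sits at ``arrival + alpha*beta``.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim >= 1 and t.size and np.any(np.diff(t) < 0):
        raise ValueError("time grid must be non-decreasing")
    x = np.clip(t - params.arrival_time, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = x**params.alpha * np.exp(-x / params.beta)
    peak = (params.alpha * params.beta) ** params.alpha * np.exp(-params.alpha)
    return params.amplitude * raw / peak


# ---------------------------------------------------------------------------
# closed-form propagation helpers
# ---------------------------------------------------------------------------

def _phi(a, b, dt):
    """(exp(a*dt) - exp(b*dt)) / (a - b), with the a == b limit dt*exp(a*dt).

    Uses expm1 so the difference stays accurate when a*dt and b*dt are
    tiny (long T1 limits, fine substeps).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a - b
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-30)
    near = np.abs(diff) < 1e-9 * scale
    safe = np.where(near, 1.0, diff)
    out = (np.expm1(a * dt) - np.expm1(b * dt)) / safe
    return np.where(near, dt * np.exp(a * dt), out)


def _int_exp(lam, dt):
    """Integral of exp(lam*s) over [0, dt] (== dt when lam == 0)."""
    lam = np.asarray(lam, dtype=float)
    zero = np.abs(lam) * dt < 1e-300
    safe = np.where(zero, 1.0, lam)
    return np.where(zero, dt, np.expm1(lam * dt) / safe)


def _substep_propagator(lam_p, lam_l, lam_b, k_pl, k_pb, dt):
    """Closed-form one-substep propagator of the triangular system.

    Returns the nonzero entries of E = exp(A*dt) and the input response
    psi = int_0^dt exp(A*(dt-s)) e_P ds for unit constant input into P.
    """
    e_pp = np.exp(lam_p * dt)
    e_ll = np.exp(lam_l * dt)
    e_bb = np.exp(lam_b * dt)
    e_lp = k_pl * _phi(lam_p, lam_l, dt)
    e_bp = k_pb * _phi(lam_p, lam_b, dt)
    psi_p = _int_exp(lam_p, dt)
    # int_0^dt phi(lam_p, lam_x, s) ds, via the same difference quotient
    psi_l = k_pl * _phi_integral(lam_p, lam_l, dt)
    psi_b = k_pb * _phi_integral(lam_p, lam_b, dt)
    return e_pp, e_ll, e_bb, e_lp, e_bp, psi_p, psi_l, psi_b


def _phi_integral(a, b, dt):
    """Integral over [0, dt] of phi(a, b, s) ds, limits handled."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a - b
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-30)
    near = np.abs(diff) < 1e-9 * scale
    safe = np.where(near, 1.0, diff)
    out = (_int_exp(a, dt) - _int_exp(b, dt)) / safe
    # a == b limit: int s*exp(a*s) ds over [0, dt]
    azero = np.abs(a) * dt < 1e-8
    asafe = np.where(azero, 1.0, a)
    lim = np.where(
        azero,
        dt**2 / 2.0,
        (dt * np.exp(a * dt) - _int_exp(a, dt)) / asafe,
    )
    return np.where(near, lim, out)


# ---------------------------------------------------------------------------
# two-site exchange forward model
# ---------------------------------------------------------------------------

def simulate_two_site(
    input,
    kp: KineticParams,
    acq: AcquisitionParams,
    *,
    amplitude_map: np.ndarray | None = None,
    substeps_per_frame: int = 60,
    initial: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> MetaboliteSeries:
    """Simulate noiseless sampled metabolite signals for the two-site model.

    Parameters
    ----------
    input
        Either a :class:`BolusParams` (the pyruvate pool is driven by the
        gamma-variate input and evolves by the full linear system from
        t = 0) or a 1-D array giving the pyruvate magnetization at the
        sample times, in which case pyruvate is prescribed and only the
        product pools evolve (piecewise-linear pyruvate between samples,
        with the cos(alpha_P) sampling loss applied at each frame start).
    kp
        Rates and T1 values.  ``k_pl``/``k_pb`` may be scalars or arrays
        (voxelwise rate maps); arrays broadcast against ``amplitude_map``.
    acq
        Sampling schedule and flip angles.
    amplitude_map
        Optional per-voxel bolus amplitude scaling (perfusion-like map);
        only meaningful with a ``BolusParams`` input.
    substeps_per_frame
        Fine substeps per 3-s frame for the input discretization.
    initial
        Magnetization ``(P, L, B)`` at t = 0 (driven input only);
        defaults to the fully relaxed state.

    Returns
    -------
    MetaboliteSeries
        Real-valued signals S_X(i) = M_X(t_i) sin(alpha_X), shaped
        ``(n_timepoints,) + broadcast_shape``.
    """
    k_pl = np.asarray(kp.k_pl, dtype=float)
    k_pb = np.asarray(kp.k_pb, dtype=float)
    if np.any(k_pl < 0) or np.any(k_pb < 0):
        raise ValueError("conversion rates must be >= 0")
    t = acq.time_axis()
    sin_a = {m: np.sin(np.deg2rad(a)) for m, a in acq.flips.items()}
    cos_a = {m: np.cos(np.deg2rad(a)) for m, a in acq.flips.items()}

    if isinstance(input, BolusParams):
        return _simulate_driven(
            input, k_pl, k_pb, kp, acq, t, sin_a, cos_a,
            amplitude_map, substeps_per_frame, initial,
        )
    return _simulate_prescribed(
        np.asarray(input, dtype=float), k_pl, k_pb, kp, acq, t, sin_a, cos_a
    )


def _simulate_driven(
    bolus, k_pl, k_pb, kp, acq, t, sin_a, cos_a, amplitude_map,
    substeps_per_frame, initial=(0.0, 0.0, 0.0),
):
    lam_p = -(1.0 / kp.t1_pyr + k_pl + k_pb)
    lam_l = -1.0 / kp.t1_lac
    lam_b = -1.0 / kp.t1_bic
    shape = np.broadcast_shapes(
        k_pl.shape, k_pb.shape,
        () if amplitude_map is None else np.shape(amplitude_map),
    )
    amp = np.ones(shape) if amplitude_map is None else np.broadcast_to(
        np.asarray(amplitude_map, dtype=float), shape
    )

    dt = acq.temporal_resolution / substeps_per_frame
    prop = _substep_propagator(lam_p, lam_l, lam_b, k_pl, k_pb, dt)

    P = np.full(shape, float(initial[0]))
    L = np.full(shape, float(initial[1]))
    B = np.full(shape, float(initial[2]))

    def advance(P, L, B, t0, n_steps, prop, dt):
        e_pp, e_ll, e_bb, e_lp, e_bp, psi_p, psi_l, psi_b = prop
        for k in range(n_steps):
            u = simulate_bolus(bolus, np.array(t0 + (k + 0.5) * dt)) * amp
            L = e_ll * L + e_lp * P + psi_l * u
            B = e_bb * B + e_bp * P + psi_b * u
            P = e_pp * P + psi_p * u
        return P, L, B

    # evolve from injection (t = 0) to the first sample
    delay = float(t[0])
    n_pre = int(np.floor(delay / dt + 1e-9))
    P, L, B = advance(P, L, B, 0.0, n_pre, prop, dt)
    rem = delay - n_pre * dt
    if rem > 1e-12:
        prop_rem = _substep_propagator(lam_p, lam_l, lam_b, k_pl, k_pb, rem)
        P, L, B = advance(P, L, B, n_pre * dt, 1, prop_rem, rem)

    n_t = acq.n_timepoints
    out = {m: np.empty((n_t,) + shape) for m in ("pyr", "lac", "bic")}
    for i in range(n_t):
        out["pyr"][i] = P * sin_a["pyr"]
        out["lac"][i] = L * sin_a["lac"]
        out["bic"][i] = B * sin_a["bic"]
        P = P * cos_a["pyr"]
        L = L * cos_a["lac"]
        B = B * cos_a["bic"]
        if i < n_t - 1:
            P, L, B = advance(P, L, B, t[i], substeps_per_frame, prop, dt)

    return MetaboliteSeries(
        pyr=out["pyr"], lac=out["lac"], bic=out["bic"], time=t, acq=acq
    )


def _simulate_prescribed(pmag, k_pl, k_pb, kp, acq, t, sin_a, cos_a):
    """Product-pool evolution driven by a prescribed pyruvate trace."""
    if pmag.shape[0] != acq.n_timepoints:
        raise ValueError("pyruvate trace length must equal n_timepoints")
    lam_l = -1.0 / kp.t1_lac
    lam_b = -1.0 / kp.t1_bic
    dt = acq.temporal_resolution
    shape = np.broadcast_shapes(k_pl.shape, k_pb.shape, pmag.shape[1:])
    n_t = acq.n_timepoints

    out = {m: np.zeros((n_t,) + shape) for m in ("pyr", "lac", "bic")}
    L = np.zeros(shape)
    B = np.zeros(shape)
    for i in range(n_t):
        out["pyr"][i] = pmag[i] * sin_a["pyr"]
        out["lac"][i] = L * sin_a["lac"]
        out["bic"][i] = B * sin_a["bic"]
        if i == n_t - 1:
            break
        # pyruvate within the interval: linear from post-flip value to the
        # next sampled value
        p0 = pmag[i] * cos_a["pyr"]
        p1 = pmag[i + 1]
        g0_l, g1_l = _linear_drive(lam_l, dt)
        g0_b, g1_b = _linear_drive(lam_b, dt)
        L = L * cos_a["lac"] * np.exp(lam_l * dt) + k_pl * (
            p0 * g0_l + (p1 - p0) / dt * g1_l
        )
        B = B * cos_a["bic"] * np.exp(lam_b * dt) + k_pb * (
            p0 * g0_b + (p1 - p0) / dt * g1_b
        )
    return MetaboliteSeries(
        pyr=out["pyr"], lac=out["lac"], bic=out["bic"], time=t, acq=acq
    )


def _linear_drive(lam, dt):
    """Moments int e^{lam(dt-s)} ds and int s e^{lam(dt-s)} ds over [0, dt]."""
    g0 = _int_exp(lam, dt)
    if abs(lam) * dt < 1e-8:
        return g0, dt**2 / 2.0
    # int_0^dt s e^{lam (dt - s)} ds ; substitute x = dt - s:
    #   = int_0^dt (dt - x) e^{lam x} dx = dt*g0 - (dt e^{lam dt} - g0)/lam
    g1 = dt * g0 - (dt * np.exp(lam * dt) - g0) / lam
    return g0, g1


# ---------------------------------------------------------------------------
# multichannel synthesis
# ---------------------------------------------------------------------------

def default_coil_profiles(
    n_channels: int, volume_shape: tuple[int, int, int], seed: int = 0
) -> np.ndarray:
    """Smooth complex channel sensitivities, shape (channel, slice, row, col).

    Each channel is a Gaussian sensitivity lobe centered on the volume
    periphery with a slowly varying phase, loosely emulating a receive
    array around the head.
    """
    rng = np.random.default_rng(seed)
    ns, nr, nc = volume_shape
    z, r, c = np.mgrid[:ns, :nr, :nc].astype(float)
    profiles = np.empty((n_channels, ns, nr, nc), dtype=complex)
    angles = 2 * np.pi * np.arange(n_channels) / n_channels
    for ch, th in enumerate(angles):
        center = np.array(
            [
                (ns - 1) / 2,
                (nr - 1) / 2 + 0.6 * (nr / 2) * np.sin(th),
                (nc - 1) / 2 + 0.6 * (nc / 2) * np.cos(th),
            ]
        )
        d2 = (z - center[0]) ** 2 + (r - center[1]) ** 2 + (c - center[2]) ** 2
        mag = np.exp(-d2 / (2 * (0.6 * max(nr, nc)) ** 2))
        phase = rng.uniform(-np.pi, np.pi) + 0.02 * (r - center[1]) + 0.02 * (
            c - center[2]
        )
        profiles[ch] = mag * np.exp(1j * phase)
    return profiles


def synthesize_multichannel(
    series: MetaboliteSeries,
    coil_profiles: np.ndarray,
    noise: NoiseModel,
    seed: int,
) -> RawDynamic:
    """Project a noiseless series onto coil profiles and add correlated noise.

    The complex channel data are ``profile[c] * signal`` plus circular
    complex Gaussian noise with channel covariance
    ``noise_scale**2 * channel_covariance``.  Signal-free timepoints
    (all-metabolite zero frames, typically the pre-arrival samples) are
    designated as noise frames; if none exist a dedicated trailing noise
    frame is appended and flagged.
    """
    profiles = np.asarray(coil_profiles)
    if profiles.shape[0] != noise.n_channels:
        raise ValueError(
            f"{profiles.shape[0]} coil profiles vs "
            f"{noise.n_channels}-channel covariance"
        )
    L = noise.cholesky()  # raises if not positive-definite
    rng = np.random.default_rng(seed)

    stacked = series.stack()  # (metab, time, slice, row, col)
    signal_free = [
        int(i) for i in range(stacked.shape[1])
        if np.all(stacked[:, i] == 0)
    ]
    n_t = stacked.shape[1]
    append = len(signal_free) == 0

    data: dict[str, np.ndarray] = {}
    for mi, m in enumerate(("pyr", "lac", "bic")):
        sig = np.einsum("czyx,tzyx->ctzyx", profiles, stacked[mi])
        if append:
            sig = np.concatenate([sig, np.zeros_like(sig[:, :1])], axis=1)
        if noise.noise_scale > 0:
            w = rng.standard_normal(sig.shape + (2,)) @ np.array([1.0, 1.0j])
            w *= np.sqrt(0.5)  # unit-variance circular complex
            colored = np.einsum("ij,jtzyx->itzyx", L, w) * noise.noise_scale
            sig = sig + colored
        data[m] = sig

    noise_frames = [n_t] if append else signal_free
    acq = series.acq if series.acq is not None else AcquisitionParams(
        n_timepoints=n_t
    )
    return RawDynamic(
        data=data,
        acq=acq,
        noise_frames=noise_frames,
        appended_noise_frame=append,
    )
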