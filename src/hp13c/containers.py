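"""Shared data containers for the hyperpolarized-13C analysis pipeline.

Axis convention throughout the package: volumes are indexed
``(slice, row, column)`` with 0-based indices; dynamic volumes prepend a
time axis ``(time, slice, row, column)``; raw multichannel data prepend a
channel axis ``(channel, time, slice, row, column)``.  The mid-sagittal
plane is the column-axis midplane; volumes with an even column count
reflect about the half-integer center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "AcquisitionParams",
    "BolusParams",
    "KineticParams",
    "PhantomROISet",
    "NoiseModel",
    "RawDynamic",
    "MetaboliteSeries",
    "KineticFitResult",
    "KineticMap",
    "METABOLITES",
]

#: Canonical metabolite order used for stacked tensors and loops.
METABOLITES = ("pyr", "lac", "bic")


@dataclass
class AcquisitionParams:
    """Dynamic EPI acquisition schedule and flip-angle scheme.

    Defaults mirror a metabolite-selective 2D multislice EPI readout:
    20 timepoints at 3 s temporal resolution (60 s total), flip angles
    (20, 30, 30) degrees for pyruvate/lactate/bicarbonate, 16x16 in-plane
    matrix over a 24 cm FOV, 1032 us echo spacing, 8 slices.
    """

    n_timepoints: int = 20
    temporal_resolution: float = 3.0  # s
    acquisition_delay: float = 2.0  # s after injection end
    flip_pyr: float = 20.0  # degrees
    flip_lac: float = 30.0
    flip_bic: float = 30.0
    matrix_n: int = 16
    fov: float = 24.0  # cm
    echo_spacing: float = 1032e-6  # s
    n_slices: int = 8

    def __post_init__(self) -> None:
        if self.n_timepoints < 1 or self.matrix_n < 1 or self.n_slices < 1:
            raise ValueError("counts must be >= 1")
        if self.temporal_resolution <= 0:
            raise ValueError("temporal_resolution must be > 0")
        if self.echo_spacing <= 0:
            raise ValueError("echo_spacing must be > 0")
        for name in ("flip_pyr", "flip_lac", "flip_bic"):
            a = getattr(self, name)
            if not 0 < a < 90:
                raise ValueError(f"{name} must lie in (0, 90) degrees, got {a}")

    @property
    def flips(self) -> dict[str, float]:
        return {"pyr": self.flip_pyr, "lac": self.flip_lac, "bic": self.flip_bic}

    def time_axis(self) -> np.ndarray:
        """Sample times t_i = acquisition_delay + i * temporal_resolution."""
        return self.acquisition_delay + self.temporal_resolution * np.arange(
            self.n_timepoints, dtype=float
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)


@dataclass
class BolusParams:
    """Gamma-variate pyruvate input: A * (t-t0)^alpha * exp(-(t-t0)/beta).

    A synthetic stand-in for the in-vivo arterial input; smooth and
    unimodal, zero before ``arrival_time``, peaking at t0 + alpha*beta.
    """

    arrival_time: float = 4.0  # s
    alpha: float = 2.5  # gamma shape, dimensionless
    beta: float = 3.5  # gamma scale, s
    amplitude: float = 1.0  # peak signal, arbitrary units

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def peak_time(self) -> float:
        return self.arrival_time + self.alpha * self.beta


@dataclass
class KineticParams:
    """Two-site exchange rates and longitudinal relaxation times.

    k_pl and k_pb are the apparent first-order rates (1/s) for
    pyruvate->lactate and pyruvate->bicarbonate conversion.  T1 defaults
    (pyruvate 30 s, lactate 25 s, bicarbonate 25 s) are configurable
    model assumptions.
    """

    k_pl: float = 0.015
    k_pb: float = 0.003
    t1_pyr: float = 30.0
    t1_lac: float = 25.0
    t1_bic: float = 25.0

    def __post_init__(self) -> None:
        if self.k_pl < 0 or self.k_pb < 0:
            raise ValueError("conversion rates must be >= 0")
        if min(self.t1_pyr, self.t1_lac, self.t1_bic) <= 0:
            raise ValueError("T1 values must be > 0")


@dataclass
class PhantomROISet:
    """Binary ROI volumes on a common (slice, row, column) grid."""

    brain_mask: np.ndarray
    nawm_mask: np.ndarray
    gm_mask: np.ndarray
    t2_lesion_mask: np.ndarray
    tumor_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)

    def __post_init__(self) -> None:
        shape = self.brain_mask.shape
        for name in ("nawm_mask", "gm_mask", "t2_lesion_mask", "tumor_mask"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} != brain {shape}")
        if np.any(self.nawm_mask & self.t2_lesion_mask):
            raise ValueError("NAWM and T2-lesion masks must be disjoint")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.brain_mask.shape


@dataclass
class NoiseModel:
    """Complex circular Gaussian channel noise with a full covariance."""

    channel_covariance: np.ndarray  # (n_channels, n_channels), Hermitian PD
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.channel_covariance)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("channel_covariance must be square")
        if not np.allclose(c, c.conj().T, atol=1e-10 * max(1.0, np.abs(c).max())):
            raise ValueError("channel_covariance must be Hermitian")
        self.channel_covariance = c

    @property
    def n_channels(self) -> int:
        return self.channel_covariance.shape[0]

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor L with cov = L @ L^H; errors if not PD."""
        try:
            return np.linalg.cholesky(self.channel_covariance)
        except np.linalg.LinAlgError as e:
            raise ValueError("channel covariance is not positive-definite") from e


@dataclass
class RawDynamic:
    """Multichannel complex dynamic data, one 5-D array per metabolite.

    ``data[m]`` has shape (channel, time, slice, row, column).
    ``noise_frames`` indexes signal-free timepoints usable for noise
    covariance estimation; ``appended_noise_frame`` marks a dedicated
    trailing noise frame that is not part of the dynamic schedule.
    """

    data: dict[str, np.ndarray]
    acq: AcquisitionParams
    noise_frames: list[int] = field(default_factory=list)
    appended_noise_frame: bool = False

    def __post_init__(self) -> None:
        shapes = {m: a.shape for m, a in self.data.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"metabolite arrays disagree in shape: {shapes}")
        for m, a in self.data.items():
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in raw data for {m}")
        expected_t = self.acq.n_timepoints + (1 if self.appended_noise_frame else 0)
        t = next(iter(self.data.values())).shape[1]
        if t != expected_t:
            raise ValueError(f"time dim {t} != expected {expected_t}")

    @property
    def n_channels(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.acq.n_timepoints


@dataclass
class MetaboliteSeries:
    """Channel-combined per-metabolite dynamic volumes on one time axis.

    Arrays have shape (time, slice, row, column).  Before phasing the
    arrays are complex; after phasing they are real.  ``noise_sd`` is the
    per-sample noise standard deviation of the combined data (estimated
    from noise frames) and ``invalid_mask`` flags voxels where channel
    combination was undefined (all-zero pyruvate).
    """

    pyr: np.ndarray
    lac: np.ndarray
    bic: np.ndarray
    time: np.ndarray  # (n_timepoints,), seconds
    acq: AcquisitionParams | None = None
    noise_sd: float | None = None
    invalid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.pyr.shape == self.lac.shape == self.bic.shape):
            raise ValueError("metabolite arrays must share one shape")
        if self.pyr.shape[0] != len(self.time):
            raise ValueError("time axis length != time dimension")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0 once estimated")

    def __getitem__(self, metabolite: str) -> np.ndarray:
        return getattr(self, metabolite)

    @property
    def volume_shape(self) -> tuple[int, ...]:
        return self.pyr.shape[1:]

    def stack(self) -> np.ndarray:
        """Stack to (metabolite, time, slice, row, column) in canonical order."""
        return np.stack([self.pyr, self.lac, self.bic])

    def replace_data(self, stacked: np.ndarray) -> "MetaboliteSeries":
        return MetaboliteSeries(
            pyr=stacked[0], lac=stacked[1], bic=stacked[2],
            time=self.time, acq=self.acq, noise_sd=self.noise_sd,
            invalid_mask=self.invalid_mask,
        )


@dataclass
class KineticFitResult:
    """Single-voxel joint fit of k_PL and k_PB with fractional errors."""

    k_pl: float
    k_pb: float
    k_pl_error: float  # standard error as a fraction of k_pl
    k_pb_error: float
    fitted_lac: np.ndarray
    fitted_bic: np.ndarray
    residual_sse: float
    converged: bool = True


@dataclass
class KineticMap:
    """Voxelwise rate-constant maps with error maps and validity mask."""

    k_pl: np.ndarray
    k_pb: np.ndarray
    k_pl_error: np.ndarray
    k_pb_error: np.ndarray
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = np.isfinite(self.k_pl) & np.isfinite(self.k_pb)
        if np.any(self.valid_mask & ~finite):
            raise ValueError("valid_mask includes voxels with non-finite fits")
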