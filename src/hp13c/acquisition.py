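"""Frequency referencing, excitation response, EPI timing, and injection QC.

Utilities around the metabolite-selective EPI acquisition: deriving the
pyruvate center frequency from a urea or water reference, the spectral
response of the narrowband excitation pulse, phase-encode voxel
bandwidth and off-resonance pixel shift, the dynamic sampling schedule,
and the pharmacy quality-control gate applied before tracer injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AcquisitionParams

__all__ = [
    "UREA_TO_PYR_OFFSET_HZ",
    "WATER_TO_PYR_RATIO",
    "FrequencyReference",
    "QCRecord",
    "QCResult",
    "f0_from_urea",
    "f0_from_water",
    "excitation_response",
    "voxel_bandwidth",
    "pixel_shift",
    "timing",
    "qc_check",
]

#: Chemical-shift offset of [1-13C]pyruvate relative to [13C]urea at 3 T.
UREA_TO_PYR_OFFSET_HZ = 270.0

#: Empirical 1H->13C gyromagnetic conversion ratio relating the water
#: center frequency to the pyruvate center frequency.
WATER_TO_PYR_RATIO = 0.251491899


@dataclass
class FrequencyReference:
    """A pyruvate center-frequency estimate and its provenance."""

    method: str  # "urea" or "water"
    reference_frequency: float  # Hz
    derived_f0_pyr: float  # Hz
    offset_observed: float | None = None  # Hz, from post-imaging spectroscopy


def f0_from_urea(f_urea: float) -> float:
    """Pyruvate center frequency from a coil-embedded urea reference.

    The pyruvate resonance sits 270 Hz above urea at this field strength.
    """
    if not np.isfinite(f_urea):
        raise ValueError("reference frequency must be finite")
    return float(f_urea) + UREA_TO_PYR_OFFSET_HZ


def f0_from_water(f_water: float) -> float:
    """Pyruvate center frequency from the proton water center frequency.

    Applies the empirical gyromagnetic conversion ratio 0.251491899.
    """
    if not (np.isfinite(f_water) and f_water > 0):
        raise ValueError("water center frequency must be positive and finite")
    return float(f_water) * WATER_TO_PYR_RATIO


def excitation_response(offset, fwhm: float = 130.0):
    """Fractional transverse magnetization at a spectral offset.

    Gaussian passband model of the spectral-spatial excitation pulse,
    ``M_xy = exp(-4 ln2 * offset^2 / FWHM^2)``, parameterized by the
    pulse's 130 Hz full width at half maximum.  This models the pulse's
    passband, not a measured profile; a user-supplied response can be
    used in its place wherever a callable is accepted.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    offset = np.asarray(offset, dtype=float)
    out = np.exp(-4.0 * np.log(2.0) * offset**2 / fwhm**2)
    return float(out) if out.ndim == 0 else out


def voxel_bandwidth(matrix_n: int, echo_spacing: float) -> float:
    """Per-voxel bandwidth (Hz) along the EPI phase-encode direction.

    Equals ``1 / (matrix_n * echo_spacing)``: the reciprocal of the time
    to traverse k-space once in the phase-encode direction.
    """
    if matrix_n < 1:
        raise ValueError("matrix_n must be >= 1")
    if echo_spacing <= 0:
        raise ValueError("echo_spacing must be > 0")
    return 1.0 / (matrix_n * echo_spacing)


def pixel_shift(offset: float, voxel_bw: float) -> tuple[float, bool]:
    """Signed voxel displacement from off-resonance, with a correction flag.

    Off-resonance shifts EPI data along the phase-encode direction by
    ``offset / voxel_bw`` voxels.  A magnitude strictly greater than half
    a voxel (half the voxel bandwidth) flags that correction is needed.
    """
    if voxel_bw <= 0:
        raise ValueError("voxel bandwidth must be > 0")
    shift = float(offset) / float(voxel_bw)
    return shift, bool(abs(shift) > 0.5)


def timing(acq: AcquisitionParams) -> tuple[np.ndarray, float]:
    """Sample time axis and total dynamic duration for a schedule.

    ``t_i = acquisition_delay + i * temporal_resolution``; the dynamic
    acquisition spans ``n_timepoints * temporal_resolution`` seconds.
    """
    return acq.time_axis(), acq.n_timepoints * acq.temporal_resolution


# ---------------------------------------------------------------------------
# injection QC
# ---------------------------------------------------------------------------

@dataclass
class QCRecord:
    """Pre-injection pharmacy quality-control measurements."""

    polarization: float  # percent
    pyruvate_concentration: float  # mM
    epa_concentration: float  # uM electron paramagnetic agent
    ph: float
    temperature: float  # degrees C
    volume: float  # mL
    bubble_point_passed: bool


@dataclass
class QCResult:
    passed: bool
    violations: list[str] = field(default_factory=list)


def qc_check(record: QCRecord) -> QCResult:
    """Apply the injection release criteria and list any violations.

    Pass requires: polarization >= 15%, pyruvate concentration within
    220-280 mM, EPA <= 3.0 uM, pH within 5.0-9.0, temperature within
    25-37 C, volume strictly > 38 mL, and a passed bubble-point test.
    Range endpoints are inclusive except the volume bound, which is
    strict.
    """
    for name in (
        "polarization", "pyruvate_concentration", "epa_concentration",
        "ph", "temperature", "volume",
    ):
        v = getattr(record, name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"QC field {name!r} is missing or non-finite")
    violations = []
    if record.polarization < 15.0:
        violations.append(f"polarization {record.polarization}% < 15%")
    if not 220.0 <= record.pyruvate_concentration <= 280.0:
        violations.append(
            f"pyruvate concentration {record.pyruvate_concentration} mM "
            "outside [220, 280]"
        )
    if record.epa_concentration > 3.0:
        violations.append(f"EPA {record.epa_concentration} uM > 3.0")
    if not 5.0 <= record.ph <= 9.0:
        violations.append(f"pH {record.ph} outside [5.0, 9.0]")
    if not 25.0 <= record.temperature <= 37.0:
        violations.append(f"temperature {record.temperature} C outside [25, 37]")
    if not record.volume > 38.0:
        violations.append(f"volume {record.volume} mL not > 38")
    if not record.bubble_point_passed:
        violations.append("bubble point test failed")
    return QCResult(passed=not violations, violations=violations)
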