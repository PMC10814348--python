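"""Frequency referencing, excitation response, and the injection QC gate.

Shows the two pyruvate center-frequency referencing rules, how far an
off-resonance excitation degrades the transverse magnetization of the
130-Hz-FWHM spectral-spatial pulse, the phase-encode voxel bandwidth of
the EPI readout, and the pharmacy release criteria.
"""

from hp13c import (
    QCRecord,
    excitation_response,
    f0_from_urea,
    f0_from_water,
    pixel_shift,
    qc_check,
    voxel_bandwidth,
)

f_water = 127_730_000.0
print(f"water reference {f_water:.0f} Hz -> f0(pyruvate) = {f0_from_water(f_water):,.1f} Hz")
print(f"urea reference 32,000,000 Hz -> f0(pyruvate) = {f0_from_urea(32_000_000.0):,.1f} Hz")

for off in (0.0, 16.0, 65.0):
    print(f"excitation at {off:5.1f} Hz off-resonance: M_xy = {excitation_response(off):.3f}")

bw = voxel_bandwidth(16, 1032e-6)
shift, flagged = pixel_shift(10.0, bw)
print(f"voxel bandwidth = {bw:.3f} Hz; a 10 Hz offset shifts the image by "
      f"{shift:.3f} voxels (correction needed: {flagged})")

record = QCRecord(polarization=28.0, pyruvate_concentration=245.0,
                  epa_concentration=1.2, ph=7.4, temperature=31.0,
                  volume=41.0, bubble_point_passed=True)
print(f"QC pass: {qc_check(record).passed}")
bad = QCRecord(polarization=12.0, pyruvate_concentration=245.0,
               epa_concentration=1.2, ph=7.4, temperature=31.0,
               volume=41.0, bubble_point_passed=True)
print(f"QC violations: {qc_check(bad).violations}")
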