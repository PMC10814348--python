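"""Acquisition-delay simulation: what a late start does to kinetics.

Spline-interpolated complete-capture metabolite traces are shifted in
0.1-s steps and resampled at the native 3-s resolution; %Inflow and the
kinetic fit are recomputed at each shift.  As the captured inflow
drops, the fitted rates are systematically overestimated and the fit
errors grow steeply.
"""

import numpy as np

from hp13c import AcquisitionParams, BolusParams, KineticParams
from hp13c import simulate_delay_sweep, simulate_two_site

acq = AcquisitionParams(acquisition_delay=2.0, n_timepoints=20)
t1 = KineticParams(t1_pyr=12.0)  # apparent decay incl. washout for the reference trace
kp = KineticParams(t1_pyr=12.0)
kp.k_pl = np.full((2, 2, 2), 0.015)
kp.k_pb = np.full((2, 2, 2), 0.003)
series = simulate_two_site(BolusParams(arrival_time=3.0, alpha=3.0, beta=2.5), kp, acq)

sweep = simulate_delay_sweep(series, np.ones((2, 2, 2)), max_delay=11.0,
                             thresholds=(0.30,), t1=t1)

print("extra delay   %Inflow   rel k_PL   k_PL error")
for d in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0):
    i = int(round(d / 0.1))
    print(f"{d:8.1f} s   {sweep.percent_inflow[0.30][i]:7.1f}   "
          f"{sweep.rel_k_pl[0.30][i]:8.3f}   {sweep.k_pl_error[0.30][i]:9.4f}")
print("rel k_PL = 1 means the fit matches the complete-capture reference;")
print("values > 1 quantify the overestimation caused by missing the bolus rise.")
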