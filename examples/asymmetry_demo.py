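"""Hemispheric asymmetry scoring of a rate-constant map.

A mirror-symmetric map scores S = 0; adding a one-sided focal
elevation (a synthetic 'lesion' in apparent kinetics) raises S in
proportion to the perturbation.
"""

import numpy as np

from hp13c import global_asymmetry, local_asymmetry, prepare_map

rng = np.random.default_rng(0)
base = rng.standard_normal((2, 10, 10))
base = (base + base[:, :, ::-1]) / 2  # force left-right symmetry
brain = np.ones(base.shape, dtype=bool)

prep = prepare_map(base, brain)
print(f"mirror-symmetric map: S = {global_asymmetry(local_asymmetry(prep, 1.0)).S:.6f}")

for amp in (0.5, 1.0, 2.0):
    m = base.copy()
    m[0, 5, 2] += amp  # focal left-hemisphere elevation
    prep = prepare_map(m, brain)
    res = global_asymmetry(local_asymmetry(prep, 1.0))
    print(f"perturbation +{amp:.1f}: S = {res.S:.4f} over {res.n_points} points")
print("S grows with the one-sided perturbation; per-slice values are in S_per_slice.")
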