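"""Simulate DWI signals from a known tensor, fit, and compare metrics.

Noiseless signals recover the ground truth to numerical precision; with
Rician noise at SNR 25 the fitted metrics scatter around it.
"""

import numpy as np

from dtiq import (
    DiffusionTensor,
    add_rician_noise,
    eigen_decompose,
    fit_tensor_loglinear,
    make_gradient_scheme,
    scalar_metrics,
    simulate_signal,
)

truth = DiffusionTensor(1.7e-3, 0.3e-3, 0.2e-3).as_array()
scheme = make_gradient_scheme(n_directions=30, b_value=1000.0, seed=0)
clean = simulate_signal(truth, scheme, s0=1000.0)

m_true = scalar_metrics(eigen_decompose(truth).eigenvalues)
fit = fit_tensor_loglinear(clean, scheme)
m_fit = scalar_metrics(eigen_decompose(fit.tensor).eigenvalues)
print("noiseless round trip:")
print(f"  true FA = {m_true.fa:.10f}   fitted FA = {m_fit.fa:.10f}")
print(f"  max |component error| = {np.max(np.abs(fit.tensor - truth)):.2e} mm^2/s")

noisy = add_rician_noise(np.tile(clean, (500, 1)), sigma=40.0, seed=1)
fits = fit_tensor_loglinear(noisy, scheme)
ev = eigen_decompose(fits.tensor).eigenvalues
from dtiq import compute_fa, compute_q

print("\n500 noisy replicate voxels (SNR 25):")
print(f"  FA: true {m_true.fa:.3f}, fitted median {np.median(compute_fa(ev)):.3f}")
print(f"  q : true {m_true.q * 1e3:.3f}, fitted median "
      f"{np.median(compute_q(ev)) * 1e3:.3f}  [10^-3 mm^2/s]")
print(f"  non-physical voxels: {int(fits.nonphysical.sum())}")
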