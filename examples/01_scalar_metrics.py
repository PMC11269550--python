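"""Compute the four tensor scalars (MD, FA, L, q) for a single voxel.

A white-matter-like tensor with eigenvalues (1.7, 0.3, 0.2) x 10^-3
mm^2/s is decomposed and summarised.  MD is the eigenvalue mean, L the
total diffusion magnitude (Frobenius norm), q the pure anisotropy
(eigenvalue dispersion about the mean) and FA = sqrt(3/2) q / L their
dimensionless ratio.
"""

import numpy as np

from dtiq import DiffusionTensor, eigen_decompose, scalar_metrics

tensor = DiffusionTensor(dxx=1.7e-3, dyy=0.3e-3, dzz=0.2e-3)
spectrum = eigen_decompose(tensor)
m = scalar_metrics(spectrum.eigenvalues)

print("eigenvalues [mm^2/s]:", spectrum.eigenvalues)
print(f"MD = {m.md:.6e} mm^2/s   (overall diffusivity)")
print(f"L  = {m.l:.6e} mm^2/s   (total diffusion magnitude)")
print(f"q  = {m.q:.6e} mm^2/s   (pure anisotropy)")
print(f"FA = {m.fa:.4f}            (normalized anisotropy, 0..1)")
print("identity check q^2 + 3 MD^2 - L^2 =", m.q**2 + 3 * m.md**2 - m.l**2)
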