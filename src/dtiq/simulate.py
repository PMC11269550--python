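"""DWI acquisition-scheme and signal simulation primitives.

The forward model is the standard monoexponential tensor signal,

    S(b, g) = S0 * exp(-b * g^T D g),

with magnitude-MRI noise modelled as Rician: the noise-free signal is
placed on the real axis of the complex plane, independent Gaussian noise
of standard deviation sigma is added to both quadratures, and the
magnitude is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tensors import DiffusionTensor, eigen_decompose, matrix_from_tensor

__all__ = [
    "GradientScheme",
    "make_gradient_scheme",
    "simulate_signal",
    "add_rician_noise",
]

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: b-values (s/mm^2) and unit directions.

    Contains at least one b = 0 entry plus >= 6 non-collinear nonzero-b
    directions so the tensor (6 components + log S0) is identifiable.
    b = 0 entries carry a zero direction vector by convention.
    """

    bvals: np.ndarray  # (N,)
    bvecs: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"inconsistent scheme shapes: bvals {bvals.shape}, bvecs {bvecs.shape}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if not np.any(bvals == 0):
            raise ValueError("scheme requires at least one b = 0 entry")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > _NORM_TOL):
            raise ValueError("nonzero-b directions must be unit vectors")
        if nz.sum() < 6:
            raise ValueError("tensor identifiability requires >= 6 nonzero-b directions")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    def to_files(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        """Write FSL-dialect text files (one row of b-values; three rows of
        x/y/z direction components)."""
        Path(bval_path).write_text(
            " ".join(f"{b:.6g}" for b in self.bvals) + "\n"
        )
        rows = []
        for axis in range(3):
            rows.append(" ".join(f"{v:.10f}" for v in self.bvecs[:, axis]))
        Path(bvec_path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_files(cls, bval_path: str | Path, bvec_path: str | Path) -> "GradientScheme":
        bvals = np.loadtxt(bval_path, ndmin=1)
        bvecs = np.loadtxt(bvec_path, ndmin=2)
        if bvecs.shape[0] == 3:  # FSL stores directions as three rows
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors via the spherical Fibonacci
    spiral, folded onto a hemisphere (antipodal directions are equivalent
    for diffusion encoding)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    # spread points over the full sphere, then fold z < 0 to z >= 0
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    flip = pts[:, 2] < 0
    pts[flip] *= -1
    return pts


def _electrostatic_repulsion(points: np.ndarray, n_iter: int = 120) -> np.ndarray:
    """Relax unit vectors under antipodally-symmetric Coulomb repulsion
    (each point repels every other point and its antipode), the standard
    criterion for uniform diffusion-encoding directions.  Also breaks the
    ring degeneracies a pure spiral layout can have at small n."""
    p = points.copy()
    n = len(p)
    step = 0.05
    for _ in range(n_iter):
        diff_m = p[:, None, :] - p[None, :, :]
        diff_p = p[:, None, :] + p[None, :, :]
        dist_m = np.linalg.norm(diff_m, axis=-1)
        dist_p = np.linalg.norm(diff_p, axis=-1)
        np.fill_diagonal(dist_m, np.inf)
        np.fill_diagonal(dist_p, np.inf)
        force = (diff_m / dist_m[..., None] ** 3).sum(axis=1) + (
            diff_p / dist_p[..., None] ** 3
        ).sum(axis=1)
        # project onto the tangent plane and take a normalized step
        force -= (force * p).sum(axis=1, keepdims=True) * p
        norms = np.linalg.norm(force, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        p = p + step * force / norms
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        step *= 0.97
    return p


def make_gradient_scheme(
    n_directions: int = 30, b_value: float = 1000.0, seed: int = 0
) -> GradientScheme:
    """Build a single-shell scheme: one b = 0 volume plus ``n_directions``
    approximately uniform unit directions at ``b_value``.

    Directions start on a deterministic Fibonacci spiral, are relaxed by
    antipodally-symmetric electrostatic repulsion, and are finally rotated
    by a random rotation drawn from ``seed`` — different seeds give
    distinct but equally uniform schemes.

    Raises
    ------
    ValueError
        If ``n_directions`` < 6 (tensor not identifiable).
    """
    if n_directions < 6:
        raise ValueError("n_directions must be >= 6 for tensor identifiability")
    dirs = _electrostatic_repulsion(_fibonacci_hemisphere(n_directions))
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    a = rng.normal(size=(3, 3))
    qmat, rmat = np.linalg.qr(a)
    qmat *= np.sign(np.diag(rmat))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] *= -1
    dirs = dirs @ qmat.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def simulate_signal(tensor, scheme: GradientScheme, s0: float = 1000.0) -> np.ndarray:
    """Noise-free DWI signals for one or many tensors.

    Parameters
    ----------
    tensor : (...,6) array or DiffusionTensor
        Tensor components in canonical lower-triangular order.
    scheme : GradientScheme
    s0 : baseline (b = 0) signal, > 0.

    Returns
    -------
    (..., N) array of signals; b = 0 entries equal ``s0`` exactly and all
    signals lie in (0, s0] for physical tensors.

    Notes
    -----
    Non-physical tensors (negative eigenvalue) are simulated anyway — the
    exponent can then exceed 0 — and reported via ``RuntimeWarning``.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if isinstance(tensor, DiffusionTensor):
        tensor = tensor.as_array()
    t = np.asarray(tensor, dtype=float)
    ev = eigen_decompose(t).eigenvalues
    if np.any(ev[..., -1] < 0):
        import warnings

        warnings.warn(
            "simulating signal from a non-physical tensor (negative eigenvalue)",
            RuntimeWarning,
            stacklevel=2,
        )
    d = matrix_from_tensor(t)  # (...,3,3)
    g = scheme.bvecs  # (N,3)
    # g^T D g for each scheme entry: (...,N)
    quad = np.einsum("ni,...ij,nj->...n", g, d, g)
    return s0 * np.exp(-scheme.bvals * quad)


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Corrupt signals with Rician noise of scale ``sigma``.

    Returns ``sqrt((S + e1)^2 + e2^2)`` with e1, e2 ~ Normal(0, sigma^2)
    i.i.d.  ``sigma = 0`` returns the input unchanged; a fixed seed gives
    bit-identical output.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, size=signal.shape)
    e2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)
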