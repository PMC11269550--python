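"""Diffusion-tensor data model and the four scalar metrics MD, FA, L and q.

A diffusion tensor is a symmetric 3x3 matrix of apparent diffusivities
(units mm^2/s; brain tissue is typically 0.2-2.0 x 10^-3 mm^2/s).  Only six
unique components are stored, in *lower-triangular row order*::

    (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)

All metric definitions act on the eigenvalues lambda_1 >= lambda_2 >=
lambda_3 of that matrix, with lambda_bar their mean:

* ``MD = lambda_bar``                                    (mean diffusivity)
* ``L  = sqrt(l1^2 + l2^2 + l3^2)``                      (total diffusion
  magnitude; equals the Frobenius norm of the tensor)
* ``q  = sqrt((l1-lb)^2 + (l2-lb)^2 + (l3-lb)^2)``       (pure anisotropy)
* ``FA = sqrt(3/2) * q / L``                             (fractional
  anisotropy, dimensionless in [0, 1]; defined as 0 for the zero tensor)

These satisfy the algebraic identity ``q^2 + 3*MD^2 = L^2`` and are
invariant under rotation of the tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TENSOR_COMPONENTS",
    "DiffusionTensor",
    "EigenSpectrum",
    "ScalarMetrics",
    "tensor_from_matrix",
    "matrix_from_tensor",
    "eigen_decompose",
    "compute_md",
    "compute_l",
    "compute_q",
    "compute_fa",
    "scalar_metrics",
    "compute_metric_maps",
]

#: storage order of the six unique tensor components (lower-triangular rows)
TENSOR_COMPONENTS = ("dxx", "dxy", "dyy", "dxz", "dyz", "dzz")

# indices of the diagonal / off-diagonal entries within TENSOR_COMPONENTS
_DIAG = (0, 2, 5)
_OFFDIAG = (1, 3, 4)


@dataclass(frozen=True)
class DiffusionTensor:
    """A single symmetric diffusion tensor (six unique components, mm^2/s)."""

    dxx: float
    dyy: float
    dzz: float
    dxy: float = 0.0
    dxz: float = 0.0
    dyz: float = 0.0

    def as_array(self) -> np.ndarray:
        """Components in canonical lower-triangular order."""
        return np.array(
            [self.dxx, self.dxy, self.dyy, self.dxz, self.dyz, self.dzz]
        )

    def as_matrix(self) -> np.ndarray:
        return matrix_from_tensor(self.as_array())

    @property
    def is_physical(self) -> bool:
        """True when all eigenvalues are non-negative."""
        return bool(np.all(eigen_decompose(self.as_array()).eigenvalues >= 0))


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigenvalues of a diffusion tensor, sorted descending, with their mean."""

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        if not (self.lambda1 >= self.lambda2 >= self.lambda3):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def lambda_bar(self) -> float:
        return (self.lambda1 + self.lambda2 + self.lambda3) / 3.0

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])


@dataclass(frozen=True)
class ScalarMetrics:
    """The four per-voxel scalar metrics."""

    md: float
    fa: float
    l: float
    q: float


def tensor_from_matrix(matrix: np.ndarray) -> np.ndarray:
    """Extract the six unique components from (...,3,3) symmetric matrices."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[-2:] != (3, 3):
        raise ValueError(f"expected (...,3,3) matrices, got {matrix.shape}")
    m = matrix
    return np.stack(
        [m[..., 0, 0], m[..., 1, 0], m[..., 1, 1], m[..., 2, 0], m[..., 2, 1], m[..., 2, 2]],
        axis=-1,
    )


def matrix_from_tensor(tensor: np.ndarray) -> np.ndarray:
    """Expand (...,6) component arrays to full symmetric (...,3,3) matrices."""
    t = np.asarray(tensor, dtype=float)
    if t.shape[-1] != 6:
        raise ValueError(f"expected (...,6) tensor components, got {t.shape}")
    dxx, dxy, dyy, dxz, dyz, dzz = (t[..., i] for i in range(6))
    row0 = np.stack([dxx, dxy, dxz], axis=-1)
    row1 = np.stack([dxy, dyy, dyz], axis=-1)
    row2 = np.stack([dxz, dyz, dzz], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def _as_components(tensor) -> np.ndarray:
    if isinstance(tensor, DiffusionTensor):
        return tensor.as_array()
    return np.asarray(tensor, dtype=float)


class _Spectra:
    """Eigen-spectra of a batch of tensors (descending eigenvalues)."""

    __slots__ = ("eigenvalues", "eigenvectors")

    def __init__(self, eigenvalues: np.ndarray, eigenvectors: np.ndarray | None):
        self.eigenvalues = eigenvalues
        self.eigenvectors = eigenvectors

    @property
    def lambda_bar(self) -> np.ndarray:
        return self.eigenvalues.mean(axis=-1)

    def as_spectrum(self) -> EigenSpectrum:
        if self.eigenvalues.shape != (3,):
            raise ValueError("as_spectrum() only applies to a single tensor")
        l1, l2, l3 = self.eigenvalues
        return EigenSpectrum(float(l1), float(l2), float(l3))


def eigen_decompose(tensor, return_vectors: bool = False) -> _Spectra:
    """Eigenvalues (and optionally eigenvectors) of symmetric tensors.

    Parameters
    ----------
    tensor : (...,6) array or DiffusionTensor
        Components in canonical lower-triangular order.
    return_vectors : bool
        Also return eigenvectors (columns matched to eigenvalues).

    Returns
    -------
    _Spectra with ``eigenvalues`` sorted descending along the last axis.
    """
    t = _as_components(tensor)
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor components must be finite")
    m = matrix_from_tensor(t)
    if return_vectors:
        w, v = np.linalg.eigh(m)  # ascending
        return _Spectra(w[..., ::-1], v[..., :, ::-1])
    w = np.linalg.eigvalsh(m)
    return _Spectra(w[..., ::-1], None)


def _evals(spec) -> np.ndarray:
    if isinstance(spec, EigenSpectrum):
        return spec.eigenvalues
    if isinstance(spec, _Spectra):
        return spec.eigenvalues
    return np.asarray(spec, dtype=float)


def compute_md(spec) -> np.ndarray | float:
    """Mean diffusivity: the eigenvalue mean lambda_bar (= trace/3)."""
    return _evals(spec).mean(axis=-1)


def compute_l(spec) -> np.ndarray | float:
    """Total diffusion magnitude L = sqrt(sum lambda_i^2) (Frobenius norm)."""
    ev = _evals(spec)
    return np.sqrt((ev**2).sum(axis=-1))


def compute_q(spec) -> np.ndarray | float:
    """Pure anisotropy q = sqrt(sum (lambda_i - lambda_bar)^2).

    Zero iff the tensor is isotropic; invariant under adding a constant to
    all eigenvalues.
    """
    ev = _evals(spec)
    dev = ev - ev.mean(axis=-1, keepdims=True)
    return np.sqrt((dev**2).sum(axis=-1))


def compute_fa(spec) -> np.ndarray | float:
    """Fractional anisotropy FA = sqrt(3/2) * q / L, clamped to [0, 1].

    Defined as 0 at the zero tensor (continuous limit convention).
    """
    ev = _evals(spec)
    l = compute_l(ev)
    q = compute_q(ev)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.where(l > 0, q / np.where(l > 0, l, 1.0), 0.0)
    return np.clip(fa, 0.0, 1.0)


def scalar_metrics(spec) -> ScalarMetrics:
    """All four metrics of a single eigen-spectrum."""
    ev = _evals(spec)
    if ev.shape != (3,):
        raise ValueError("scalar_metrics() expects a single spectrum")
    return ScalarMetrics(
        md=float(compute_md(ev)),
        fa=float(compute_fa(ev)),
        l=float(compute_l(ev)),
        q=float(compute_q(ev)),
    )


def compute_metric_maps(
    tensor_field: np.ndarray,
    mask: np.ndarray | None = None,
    fill_value: float = np.nan,
) -> dict[str, np.ndarray]:
    """Voxel-wise MD/FA/L/q maps from a tensor field.

    Parameters
    ----------
    tensor_field : (X,Y,Z,6) array
        Per-voxel tensor components in canonical order.
    mask : (X,Y,Z) boolean array, optional
        Voxels outside the mask are set to ``fill_value``.  Default: all in.
    fill_value : float
        Value written outside the mask (NaN by default, so ROI averaging
        can exclude non-fitted voxels).

    Returns
    -------
    dict with keys ``md``, ``fa``, ``l``, ``q`` (float maps) and
    ``nonphysical`` (boolean map flagging voxels with a negative
    eigenvalue; always False outside the mask).
    """
    field = np.asarray(tensor_field, dtype=float)
    if field.ndim < 2 or field.shape[-1] != 6:
        raise ValueError(f"expected (...,6) tensor field, got {field.shape}")
    grid = field.shape[:-1]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid:
            raise ValueError(
                f"mask shape {mask.shape} does not match tensor grid {grid}"
            )
    ev = eigen_decompose(field).eigenvalues
    maps = {
        "md": compute_md(ev),
        "fa": compute_fa(ev),
        "l": compute_l(ev),
        "q": compute_q(ev),
    }
    out = {}
    for name, volume in maps.items():
        vol = np.where(mask, volume, fill_value)
        out[name] = vol
    out["nonphysical"] = mask & (ev[..., -1] < 0)
    return out
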