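"""Synthetic study generator: DWI phantom cohorts and histology counts.

This module emulates a longitudinal small-animal DTI study of repetitive
mild traumatic brain injury (rmTBI): three groups (sham, short-interval,
long-interval; n = 6 each) imaged at two chronic timepoints (day 50 and
day 90 post-injury), with six regions of interest — cortex, corpus
callosum (CC) and hippocampus (HPC) under the impact site, and the remote
white matter ROIs medial CC, external capsule (EC) and internal capsule
(IC).

Each ROI carries a ground-truth diffusion tensor defined by an eigenvalue
profile and a principal fibre direction.  Group/timepoint effects modify
the profile in two orthogonal ways:

* ``spread`` scales the eigenvalue deviations about their mean — changing
  the pure anisotropy q (and FA) while leaving MD untouched;
* ``scale`` multiplies all eigenvalues — changing MD, L and q together
  while leaving FA untouched.

The default effect template encodes the study's signed findings: reduced
cortical q/FA in the short-interval group at both days, elevated CC q/FA
in the long-interval group, and reduced EC/IC L and q in the
short-interval group at day 90 only.

Per-subject biological variability is multiplicative eigenvalue jitter
(drawn once per subject so it persists across timepoints); measurement
noise is Rician on the simulated DWI signals.  Synthetic
immunohistochemistry (IHC) counts for GFAP (astrocytes), CD-68
(microglia) and NeuN (neurons) are drawn from linear models on the
ground-truth ROI-mean q at day 90 — GFAP negatively coupled, emulating
astrogliosis where anisotropy falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import GradientScheme, add_rician_noise, make_gradient_scheme, simulate_signal
from .tensors import compute_q, eigen_decompose, tensor_from_matrix

__all__ = [
    "ROI_NAMES",
    "GROUPS",
    "TIMEPOINTS",
    "STAINS",
    "RoiProfile",
    "PhantomSpec",
    "IhcCoupling",
    "CohortSpec",
    "SyntheticCohort",
    "default_profiles",
    "default_effect_template",
    "build_label_map",
    "generate_cohort",
    "generate_ihc_counts",
    "gfap_noise_sd_for_target_r",
]

ROI_NAMES = ("cortex", "CC", "HPC", "medial_CC", "EC", "IC")
GROUPS = ("sham", "short_interval", "long_interval")
TIMEPOINTS = ("day50", "day90")
STAINS = ("GFAP", "CD68", "NeuN")

# sub-seed purposes for deterministic stream derivation
_PURPOSE_JITTER = 1
_PURPOSE_NOISE = 2
_PURPOSE_IHC = 3


@dataclass(frozen=True)
class RoiProfile:
    """Ground-truth tensor of one ROI: eigenvalues (mm^2/s, descending)
    and the principal fibre direction (unit vector for lambda_1)."""

    eigenvalues: tuple[float, float, float]
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ev = self.eigenvalues
        if not (ev[0] >= ev[1] >= ev[2]):
            raise ValueError("profile eigenvalues must be sorted descending")
        if ev[2] < 0:
            raise ValueError("profile eigenvalues must be >= 0")

    def tensor(self) -> np.ndarray:
        """Six canonical components of R diag(ev) R^T with R rotating
        e1 onto the principal direction."""
        e1 = np.asarray(self.direction, dtype=float)
        e1 = e1 / np.linalg.norm(e1)
        # complete an orthonormal frame
        helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(helper, e1)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        r = np.stack([e1, e2, e3], axis=1)
        m = r @ np.diag(self.eigenvalues) @ r.T
        return tensor_from_matrix(m)


def default_profiles() -> dict[str, RoiProfile]:
    """Baseline (sham) eigenvalue profiles, in mm^2/s.

    White-matter ROIs are strongly anisotropic with distinct fibre
    orientations; cortex and hippocampus are mildly anisotropic grey
    matter.  Magnitudes are typical of rodent brain at body temperature.
    """
    return {
        "cortex": RoiProfile((0.95e-3, 0.75e-3, 0.65e-3), (1.0, 0.0, 0.0)),
        "CC": RoiProfile((1.60e-3, 0.35e-3, 0.30e-3), (1.0, 0.0, 0.0)),
        "HPC": RoiProfile((1.00e-3, 0.80e-3, 0.70e-3), (0.0, 1.0, 0.0)),
        "medial_CC": RoiProfile((1.55e-3, 0.35e-3, 0.30e-3), (1.0, 0.0, 0.0)),
        "EC": RoiProfile((1.50e-3, 0.40e-3, 0.35e-3), (0.0, 1.0, 0.0)),
        "IC": RoiProfile((1.50e-3, 0.40e-3, 0.35e-3), (0.0, 0.0, 1.0)),
    }


def default_effect_template() -> dict[tuple[str, str, str], dict[str, float]]:
    """Signed group x ROI x timepoint effects, as spread/scale factors.

    * short-interval cortex: q and FA reduced at both days (spread < 1);
    * long-interval CC: q and FA elevated at both days (spread > 1);
    * short-interval EC and IC: L and q reduced at day 90 only (scale < 1).
    """
    return {
        ("short_interval", "cortex", "day50"): {"spread": 0.85},
        ("short_interval", "cortex", "day90"): {"spread": 0.82},
        ("long_interval", "CC", "day50"): {"spread": 1.10},
        ("long_interval", "CC", "day90"): {"spread": 1.12},
        ("short_interval", "EC", "day90"): {"scale": 0.88},
        ("short_interval", "IC", "day90"): {"scale": 0.88},
    }


# fractional (x0, x1, y0, y1) extents of each ROI box; full z extent
_ROI_BOXES = {
    "cortex": (0.10, 0.90, 0.78, 0.92),
    "CC": (0.15, 0.85, 0.68, 0.76),
    "HPC": (0.25, 0.75, 0.50, 0.66),
    "medial_CC": (0.42, 0.58, 0.40, 0.48),
    "EC": (0.08, 0.24, 0.30, 0.60),
    "IC": (0.60, 0.78, 0.20, 0.38),
}


def build_label_map(grid: tuple[int, int, int]) -> np.ndarray:
    """Integer label volume with the six ROI boxes (codes 1..6 following
    ``ROI_NAMES`` order; 0 = background).

    Box extents are fractions of the grid, so any grid down to a few
    voxels per axis yields non-empty, non-overlapping ROIs.
    """
    nx, ny, nz = grid
    labels = np.zeros(grid, dtype=np.int16)
    for code, name in enumerate(ROI_NAMES, start=1):
        x0, x1, y0, y1 = _ROI_BOXES[name]
        xs = slice(round(x0 * nx), max(round(x1 * nx), round(x0 * nx) + 1))
        ys = slice(round(y0 * ny), max(round(y1 * ny), round(y0 * ny) + 1))
        region = labels[xs, ys, :]
        region[region == 0] = code  # first label wins on (unexpected) overlap
        if not np.any(labels == code):
            raise ValueError(f"grid {grid} too small: ROI {name!r} is empty")
    return labels


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, ground-truth tensor profiles and acquisition settings of
    the synthetic phantom."""

    grid: tuple[int, int, int] = (96, 96, 5)
    profiles: dict[str, RoiProfile] = field(default_factory=default_profiles)
    effects: dict[tuple[str, str, str], dict[str, float]] = field(
        default_factory=default_effect_template
    )
    s0: float = 1000.0
    noise_sigma: float = 40.0
    n_directions: int = 30
    b_value: float = 1000.0

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("phantom requires at least one ROI profile")
        for name in self.profiles:
            if name not in ROI_NAMES:
                raise ValueError(f"unknown ROI name {name!r}")
        for key in self.effects:
            group, roi, _ = key
            if roi not in self.profiles:
                raise ValueError(f"effect {key} refers to ROI without a profile")

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(n for n in ROI_NAMES if n in self.profiles)

    def label_map(self) -> np.ndarray:
        labels = build_label_map(self.grid)
        keep = np.isin(labels, [ROI_NAMES.index(n) + 1 for n in self.profiles])
        return np.where(keep, labels, 0).astype(np.int16)


@dataclass(frozen=True)
class IhcCoupling:
    """Linear model ``count = intercept + slope * q_roi + Normal(0, sd)``
    for one stain, with optional per-ROI overrides."""

    slope: float
    intercept: float
    sd: float
    per_roi: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("count noise SD must be >= 0")
        for roi, params in self.per_roi.items():
            if params.get("sd", 0.0) < 0:
                raise ValueError(f"count noise SD must be >= 0 (ROI {roi!r})")

    def params_for(self, roi: str) -> tuple[float, float, float]:
        over = self.per_roi.get(roi, {})
        return (
            over.get("slope", self.slope),
            over.get("intercept", self.intercept),
            over.get("sd", self.sd),
        )


def default_ihc_couplings() -> dict[str, IhcCoupling]:
    """Default stain couplings to ROI-mean q (mm^2/s) at day 90.

    GFAP is negatively coupled (astrogliosis where q falls); NeuN is
    positively coupled (lower q co-occurs with neuronal loss); CD-68 is
    uncoupled by default (no q relationship), carrying pure count noise.
    Intercepts put counts in the few-hundreds so integer rounding is
    negligible relative to the noise SD.
    """
    return {
        "GFAP": IhcCoupling(slope=-3.0e5, intercept=700.0, sd=12.0),
        "CD68": IhcCoupling(slope=0.0, intercept=150.0, sd=20.0),
        "NeuN": IhcCoupling(slope=4.0e5, intercept=300.0, sd=15.0),
    }


def gfap_noise_sd_for_target_r(slope: float, q_sd: float, target_r: float) -> float:
    """Count-noise SD that makes the population correlation between q and
    the stain count equal ``target_r``, given the between-subject SD of q.

    From the linear-Gaussian model, ``r = slope*q_sd / sqrt((slope*q_sd)^2
    + sd^2)``; solving for sd gives ``|slope|*q_sd*sqrt(1/r^2 - 1)``.
    """
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must lie strictly between 0 and 1 (nonzero)")
    return abs(slope) * q_sd * np.sqrt(1.0 / target_r**2 - 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study design: groups, group size, timepoints, randomness and IHC
    coupling parameters."""

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 6
    timepoints: tuple[str, ...] = TIMEPOINTS
    seed: int = 0
    jitter_sd: float = 0.03
    ihc: dict[str, IhcCoupling] = field(default_factory=default_ihc_couplings)
    #: histology subgroup sizes per group (sham/short/long = 4/3/4 by default)
    ihc_subgroup: dict[str, int] = field(
        default_factory=lambda: {"sham": 4, "short_interval": 3, "long_interval": 4}
    )

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need >= 2 subjects per group")
        if len(self.timepoints) < 1:
            raise ValueError("need >= 1 timepoint")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")

    @property
    def subject_ids(self) -> list[tuple[str, str]]:
        """(subject_id, group) pairs, e.g. ('sham_01', 'sham')."""
        out = []
        for group in self.groups:
            for i in range(self.n_per_group):
                out.append((f"{group}_{i + 1:02d}", group))
        return out


def _subseed(master: int, *key: int) -> int:
    """Derive an independent sub-seed (< 2^31) from the master seed and an
    integer key path, via SeedSequence spawning."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class SyntheticCohort:
    """A fully simulated study, with ground truth attached.

    ``dwi[(subject_id, timepoint)]`` holds the noisy 4-D signal volume;
    ``truth_tensors`` the matching noiseless per-voxel tensor field;
    ``truth_roi_q`` the ground-truth ROI q per subject/timepoint (the
    quantity IHC counts couple to).
    """

    phantom: PhantomSpec
    spec: CohortSpec
    scheme: GradientScheme
    label_map: np.ndarray
    subjects: list[tuple[str, str]]  # (subject_id, group)
    dwi: dict[tuple[str, str], np.ndarray]
    truth_tensors: dict[tuple[str, str], np.ndarray]
    truth_roi_q: dict[tuple[str, str], dict[str, float]]
    metadata: dict

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    def group_of(self, subject_id: str) -> str:
        for sid, group in self.subjects:
            if sid == subject_id:
                return group
        raise KeyError(subject_id)


def _effective_eigenvalues(
    profile: RoiProfile,
    effect: dict[str, float] | None,
    jitter: np.ndarray,
) -> np.ndarray:
    ev = np.asarray(profile.eigenvalues, dtype=float)
    if effect:
        spread = effect.get("spread", 1.0)
        scale = effect.get("scale", 1.0)
        mean = ev.mean()
        ev = scale * (mean + spread * (ev - mean))
    ev = ev * jitter
    return np.clip(np.sort(ev)[::-1], 0.0, None)


def generate_cohort(phantom: PhantomSpec, cohort: CohortSpec) -> SyntheticCohort:
    """Simulate the full study.

    For every subject x timepoint the ROI tensor fields are built from the
    group/timepoint eigenvalue profiles, per-subject multiplicative
    eigenvalue jitter is applied (drawn once per subject, persisting
    across timepoints — biological identity), noise-free DWI is simulated
    and Rician noise added with deterministic per-subject sub-seeds.
    Ground truth is stored losslessly.
    """
    labels = phantom.label_map()
    scheme = make_gradient_scheme(
        phantom.n_directions, phantom.b_value, seed=_subseed(cohort.seed, 0, 0, 0)
    )
    roi_codes = {name: ROI_NAMES.index(name) + 1 for name in phantom.roi_names}

    dwi: dict[tuple[str, str], np.ndarray] = {}
    truth: dict[tuple[str, str], np.ndarray] = {}
    truth_q: dict[tuple[str, str], dict[str, float]] = {}
    subjects = cohort.subject_ids

    for s_idx, (sid, group) in enumerate(subjects):
        jit_rng = np.random.default_rng(_subseed(cohort.seed, s_idx, 0, _PURPOSE_JITTER))
        jitter = {
            roi: np.clip(
                1.0 + cohort.jitter_sd * jit_rng.standard_normal(3), 1e-3, None
            )
            for roi in phantom.roi_names
        }
        for t_idx, tp in enumerate(cohort.timepoints):
            field_ = np.zeros(phantom.grid + (6,))
            q_by_roi: dict[str, float] = {}
            roi_signals: dict[str, np.ndarray] = {}
            for roi in phantom.roi_names:
                effect = phantom.effects.get((group, roi, tp))
                ev = _effective_eigenvalues(phantom.profiles[roi], effect, jitter[roi])
                prof = replace(phantom.profiles[roi], eigenvalues=tuple(ev))
                tensor6 = prof.tensor()
                field_[labels == roi_codes[roi]] = tensor6
                q_by_roi[roi] = float(compute_q(ev))
                roi_signals[roi] = simulate_signal(tensor6, scheme, phantom.s0)

            clean = np.zeros(phantom.grid + (len(scheme),))
            for roi in phantom.roi_names:
                clean[labels == roi_codes[roi]] = roi_signals[roi]
            noisy = add_rician_noise(
                clean,
                phantom.noise_sigma,
                seed=_subseed(cohort.seed, s_idx, t_idx, _PURPOSE_NOISE),
            )
            noisy[labels == 0] = 0.0

            key = (sid, tp)
            dwi[key] = noisy
            truth[key] = field_
            truth_q[key] = q_by_roi

    metadata = {
        "seed": cohort.seed,
        "groups": list(cohort.groups),
        "n_per_group": cohort.n_per_group,
        "timepoints": list(cohort.timepoints),
        "jitter_sd": cohort.jitter_sd,
        "grid": list(phantom.grid),
        "s0": phantom.s0,
        "noise_sigma": phantom.noise_sigma,
        "n_directions": phantom.n_directions,
        "b_value": phantom.b_value,
        "seed_scheme": "SeedSequence(master, spawn_key=(subject, timepoint, purpose))",
    }
    return SyntheticCohort(
        phantom=phantom,
        spec=cohort,
        scheme=scheme,
        label_map=labels,
        subjects=subjects,
        dwi=dwi,
        truth_tensors=truth,
        truth_roi_q=truth_q,
        metadata=metadata,
    )


def generate_ihc_counts(
    cohort: SyntheticCohort,
    couplings: dict[str, IhcCoupling] | None = None,
    seed: int | None = None,
    timepoint: str = "day90",
) -> pd.DataFrame:
    """Synthetic per-subject ROI cell counts for GFAP, CD-68 and NeuN.

    Counts follow ``round(max(0, intercept + slope * q_roi + noise))``
    where ``q_roi`` is the ground-truth ROI q of that subject at the
    histology timepoint (day 90 by default).  Only the histology subgroup
    (default 4 sham / 3 short / 4 long, mirroring terminal sampling) gets
    counts.  Reproducible for a fixed seed.

    Returns a long DataFrame with columns
    ``subject_id, group, roi, stain, count``.
    """
    couplings = couplings if couplings is not None else cohort.spec.ihc
    if seed is None:
        seed = _subseed(cohort.spec.seed, 0, 0, _PURPOSE_IHC)
    rng = np.random.default_rng(seed)

    rows = []
    taken: dict[str, int] = {g: 0 for g in cohort.spec.groups}
    quota = cohort.spec.ihc_subgroup
    for sid, group in cohort.subjects:
        if taken[group] >= quota.get(group, cohort.spec.n_per_group):
            continue
        taken[group] += 1
        q_by_roi = cohort.truth_roi_q[(sid, timepoint)]
        for roi in cohort.phantom.roi_names:
            for stain in STAINS:
                if stain not in couplings:
                    continue
                slope, intercept, sd = couplings[stain].params_for(roi)
                value = intercept + slope * q_by_roi[roi]
                if sd > 0:
                    value += rng.normal(0.0, sd)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "roi": roi,
                        "stain": stain,
                        "count": int(round(max(0.0, value))),
                    }
                )
    return pd.DataFrame(rows, columns=["subject_id", "group", "roi", "stain", "count"])
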