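"""Reproducible generate -> fit -> decompose -> summarise -> test pipeline.

A :class:`RunConfig` fully determines a run: re-running a saved config
with the same seed reproduces every output byte-identically.  The three
stages are importable functions (:func:`run_simulate`,
:func:`run_analyze`, :func:`run_all`); the ``dtiq`` command line wraps
them thinly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import nifti
from .fitting import fit_tensor_loglinear, fit_tensor_wls
from .phantom import (
    ROI_NAMES,
    CohortSpec,
    IhcCoupling,
    PhantomSpec,
    RoiProfile,
    SyntheticCohort,
    generate_cohort,
    generate_ihc_counts,
)
from .roi import METRIC_NAMES, TABLE_COLUMNS, assemble_cohort_table
from .stats import oneway_anova_tukey, pearson_with_regression, posthoc_bonferroni, rm_anova
from .tensors import compute_metric_maps

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_all"]

log = logging.getLogger("dtiq")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a full pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit_method: str = "loglinear"  # or "wls"
    min_signal: float | None = None
    alpha: float = 0.05
    posthoc_mode: str = "per_day"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.fit_method not in ("loglinear", "wls"):
            raise ValueError(f"unknown fit method {self.fit_method!r}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "phantom": {
                "grid": list(self.phantom.grid),
                "s0": self.phantom.s0,
                "noise_sigma": self.phantom.noise_sigma,
                "n_directions": self.phantom.n_directions,
                "b_value": self.phantom.b_value,
                "profiles": {
                    roi: {
                        "eigenvalues": list(p.eigenvalues),
                        "direction": list(p.direction),
                    }
                    for roi, p in self.phantom.profiles.items()
                },
                "effects": [
                    {"group": g, "roi": r, "timepoint": t, **params}
                    for (g, r, t), params in self.phantom.effects.items()
                ],
            },
            "cohort": {
                "groups": list(self.cohort.groups),
                "n_per_group": self.cohort.n_per_group,
                "timepoints": list(self.cohort.timepoints),
                "seed": self.cohort.seed,
                "jitter_sd": self.cohort.jitter_sd,
                "ihc": {
                    stain: {
                        "slope": c.slope,
                        "intercept": c.intercept,
                        "sd": c.sd,
                        "per_roi": c.per_roi,
                    }
                    for stain, c in self.cohort.ihc.items()
                },
                "ihc_subgroup": dict(self.cohort.ihc_subgroup),
            },
            "fit_method": self.fit_method,
            "min_signal": self.min_signal,
            "alpha": self.alpha,
            "posthoc_mode": self.posthoc_mode,
            "verbose": self.verbose,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "phantom" in d:
            p = dict(d.pop("phantom"))
            p_known = {"grid", "s0", "noise_sigma", "n_directions", "b_value", "profiles", "effects"}
            bad = set(p) - p_known
            if bad:
                raise ValueError(f"unknown phantom keys: {sorted(bad)}")
            if "grid" in p:
                p["grid"] = tuple(p["grid"])
            if "profiles" in p:
                p["profiles"] = {
                    roi: RoiProfile(tuple(v["eigenvalues"]), tuple(v["direction"]))
                    for roi, v in p["profiles"].items()
                }
            if "effects" in p:
                effects = {}
                for e in p["effects"]:
                    e = dict(e)
                    key = (e.pop("group"), e.pop("roi"), e.pop("timepoint"))
                    effects[key] = e
                p["effects"] = effects
            kwargs["phantom"] = PhantomSpec(**p)
        if "cohort" in d:
            c = dict(d.pop("cohort"))
            c_known = {"groups", "n_per_group", "timepoints", "seed", "jitter_sd", "ihc", "ihc_subgroup"}
            bad = set(c) - c_known
            if bad:
                raise ValueError(f"unknown cohort keys: {sorted(bad)}")
            if "groups" in c:
                c["groups"] = tuple(c["groups"])
            if "timepoints" in c:
                c["timepoints"] = tuple(c["timepoints"])
            if "ihc" in c:
                c["ihc"] = {stain: IhcCoupling(**v) for stain, v in c["ihc"].items()}
            kwargs["cohort"] = CohortSpec(**c)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, cohort=dataclasses.replace(self.cohort, seed=seed)
        )


def _setup_logging(verbose: bool) -> None:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


# -- simulate --------------------------------------------------------------


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write it to ``out_dir``.

    Layout: per subject-timepoint DWI (``<sid>_<tp>_dwi.nii``) and
    ground-truth tensor field, shared ``labels.nii``(+json) and
    ``scheme.bval/.bvec``, ``ihc_counts.csv``, ``manifest.json`` and a
    config snapshot ``config.yaml``.
    """
    _setup_logging(config.verbose)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cohort = generate_cohort(config.phantom, config.cohort)
    ihc = generate_ihc_counts(cohort)

    roi_codes = {n: ROI_NAMES.index(n) + 1 for n in config.phantom.roi_names}
    nifti.save_label_map(cohort.label_map, roi_codes, out / "labels.nii")
    cohort.scheme.to_files(out / "scheme.bval", out / "scheme.bvec")
    ihc.to_csv(out / "ihc_counts.csv", index=False)

    entries = []
    for sid, group in cohort.subjects:
        for tp in config.cohort.timepoints:
            dwi_name = f"{sid}_{tp}_dwi.nii"
            truth_name = f"{sid}_{tp}_truth_tensor.nii"
            nifti.save_volume(cohort.dwi[(sid, tp)], out / dwi_name)
            nifti.save_volume(cohort.truth_tensors[(sid, tp)], out / truth_name)
            entries.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "timepoint": tp,
                    "dwi": dwi_name,
                    "truth_tensor": truth_name,
                }
            )
    manifest = {
        "entries": entries,
        "labels": "labels.nii",
        "bval": "scheme.bval",
        "bvec": "scheme.bvec",
        "ihc_counts": "ihc_counts.csv",
        "roi_names": list(config.phantom.roi_names),
        "metadata": cohort.metadata,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    config.to_yaml(out / "config.yaml")
    log.info(
        "simulate: wrote %d acquisitions (%d subjects) to %s in %.1fs",
        len(entries), len(cohort.subjects), out, time.time() - t0,
    )
    return out


# -- analyze ---------------------------------------------------------------


def _fit_subject(dwi, scheme, mask, method, min_signal):
    signals = dwi[mask]
    fit = (fit_tensor_wls if method == "wls" else fit_tensor_loglinear)(
        signals, scheme, min_signal
    )
    field_ = np.zeros(mask.shape + (6,))
    field_[mask] = fit.tensor
    return field_, int(fit.nonphysical.sum()), fit.n_clipped


def run_analyze(config: RunConfig, cohort_dir: str | Path, out_dir: str | Path) -> Path:
    """Fit tensors, write scalar maps, build the metric table and run the
    statistical battery on a cohort stored on disk."""
    _setup_logging(config.verbose)
    cohort_dir, out = Path(cohort_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    labels, roi_codes = nifti.load_label_map(cohort_dir / manifest["labels"])
    from .simulate import GradientScheme

    scheme = GradientScheme.from_files(
        cohort_dir / manifest["bval"], cohort_dir / manifest["bvec"]
    )
    mask = labels > 0

    expected = [(e["subject_id"], e["timepoint"]) for e in manifest["entries"]]
    subjects = list(dict.fromkeys((e["subject_id"], e["group"]) for e in manifest["entries"]))
    timepoints = list(dict.fromkeys(e["timepoint"] for e in manifest["entries"]))
    groups_by_sid = dict(subjects)
    missing = [
        (sid, tp) for sid, _ in subjects for tp in timepoints if (sid, tp) not in expected
    ]
    if missing:
        raise ValueError(f"manifest incomplete; missing acquisitions: {missing}")

    maps_by_key = {}
    n_nonphys = n_clipped = 0
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for entry in manifest["entries"]:
        sid, tp = entry["subject_id"], entry["timepoint"]
        dwi_path = cohort_dir / entry["dwi"]
        if not dwi_path.exists():
            raise FileNotFoundError(f"missing DWI volume: {dwi_path}")
        dwi, _ = nifti.load_volume(dwi_path)
        field_, np_count, clip_count = _fit_subject(
            dwi.astype(float), scheme, mask, config.fit_method, config.min_signal
        )
        n_nonphys += np_count
        n_clipped += clip_count
        maps = compute_metric_maps(field_, mask)
        for metric in ("md", "fa", "l", "q"):
            nifti.save_volume(maps[metric], maps_dir / f"{sid}_{tp}_{metric}.nii")
        maps_by_key[(sid, tp)] = maps
    log.info(
        "analyze: fitted %d acquisitions (%d non-physical voxels, %d clipped signals)",
        len(maps_by_key), n_nonphys, n_clipped,
    )

    view = SimpleNamespace(
        subjects=subjects,
        spec=SimpleNamespace(timepoints=tuple(timepoints)),
        phantom=SimpleNamespace(roi_names=tuple(manifest["roi_names"])),
        label_map=labels,
        group_of=lambda sid: groups_by_sid[sid],
    )
    table = assemble_cohort_table(view, maps_by_key)
    table.to_csv(out / "metrics.csv", index=False)

    stats_rows = []
    for roi in manifest["roi_names"]:
        for metric in METRIC_NAMES:
            cell = table[(table["roi"] == roi) & (table["metric"] == metric)]
            res = rm_anova(cell)
            for effect in ("group", "time", "interaction"):
                e = res.effect(effect)
                stats_rows.append(
                    {
                        "test": "rm_anova",
                        "roi": roi,
                        "variable": metric,
                        "effect": effect,
                        "statistic": e.F,
                        "df1": e.df1,
                        "df2": e.df2,
                        "p": e.p,
                        "decision": "significant" if e.p < config.alpha else "ns",
                    }
                )
            post = posthoc_bonferroni(cell, alpha=config.alpha, mode=config.posthoc_mode)
            for _, row in post.iterrows():
                stats_rows.append(
                    {
                        "test": f"posthoc_bonferroni[{row['timepoint']}]",
                        "roi": roi,
                        "variable": metric,
                        "effect": row["contrast"],
                        "statistic": row["t"],
                        "df1": 1,
                        "df2": row["df"],
                        "p": row["p_raw"],
                        "decision": "significant" if row["significant"] else "ns",
                    }
                )

    ihc_path = cohort_dir / manifest.get("ihc_counts", "ihc_counts.csv")
    if ihc_path.exists():
        ihc = pd.read_csv(ihc_path)
        for (roi, stain), cell in ihc.groupby(["roi", "stain"], sort=False):
            try:
                anova, tukey = oneway_anova_tukey(cell)
            except ValueError as err:
                log.warning("IHC ANOVA skipped for %s/%s: %s", roi, stain, err)
                continue
            stats_rows.append(
                {
                    "test": "oneway_anova",
                    "roi": roi,
                    "variable": stain,
                    "effect": "group",
                    "statistic": anova.F,
                    "df1": anova.df1,
                    "df2": anova.df2,
                    "p": anova.p,
                    "decision": "significant" if anova.p < config.alpha else "ns",
                }
            )
            for _, row in tukey.iterrows():
                stats_rows.append(
                    {
                        "test": "tukey_hsd",
                        "roi": roi,
                        "variable": stain,
                        "effect": row["contrast"],
                        "statistic": row["q"],
                        "df1": 1,
                        "df2": row["df"],
                        "p": row["p_adj"],
                        "decision": "significant" if row["significant"] else "ns",
                    }
                )
        # imaging-histology association: ROI-mean q at the histology
        # timepoint vs GFAP counts in the remote WM ROIs
        tp_last = timepoints[-1]
        for roi in ("EC", "IC"):
            if roi not in manifest["roi_names"]:
                continue
            gfap = ihc[(ihc["roi"] == roi) & (ihc["stain"] == "GFAP")]
            qvals = table[
                (table["roi"] == roi)
                & (table["metric"] == "q")
                & (table["timepoint"] == tp_last)
            ].set_index("subject_id")["value"]
            merged = gfap.assign(q=gfap["subject_id"].map(qvals)).dropna(subset=["q"])
            if len(merged) < 3:
                continue
            corr = pearson_with_regression(merged["q"], merged["count"])
            stats_rows.append(
                {
                    "test": "pearson_q_vs_GFAP",
                    "roi": roi,
                    "variable": "GFAP",
                    "effect": f"slope={corr.slope:.4g}",
                    "statistic": corr.r,
                    "df1": 1,
                    "df2": corr.n - 2,
                    "p": corr.p,
                    "decision": "significant" if corr.p < config.alpha else "ns",
                }
            )

    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out / "stats.csv", index=False)

    n_sig = int((stats_df["decision"] == "significant").sum()) if len(stats_df) else 0
    report = [
        "dtiq analysis report",
        f"cohort: {cohort_dir}",
        f"subjects: {len(subjects)}; timepoints: {timepoints}",
        f"fit method: {config.fit_method}; non-physical voxels: {n_nonphys}; clipped signals: {n_clipped}",
        f"metric table rows: {len(table)}",
        f"tests run: {len(stats_df)}; significant at alpha={config.alpha}: {n_sig}",
        f"seed: {manifest['metadata'].get('seed')}",
    ]
    (out / "report.txt").write_text("\n".join(report) + "\n")
    log.info("analyze: finished in %.1fs (%d tests, %d significant)",
             time.time() - t0, len(stats_df), n_sig)
    return out


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and analyze it: one command reproduces the whole
    synthetic study under ``out_dir`` (``cohort/`` + ``analysis/``)."""
    out = Path(out_dir)
    cohort_dir = run_simulate(config, out / "cohort")
    run_analyze(config, cohort_dir, out / "analysis")
    return out
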