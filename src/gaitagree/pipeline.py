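"""End-to-end study pipeline: simulate -> extract -> aggregate -> agreement report.

``run_study`` executes the whole chain deterministically for a given seed and
writes plot-ready CSV tables plus a JSON summary; ``analyze_cohort`` runs the
agreement stage alone on any long-format angle table (simulated or imported).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .agreement import (
    BlandAltmanResult,
    ICCResult,
    PairedTResult,
    RatingsMatrix,
    bland_altman,
    icc_single,
    paired_t,
)
from .io import write_cohort_csv, write_force_csv, write_marker_csv
from .synthetic import (
    JOINTS,
    CameraModel,
    CohortConfig,
    ErrorModel,
    aggregate_repetitions,
    sample_subject,
    simulate_cohort,
    simulate_trial,
    substream,
)

__all__ = [
    "Contrast",
    "STANDARD_CONTRASTS",
    "RunConfig",
    "StudyReport",
    "build_ratings_matrix",
    "analyze_cohort",
    "run_study",
    "make_fixtures",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class Contrast:
    """One pairwise agreement comparison over the aggregated table.

    ``filters`` select the slice of the table, ``column`` names the variable
    whose two levels (in ``order``) become the paired measurements. The
    difference sign is ``order[0] - order[1]``.
    """

    name: str
    filters: Mapping[str, object]
    column: str
    order: tuple

    def describe(self) -> str:
        return f"{self.column}: {self.order[0]} - {self.order[1]}"


#: The classic reliability-study contrasts: per-observer test-retest across
#: sessions, between-observer agreement on the same session, and video system
#: versus the 3D reference. Difference orders are fixed: session1 - session2,
#: observer1 - observer2, video - reference.
STANDARD_CONTRASTS = {
    "intra_observer_1": Contrast("intra_observer_1", {"system": "video", "observer": 1}, "session", (1, 2)),
    "intra_observer_2": Contrast("intra_observer_2", {"system": "video", "observer": 2}, "session", (1, 2)),
    "inter_rater": Contrast("inter_rater", {"system": "video", "session": 1}, "observer", (1, 2)),
    "system": Contrast("system", {"session": 1, "observer": 1}, "system", ("video", "reference")),
}


def _dataclass_from_dict(cls, data: Mapping) -> object:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise PipelineError(f"config: unknown {cls.__name__} fields {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible study run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    error: ErrorModel = field(default_factory=ErrorModel)
    camera: CameraModel = field(default_factory=CameraModel)
    contrasts: tuple[str, ...] = tuple(STANDARD_CONTRASTS)
    aggregation: str = "mean"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.contrasts:
            raise PipelineError("config: at least one contrast is required")
        unknown = [c for c in self.contrasts if c not in STANDARD_CONTRASTS]
        if unknown:
            raise PipelineError(f"config: unknown contrasts {unknown}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        kwargs: dict = {}
        if "cohort" in data:
            kwargs["cohort"] = _dataclass_from_dict(CohortConfig, data.pop("cohort"))
        if "error" in data:
            kwargs["error"] = _dataclass_from_dict(ErrorModel, data.pop("error"))
        if "camera" in data:
            kwargs["camera"] = _dataclass_from_dict(CameraModel, data.pop("camera"))
        for key in ("contrasts", "aggregation", "seed", "log_level"):
            if key in data:
                val = data.pop(key)
                kwargs[key] = tuple(val) if key == "contrasts" else val
        if data:
            raise PipelineError(f"config: unknown top-level keys {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["contrasts"] = list(self.contrasts)
        out["cohort"]["systems"] = list(self.cohort.systems)
        out["camera"]["resolution"] = list(out["camera"]["resolution"])
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    """Per-joint, per-contrast agreement results with run provenance."""

    results: dict  # contrast -> joint -> {"icc_abs", "icc_cons", "ba", "t", "mean_a", ...}
    cohort: pd.DataFrame
    aggregated: pd.DataFrame
    config: RunConfig
    seed: int
    config_hash: str
    version: str = __version__

    def summary_dict(self) -> dict:
        out: dict = {
            "seed": self.seed,
            "config_sha256": self.config_hash,
            "version": self.version,
            "contrasts": {},
        }
        for cname, joints in self.results.items():
            cdict = {}
            for joint, res in joints.items():
                icc_a: ICCResult = res["icc_abs"]
                icc_c: ICCResult = res["icc_cons"]
                ba: BlandAltmanResult = res["ba"]
                tt: PairedTResult = res["t"]
                cdict[joint] = {
                    "mean_a": res["mean_a"], "sd_a": res["sd_a"],
                    "mean_b": res["mean_b"], "sd_b": res["sd_b"],
                    "icc": icc_a.estimate, "icc_ci": [icc_a.ci_low, icc_a.ci_high],
                    "icc_band": icc_a.band,
                    "icc_consistency": icc_c.estimate,
                    "icc_consistency_ci": [icc_c.ci_low, icc_c.ci_high],
                    "bias": ba.bias, "sd_diff": ba.sd_diff,
                    "loa": [ba.loa_low, ba.loa_high],
                    "md": tt.md, "md_ci": [tt.ci_low, tt.ci_high],
                    "t": tt.t_stat, "df": tt.df, "p": tt.p,
                }
            out["contrasts"][cname] = cdict
        return out


def build_ratings_matrix(agg: pd.DataFrame, joint: str, contrast: Contrast) -> RatingsMatrix:
    """Pivot the aggregated table into an n-subjects x 2 ratings matrix."""
    sub = agg[agg["joint"] == joint]
    for key, val in contrast.filters.items():
        sub = sub[sub[key] == val]
    pivot = sub.pivot_table(index="subject", columns=contrast.column,
                            values="angle_deg", aggfunc="mean")
    missing_cols = [c for c in contrast.order if c not in pivot.columns]
    if missing_cols:
        raise PipelineError(
            f"contrast {contrast.name!r}: levels {missing_cols} absent from the table")
    pivot = pivot[list(contrast.order)].dropna()
    if pivot.shape[0] < 2:
        raise PipelineError(f"contrast {contrast.name!r}: fewer than 2 complete subjects")
    return RatingsMatrix(values=pivot.to_numpy(dtype=float),
                         row_labels=tuple(pivot.index),
                         col_labels=tuple(contrast.order))


def analyze_cohort(
    cohort: pd.DataFrame,
    contrasts: Mapping[str, Contrast] | None = None,
    aggregation: str = "mean",
) -> dict:
    """Agreement statistics for every requested contrast and joint.

    Repetitions are aggregated first (mean by default); each contrast then
    yields, per joint, both ICC forms, the Bland-Altman result and the paired
    t comparison, with column order as documented on the contrast.
    """
    contrasts = dict(contrasts) if contrasts is not None else dict(STANDARD_CONTRASTS)
    agg = aggregate_repetitions(cohort, how=aggregation)
    joints = [j for j in JOINTS if j in set(cohort["joint"])]
    results: dict = {}
    for cname, contrast in contrasts.items():
        try:
            per_joint = {}
            for joint in joints:
                m = build_ratings_matrix(agg, joint, contrast)
                a, b = m.values[:, 0], m.values[:, 1]
                per_joint[joint] = {
                    "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
                    "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
                    "icc_abs": icc_single(m, "absolute_agreement_single"),
                    "icc_cons": icc_single(m, "consistency_single"),
                    "ba": bland_altman(a, b),
                    "t": paired_t(a, b),
                }
            results[cname] = per_joint
        except Exception as exc:
            raise PipelineError(f"stage agreement/{cname}: {exc}") from exc
    return results


def _results_table(per_joint: dict) -> pd.DataFrame:
    rows = []
    for joint, res in per_joint.items():
        icc_a, icc_c, ba, tt = res["icc_abs"], res["icc_cons"], res["ba"], res["t"]
        rows.append({
            "joint": joint,
            "mean_a": res["mean_a"], "sd_a": res["sd_a"],
            "mean_b": res["mean_b"], "sd_b": res["sd_b"],
            "icc": icc_a.estimate, "ci_low": icc_a.ci_low, "ci_high": icc_a.ci_high,
            "band": icc_a.band,
            "icc_consistency": icc_c.estimate,
            "icc_consistency_ci_low": icc_c.ci_low, "icc_consistency_ci_high": icc_c.ci_high,
            "md": tt.md, "md_ci_low": tt.ci_low, "md_ci_high": tt.ci_high,
            "t": tt.t_stat, "df": tt.df, "p": tt.p,
            "bias": ba.bias, "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        })
    return pd.DataFrame(rows)


def run_study(config: RunConfig, outdir: str | Path | None = None) -> StudyReport:
    """Simulate the cohort, extract angles, aggregate, and report agreement.

    Deterministic per seed: rerunning with an identical config produces
    byte-identical output files. ``config.seed`` overrides the cohort block's
    seed so one number controls the whole run.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cohort_cfg = replace(config.cohort, rng_seed=config.seed)
    logger.info("run %s: simulating %d subjects", config.config_hash(), cohort_cfg.n_subjects)
    try:
        cohort = simulate_cohort(cohort_cfg, config.error, config.camera)
    except Exception as exc:
        raise PipelineError(f"stage simulate: {exc}") from exc
    agg = aggregate_repetitions(cohort, how=config.aggregation)
    contrasts = {name: STANDARD_CONTRASTS[name] for name in config.contrasts}
    results = analyze_cohort(cohort, contrasts, aggregation=config.aggregation)
    report = StudyReport(results=results, cohort=cohort, aggregated=agg,
                         config=config, seed=config.seed,
                         config_hash=config.config_hash())
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write cohort table, per-contrast result tables, plot data and summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {"seed": report.seed, "config_sha256": report.config_hash,
              "gaitagree_version": report.version}
    write_cohort_csv(outdir / "cohort.csv", report.cohort, comments=header)
    write_cohort_csv(outdir / "cohort_aggregated.csv", report.aggregated, comments=header)
    for cname, per_joint in report.results.items():
        table = _results_table(per_joint)
        path = outdir / f"table_{cname}.csv"
        with open(path, "w") as fh:
            for key, val in header.items():
                fh.write(f"# {key}={val}\n")
            fh.write(f"# contrast={STANDARD_CONTRASTS[cname].describe()}\n")
            table.to_csv(fh, index=False)
        for joint, res in per_joint.items():
            ba: BlandAltmanResult = res["ba"]
            if ba.means.size == 0:
                continue
            bpath = outdir / f"bland_altman_{cname}_{joint}.csv"
            with open(bpath, "w") as fh:
                for key, val in header.items():
                    fh.write(f"# {key}={val}\n")
                fh.write(f"# bias={ba.bias!r}\n# loa_low={ba.loa_low!r}\n# loa_high={ba.loa_high!r}\n")
                pd.DataFrame({"mean": ba.means, "difference": ba.differences}).to_csv(fh, index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(report.config.to_dict(), fh, sort_keys=True)


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict:
    """Emit a small packaged dataset for tests and demos.

    Writes a 5-subject mini cohort table (2 sessions x 2 repetitions x 2
    observers x 2 systems), one noise-free orthographically projected trial
    (marker tracks in metres plus the force signal), and a JSON manifest with
    the trial's ground-truth IC angles, IC frame and force-threshold sample.
    Re-running with the same seed reproduces identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(n_subjects=5, n_sessions=2, n_repetitions=2,
                          n_observers=2, rng_seed=seed)
    err = ErrorModel()
    cam = CameraModel()
    cohort = simulate_cohort(config, err, cam)
    write_cohort_csv(outdir / "cohort.csv", cohort, comments={"seed": seed})

    # one clean trial for round-trip checks: zero noise, orthographic view
    clean_cam = CameraModel(projection_mode="orthographic")
    subject = sample_subject(config, err, substream(seed, 1, 1), index=1)
    trial = simulate_trial(subject, {}, ErrorModel.zero(), clean_cam,
                           substream(seed, 9, 1), n_frames=80)
    tracks2d = {m: arr[:, :2] for m, arr in trial.tracks_3d.items()}
    write_marker_csv(outdir / "trial_markers.csv", tracks2d, fps=clean_cam.fps,
                     units="m", comments={"seed": seed, "true_ic_frame": trial.true_ic_frame})
    write_force_csv(outdir / "trial_force.csv", trial.force,
                    comments={"seed": seed, "true_ic_sample": trial.true_ic_force_sample})

    manifest = {
        "seed": seed,
        "n_subjects": config.n_subjects,
        "true_ic_frame": trial.true_ic_frame,
        "true_ic_force_sample": trial.true_ic_force_sample,
        "true_angles_deg": {j: float(v) for j, v in trial.true_angles.items()},
        "fps": clean_cam.fps,
        "files": {},
    }
    for name in ("cohort.csv", "trial_markers.csv", "trial_force.csv"):
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
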