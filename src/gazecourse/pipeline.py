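"""End-to-end runs: raw samples -> fixations -> DVs -> time courses -> clusters.

Every stage is a pure function of its inputs and the seed, so a run is fully
reproducible from its manifest. Stage boundaries log row counts in/out
(samples, fixations, trials kept/dropped) so exclusion accounting is
first-class.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import aggregate, io, preprocess, synthetic, timecourse
from .aoi import DynamicAOIPair
from .cluster import ClusterTestResult, cluster_permutation_test, format_p
from .config import CONDITIONS, BinConfig, DetectorConfig, PermConfig, SimConfig, condition_label
from .errors import PipelineError

log = logging.getLogger("gazecourse")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``sim`` (generate a synthetic cohort) or the three input CSV paths
    must be provided. ``seed`` drives the simulation and, with a fixed offset
    per analysis, the permutation tests.
    """

    out_dir: str = "gazecourse_out"
    seed: int = 0
    sim: Optional[SimConfig] = field(default_factory=SimConfig)
    samples_path: Optional[str] = None
    aoi_path: Optional[str] = None
    subjects_path: Optional[str] = None
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    bins: BinConfig = field(default_factory=BinConfig)
    perm: PermConfig = field(default_factory=PermConfig)
    make_figure: bool = True


@dataclass
class PipelineResult:
    """In-memory artefacts of a run (everything is also written to out_dir)."""

    fixations: pd.DataFrame
    kept_fixations: pd.DataFrame
    exclusion_audit: pd.DataFrame
    trial_dvs: pd.DataFrame
    condition_prefs: pd.DataFrame
    fixation_table: pd.DataFrame
    timecourses: pd.DataFrame
    group_timecourses: Dict[str, pd.DataFrame]
    cluster_tests: Dict[str, ClusterTestResult]
    cluster_report: pd.DataFrame
    manifest: dict
    paths: Dict[str, Path]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _perm_seed(seed: int, k: int) -> int:
    return (int(seed) + 1000003 * (k + 1)) % (2**31)


def _load_inputs(cfg: RunConfig):
    if cfg.samples_path is not None:
        samples = io.read_table(cfg.samples_path, "samples")
        aoi_df = io.read_table(cfg.aoi_path, "aoi")
        trajectories = {
            sid: DynamicAOIPair.from_frame(grp)
            for sid, grp in aoi_df.groupby("stimulus_id")
        }
        subjects = (
            io.read_table(cfg.subjects_path, "subjects")
            if cfg.subjects_path is not None
            else None
        )
        return samples, trajectories, subjects
    if cfg.sim is None:
        raise PipelineError("RunConfig needs either a SimConfig or input CSV paths")
    sim = replace(cfg.sim, seed=cfg.seed)
    samples, truth = synthetic.simulate_session(sim)
    subjects = aggregate.classify_subjects(truth.subjects)
    return samples, truth.aoi_trajectories, subjects


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full analysis and write all artefacts under ``cfg.out_dir``.

    Raises :class:`PipelineError` when no trial survives the minimum-looking
    exclusion.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    samples, trajectories, subjects = _load_inputs(cfg)
    log.info("loaded %d samples across %d trials", len(samples),
             samples.groupby(["subject_id", "trial_number"]).ngroups)

    # --- preprocess -------------------------------------------------------
    fixations, labeled = preprocess.process_samples(samples, trajectories, cfg.detector)
    kept, audit = preprocess.apply_exclusions(fixations, cfg.detector)
    # trials with zero detected fixations never reach the audit but are
    # excluded trials all the same
    n_total = int(samples.groupby(preprocess.TRIAL_KEYS).ngroups)
    n_kept = int(audit["kept"].sum()) if n_total else 0
    log.info("fixations: %d; trials: %d total, %d kept, %d excluded (<%g ms looking)",
             len(fixations), n_total, n_kept, n_total - n_kept,
             cfg.detector.min_trial_looking_ms)
    if n_kept == 0:
        raise PipelineError(
            f"zero analyzable trials: all {n_total} trials fell below "
            f"{cfg.detector.min_trial_looking_ms} ms of recorded looking"
        )
    kept_keys = audit.loc[audit["kept"], preprocess.TRIAL_KEYS]
    labeled_kept = labeled.merge(kept_keys, on=preprocess.TRIAL_KEYS, how="inner")

    paths["samples"] = io.write_table(samples, out / "samples.csv", "samples")
    paths["labeled_samples"] = io.write_table(labeled, out / "labeled_samples.csv", "samples")
    paths["fixations"] = io.write_table(fixations, out / "fixations.csv", "fixations")
    paths["exclusions"] = io.write_table(audit, out / "trial_exclusions.csv")
    aoi_frames = [t.to_frame(sid) for sid, t in trajectories.items()]
    paths["aoi"] = io.write_table(pd.concat(aoi_frames, ignore_index=True), out / "aoi_trajectories.csv", "aoi")
    if subjects is not None:
        paths["subjects"] = io.write_table(subjects, out / "subjects.csv", "subjects")

    # --- aggregate --------------------------------------------------------
    trial_dvs = aggregate.trial_totals(kept)
    condition_prefs = aggregate.condition_preference(trial_dvs)
    fix_long = aggregate.fixation_table(kept, subjects)
    paths["trial_dvs"] = io.write_table(trial_dvs, out / "trial_dvs.csv")
    paths["condition_prefs"] = io.write_table(condition_prefs, out / "condition_preferences.csv")
    paths["fixation_table"] = io.write_table(fix_long, out / "fixation_table.csv")

    # --- time courses -----------------------------------------------------
    trial_bins = timecourse.bin_trials(labeled_kept, cfg.bins)
    subj_all = timecourse.subject_timecourse(trial_bins, by_condition=False)
    subj_cond = timecourse.subject_timecourse(trial_bins, by_condition=True)

    scopes: Dict[str, pd.DataFrame] = {"all": subj_all}
    for race, speech in CONDITIONS:
        sel = subj_cond[(subj_cond["face_race"] == race) & (subj_cond["speech_type"] == speech)]
        if len(sel):
            scopes[condition_label(race, speech)] = sel

    group_tcs: Dict[str, pd.DataFrame] = {}
    cluster_tests: Dict[str, ClusterTestResult] = {}
    report_rows = []
    for k, (scope, tc) in enumerate(scopes.items()):
        ids, matrix = timecourse.subject_matrix(tc)
        if matrix.shape[0] < 2:
            log.warning("scope %s has <2 subjects; skipping cluster test", scope)
            continue
        group_tcs[scope] = timecourse.group_timecourse(matrix)
        perm_cfg = replace(cfg.perm, seed=_perm_seed(cfg.seed, k))
        res = cluster_permutation_test(matrix, perm_cfg, cfg.bins.bin_width_ms)
        cluster_tests[scope] = res
        report_rows.append(res.to_frame(scope))
        log.info("scope %s: %d subjects, %d clusters, null threshold %.4f",
                 scope, matrix.shape[0], len(res.clusters), res.null.threshold)

    report_rows = [r for r in report_rows if len(r)]
    cluster_report = (
        pd.concat(report_rows, ignore_index=True)
        if report_rows
        else pd.DataFrame(columns=io.SCHEMAS["clusters"])
    )

    # tidy time-course CSV across scopes
    tc_rows = []
    trial_tidy = trial_bins.copy()
    trial_tidy.insert(0, "scope", "trial")
    trial_tidy["condition"] = [
        condition_label(r, s) for r, s in zip(trial_tidy.pop("face_race"), trial_tidy.pop("speech_type"))
    ]
    tc_rows.append(trial_tidy)
    subj_tidy = subj_all.copy()
    subj_tidy.insert(0, "scope", "subject")
    subj_tidy["condition"] = "ALL"
    tc_rows.append(subj_tidy)
    sc = subj_cond.copy()
    sc.insert(0, "scope", "subject_condition")
    sc["condition"] = [
        condition_label(r, s) for r, s in zip(sc.pop("face_race"), sc.pop("speech_type"))
    ]
    tc_rows.append(sc)
    for scope, gtc in group_tcs.items():
        g = gtc.rename(columns={"mean_proportion_lower": "proportion_lower"}).copy()
        g.insert(0, "scope", "group")
        g["subject_id"] = "ALL"
        g["condition"] = "ALL" if scope == "all" else scope
        tc_rows.append(g)
    tidy_tc = pd.concat(tc_rows, ignore_index=True)
    paths["timecourses"] = io.write_table(tidy_tc, out / "timecourses.csv")

    report_out = cluster_report.copy()
    report_out["p_value"] = [format_p(p) for p in report_out["p_value"]]
    paths["clusters"] = io.write_table(report_out, out / "clusters.csv", "clusters")
    null_rows = [
        pd.DataFrame(
            {
                "condition": scope,
                "permutation": np.arange(res.null.n_permutations),
                "max_abs_mass": res.null.max_abs_masses,
                "threshold": res.null.threshold,
            }
        )
        for scope, res in cluster_tests.items()
    ]
    paths["null"] = io.write_table(pd.concat(null_rows, ignore_index=True), out / "null_distribution.csv")

    if cfg.make_figure and group_tcs:
        paths["figure"] = render_timecourse_figure(
            group_tcs,
            {s: r.clusters for s, r in cluster_tests.items()},
            out / "timecourse.png",
            bin_width_ms=cfg.bins.bin_width_ms,
            chance=cfg.bins.chance,
        )

    manifest = {
        "seed": cfg.seed,
        "config": {
            "sim": asdict(cfg.sim) if cfg.sim is not None and cfg.samples_path is None else None,
            "detector": asdict(cfg.detector),
            "bins": asdict(cfg.bins),
            "perm": asdict(cfg.perm),
        },
        "counts": {
            "samples": int(len(samples)),
            "fixations": int(len(fixations)),
            "trials_total": n_total,
            "trials_kept": n_kept,
            "trials_excluded": n_total - n_kept,
            "subjects": int(samples["subject_id"].nunique()),
        },
        "inputs": {
            k: {"path": str(p), "sha256": _digest(p)}
            for k, p in paths.items()
            if p.suffix == ".csv"
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = manifest_path

    return PipelineResult(
        fixations=fixations,
        kept_fixations=kept,
        exclusion_audit=audit,
        trial_dvs=trial_dvs,
        condition_prefs=condition_prefs,
        fixation_table=fix_long,
        timecourses=tidy_tc,
        group_timecourses=group_tcs,
        cluster_tests=cluster_tests,
        cluster_report=cluster_report,
        manifest=manifest,
        paths=paths,
    )


def render_timecourse_figure(
    group_tcs: Dict[str, pd.DataFrame],
    clusters: Dict[str, list],
    path: str | Path,
    bin_width_ms: float = 250.0,
    chance: float = 0.50,
) -> Path:
    """Publication-style time-course figure.

    One panel per scope (a 2x2 condition grid plus the all-trials panel when
    present): subject-weighted mean with 95% CI band, a horizontal line at
    chance, and line segments beneath the curve marking significant clusters.
    """
    scopes = list(group_tcs)
    n = len(scopes)
    ncols = 2 if n > 1 else 1
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(5.5 * ncols, 3.2 * nrows),
                             squeeze=False, sharey=True)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    for ax, scope in zip(axes.ravel(), scopes):
        g = group_tcs[scope]
        x = (g["bin_index"] + 0.5) * bin_width_ms
        ax.axhline(chance, color="grey", lw=1)
        ax.fill_between(x, g["ci_low"], g["ci_high"], alpha=0.25, lw=0)
        ax.plot(x, g["mean_proportion_lower"], lw=1.5)
        y0 = 0.06
        for c in clusters.get(scope, []):
            if c.significant:
                ax.plot([c.onset_ms, c.offset_ms], [y0, y0], lw=3, color="black",
                        solid_capstyle="butt")
        ax.set_ylim(0, 1)
        ax.set_title(scope)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("prop. looking lower half")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
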