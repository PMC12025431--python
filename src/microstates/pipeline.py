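"""Study-level orchestration: manifest in, report out.

``run_study`` executes the full workflow over a manifest of recordings:
preprocessing, GFP-peak extraction, subject-level clustering, condition-level
meta-clustering, TANOVA between condition topographies, canonical alignment,
back-fitting with smoothing, microstate parameters and transitions, pre/post
paired tests with Bonferroni correction, post-stage between-group mixed ANOVA
with Dunn's post hoc, and regressions of behavioral change rates on
microstate change rates. ``run_fixtures`` writes a synthetic study to disk so
the whole pipeline is exercisable without any acquired data.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .clustering import (TemplateSet, TopographySet, align_labels,
                         modified_kmeans)
from .gfp import compute_gfp, peak_maps, select_gfp_peaks
from .recording_io import (PipelineConfig, Recording, preprocess,
                           read_recording, write_recording)
from .segmentation import backfit, compute_params, smooth_segments
from .stats import (GROUPS, STAGES, bonferroni, dunn_posthoc, linear_fit,
                    mixed_anova, paired_t, read_behavior_table, tanova)

log = logging.getLogger("microstates")

PARAMETERS = ("duration", "coverage", "occurrence")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class StudyManifest:
    """Table of (participant, group, stage, recording path) plus the paths
    of the behavior table and config file."""

    rows: pd.DataFrame
    behavior_path: Path | None = None
    config_path: Path | None = None

    def __post_init__(self) -> None:
        required = {"participant", "group", "stage", "path"}
        missing = required - set(self.rows.columns)
        if missing:
            raise PipelineError(f"manifest missing columns: {sorted(missing)}")
        if self.rows.duplicated(["participant", "stage"]).any():
            raise PipelineError("duplicate (participant, stage) in manifest")
        bad_groups = set(self.rows["group"]) - set(GROUPS)
        if bad_groups:
            raise PipelineError(f"unknown groups in manifest: {bad_groups}")
        # every participant needs both stages
        stages = self.rows.groupby("participant")["stage"].apply(set)
        incomplete = stages[stages != set(STAGES)]
        if len(incomplete):
            raise PipelineError(
                "participants missing a stage recording: "
                + ", ".join(incomplete.index.astype(str)))

    def validate_paths(self) -> None:
        for _, row in self.rows.iterrows():
            if not Path(row["path"]).exists():
                raise PipelineError(
                    f"recording not found for participant {row['participant']}"
                    f" ({row['stage']}): {row['path']}")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyManifest":
        path = Path(path)
        rows = pd.read_csv(path)
        base = path.parent
        rows["path"] = rows["path"].map(lambda p: str((base / p).resolve())
                                        if not Path(p).is_absolute() else p)
        behavior = base / "behavior.csv"
        config = base / "pipeline.cfg"
        return cls(rows=rows,
                   behavior_path=behavior if behavior.exists() else None,
                   config_path=config if config.exists() else None)

    def to_file(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def run_fixtures(out_dir: str | Path, seed: int = 0,
                 n_per_group: int | dict[str, int] = 5,
                 length: float = 30.0,
                 n_channels: int = 64) -> StudyManifest:
    """Write a synthetic 3-group pre/post study and return its manifest.

    Recording length and cohort size default far below the full design so
    fixtures stay desk-sized; pass larger values to approach it.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"cannot create fixture directory: {exc}") from exc
    pre, post = synthetic.default_study_specs()
    from dataclasses import replace
    pre = replace(pre, length=length, n_channels=n_channels,
                  montage=synthetic.disk_montage(n_channels))
    post = {g: replace(s, length=length, n_channels=n_channels,
                       montage=pre.montage)
            for g, s in post.items()}
    study = synthetic.generate_study(pre, post, n_per_group=n_per_group,
                                     seed=seed)
    rows = []
    for record in study.records:
        fname = f"{record.participant}_{record.stage}.tsv"
        write_recording(record.recording, out_dir / fname)
        record.ground_truth.labels.to_files(
            out_dir / f"{record.participant}_{record.stage}_truth_labels.txt")
        rows.append((record.participant, record.group, record.stage, fname))
    study.behavior.to_csv(out_dir / "behavior.csv", index=False)
    PipelineConfig(seed=seed).to_file(out_dir / "pipeline.cfg")
    manifest = pd.DataFrame(rows, columns=["participant", "group", "stage",
                                           "path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return StudyManifest.from_file(out_dir / "manifest.csv")


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Everything run_study produces, with provenance."""

    condition_templates: dict[tuple[str, str], TemplateSet]
    participant_params: pd.DataFrame      # long: participant, group, stage,
    #                                       class, parameter, value
    transition_tables: dict[tuple[str, str], np.ndarray]
    summary: pd.DataFrame                 # Table-2-shaped mean +/- SEM
    stats: dict
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (group, stage), ts in self.condition_templates.items():
            ts.to_files(out_dir / f"templates_{group}_{stage}.tsv")
        self.participant_params.to_csv(out_dir / "participant_params.csv",
                                       index=False)
        self.summary.to_csv(out_dir / "summary.csv", index=False)
        with open(out_dir / "stats.json", "w") as fh:
            json.dump(self.stats, fh, indent=2, default=_jsonable)
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def _stage(name: str):
    """Context helper: log a stage and re-tag its failures."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.2f s", name, time.time() - self.t0)
            return False
    return _Ctx()


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_study(manifest: StudyManifest,
              config: PipelineConfig | None = None,
              k: int | None = 4) -> StudyReport:
    """Execute the complete analysis over a manifest.

    ``k`` fixes the number of classes (4 by default, the canonical choice);
    pass ``None`` to select k by the cross-validation criterion over
    ``config.k_range``.
    """
    config = config or (PipelineConfig.from_file(manifest.config_path)
                        if manifest.config_path else PipelineConfig())
    rng = np.random.default_rng(config.seed)

    with _stage("load+preprocess"):
        manifest.validate_paths()
        recs: dict[tuple[str, str], Recording] = {}
        meta: dict[str, str] = {}
        for _, row in manifest.rows.iterrows():
            rec = read_recording(row["path"])
            recs[(row["participant"], row["stage"])] = preprocess(rec, config)
            meta[row["participant"]] = row["group"]

    with _stage("gfp-peaks"):
        peak_sets = {}
        for key, rec in recs.items():
            g = compute_gfp(rec)
            peak_sets[key] = select_gfp_peaks(
                g, config.peak_min_interval, config.peak_outlier_sd,
                two_sided=config.outlier_two_sided)

    with _stage("subject-clustering"):
        channels = next(iter(recs.values())).channels
        # canonical maps on a generic disk layout, relabeled to the
        # recording's channels so alignment is well-defined
        _canon_cache: dict[int, TemplateSet] = {}

        def canonical_for(kk: int) -> TemplateSet:
            if kk not in _canon_cache:
                ts = synthetic.make_canonical_templates(
                    synthetic.disk_montage(len(channels)), kk,
                    seed=config.seed)
                _canon_cache[kk] = TemplateSet(templates=ts.templates,
                                               channels=channels,
                                               labels=ts.labels)
            return _canon_cache[kk]

        subject_templates: dict[tuple[str, str], TemplateSet] = {}
        for key, rec in recs.items():
            obs = TopographySet(maps=peak_maps(rec, peak_sets[key]),
                                channels=rec.channels)
            if k is not None:
                kk = k
            else:
                from .clustering import select_k
                kk, _ = select_k(obs, config.k_range, config.n_restarts,
                                 config.max_iter, config.convergence_tol,
                                 seed=rng)
            ts, _, _ = modified_kmeans(obs, kk, config.n_restarts,
                                       config.max_iter,
                                       config.convergence_tol, seed=rng)
            # order rows by canonical class and fix signs so later
            # class-wise pooling and group-mean maps are well-defined
            subject_templates[key] = align_labels(ts, canonical_for(kk))

    with _stage("condition-templates"):
        # second-level modified k-means over pooled subject template maps
        condition_templates: dict[tuple[str, str], TemplateSet] = {}
        for group in sorted(set(manifest.rows["group"])):
            for stage in STAGES:
                pool = [subject_templates[(p, stage)].templates
                        for p, g in meta.items() if g == group]
                k_cond = subject_templates[next(
                    (p, stage) for p, g in meta.items() if g == group)].k
                obs = TopographySet(maps=np.vstack(pool), channels=channels)
                ts, _, _ = modified_kmeans(obs, k_cond, config.n_restarts,
                                           config.max_iter,
                                           config.convergence_tol, seed=rng)
                condition_templates[(group, stage)] = align_labels(
                    ts, canonical_for(k_cond))

    with _stage("tanova"):
        tanova_results = {}
        groups_present = sorted(set(manifest.rows["group"]))
        class_labels = next(iter(condition_templates.values())).labels
        for stage in STAGES:
            for ci, cls in enumerate(class_labels):
                for i, g1 in enumerate(groups_present):
                    for g2 in groups_present[i + 1:]:
                        maps_1 = np.vstack(
                            [subject_templates[(p, stage)].templates[ci]
                             for p, gg in meta.items() if gg == g1])
                        maps_2 = np.vstack(
                            [subject_templates[(p, stage)].templates[ci]
                             for p, gg in meta.items() if gg == g2])
                        res = tanova(maps_1, maps_2,
                                     n_perm=config.n_permutations, seed=rng)
                        tanova_results[f"{stage}/{cls}/{g1}-vs-{g2}"] = {
                            "gmd": res.statistic, "p": res.p}

    with _stage("backfit+params"):
        rows = []
        transition_tables = {}
        for (pid, stage), rec in recs.items():
            ts = condition_templates[(meta[pid], stage)]
            labels = backfit(rec, ts)
            labels = smooth_segments(labels, rec, ts,
                                     config.smooth_min_duration)
            params = compute_params(
                labels, include_boundary_runs=config.include_boundary_runs)
            transition_tables[(pid, stage)] = params.transition_matrix
            for ci, cls in enumerate(class_labels):
                rows.append((pid, meta[pid], stage, cls, "duration",
                             params.duration[ci]))
                rows.append((pid, meta[pid], stage, cls, "coverage",
                             params.coverage[ci]))
                rows.append((pid, meta[pid], stage, cls, "occurrence",
                             params.occurrence[ci]))
        participant_params = pd.DataFrame(
            rows, columns=["participant", "group", "stage", "class",
                           "parameter", "value"])

    with _stage("summary"):
        post = participant_params[participant_params["stage"] == "post"]
        agg = post.groupby(["parameter", "class", "group"])["value"].agg(
            ["mean", "sem", "count"]).reset_index()
        summary = agg.rename(columns={"count": "n"})

    with _stage("stats"):
        stats_out: dict = {"tanova": tanova_results}
        stats_out["prepost"] = _prepost_tests(participant_params)
        stats_out["transitions"] = _transition_tests(
            transition_tables, meta, class_labels)
        stats_out["between_groups"] = _between_group_tests(
            participant_params, config)
        behavior = (read_behavior_table(manifest.behavior_path)
                    if manifest.behavior_path else None)
        stats_out["regressions"] = (_delta_regressions(
            participant_params, behavior, stats_out["prepost"], config)
            if behavior is not None else {})

    try:
        pkg_version = version("microstates")
    except PackageNotFoundError:
        pkg_version = "unknown"
    provenance = {"config": {f: getattr(config, f) for f in
                             ("band_low", "band_high", "target_srate",
                              "peak_min_interval", "peak_outlier_sd",
                              "k_range", "n_restarts", "max_iter",
                              "convergence_tol", "smooth_min_duration",
                              "n_permutations", "alpha", "seed")},
                  "config_hash": config.content_hash(),
                  "seed": config.seed,
                  "software_version": pkg_version}
    return StudyReport(condition_templates=condition_templates,
                       participant_params=participant_params,
                       transition_tables=transition_tables,
                       summary=summary, stats=stats_out,
                       provenance=provenance)


# ---------------------------------------------------------------------------
# Statistical sub-stages
# ---------------------------------------------------------------------------

def _prepost_tests(params: pd.DataFrame) -> dict:
    """Paired pre/post t-tests per group, class, and parameter, Bonferroni-
    corrected within each (group, parameter) family of K classes."""
    out: dict = {}
    for (group, parameter), sub in params.groupby(["group", "parameter"]):
        wide = sub.pivot_table(index="participant", columns=["class", "stage"],
                               values="value")
        family = []
        for cls in sorted(sub["class"].unique()):
            pre = wide[(cls, "pre")].to_numpy()
            post = wide[(cls, "post")].to_numpy()
            try:
                res = paired_t(post, pre)
                family.append((cls, res))
            except Exception:
                family.append((cls, None))
        pvals = [r.p for _, r in family if r is not None]
        corrected = bonferroni(pvals, len(family))
        it = iter(corrected)
        for cls, res in family:
            key = f"{group}/{parameter}/{cls}"
            if res is None:
                out[key] = None
            else:
                out[key] = {"t": res.statistic, "df": res.df, "p": res.p,
                            "p_bonferroni": next(it),
                            "cohens_d": res.effect_size}
    return out


def _transition_tests(tables: dict, meta: dict, class_labels) -> dict:
    """Paired pre/post tests on each directed transition probability."""
    out: dict = {}
    K = len(class_labels)
    for group in sorted(set(meta.values())):
        pids = [p for p, g in meta.items() if g == group]
        pre = np.stack([tables[(p, "pre")] for p in pids])
        post = np.stack([tables[(p, "post")] for p in pids])
        results = []
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                try:
                    res = paired_t(post[:, i, j], pre[:, i, j])
                except Exception:
                    results.append((i, j, None))
                    continue
                results.append((i, j, res))
        pvals = [r.p for _, _, r in results if r is not None]
        corrected = bonferroni(pvals, K * (K - 1))
        it = iter(corrected)
        for i, j, res in results:
            key = f"{group}/{class_labels[i]}->{class_labels[j]}"
            out[key] = (None if res is None else
                        {"t": res.statistic, "p": res.p,
                         "p_bonferroni": next(it),
                         "pre_mean": float(pre[:, i, j].mean()),
                         "post_mean": float(post[:, i, j].mean())})
    return out


def _between_group_tests(params: pd.DataFrame,
                         config: PipelineConfig) -> dict:
    """Post-stage mixed ANOVA (group x class) per parameter, with Dunn's
    post hoc per class when more than one group is present."""
    out: dict = {}
    post = params[params["stage"] == "post"]
    n_groups = post["group"].nunique()
    for parameter, sub in post.groupby("parameter"):
        entry: dict = {}
        if n_groups >= 2:
            try:
                table = mixed_anova(sub, dv="value", within="class",
                                    subject="participant", between="group")
                entry["mixed_anova"] = {name: {"F": f, "df1": d1, "df2": d2,
                                               "p": p}
                                        for name, (f, d1, d2, p)
                                        in table.effects.items()}
            except Exception as exc:
                entry["mixed_anova"] = {"error": str(exc)}
            entry["dunn"] = {}
            for cls, csub in sub.groupby("class"):
                try:
                    pair = dunn_posthoc(csub["value"].to_numpy(),
                                        csub["group"].to_numpy())
                    entry["dunn"][cls] = {
                        f"{g1}-vs-{g2}": {"z": r.statistic, "p": r.p,
                                          "p_bonferroni": r.corrected_p}
                        for (g1, g2), r in pair.items()}
                except Exception as exc:
                    entry["dunn"][cls] = {"error": str(exc)}
        out[parameter] = entry
    return out


def _delta_regressions(params: pd.DataFrame, behavior: pd.DataFrame,
                       prepost: dict, config: PipelineConfig) -> dict:
    """OLS of microstate change rates on behavioral change rates.

    Follows the study logic: only microstate (group, parameter, class) cells
    whose pre/post change was significant (Bonferroni-corrected) are
    regressed, against the same group's three-back accuracy and RT change
    rates.
    """
    out: dict = {}
    b = behavior[behavior["task"] == "three-back"]
    wide = b.pivot_table(index=["participant", "group"], columns="stage",
                         values=["accuracy", "rt"]).reset_index()
    wide.columns = ["participant", "group", "acc_post", "acc_pre",
                    "rt_post", "rt_pre"]
    wide["d_acc"] = (wide["acc_post"] - wide["acc_pre"]) / wide["acc_pre"]
    wide["d_rt"] = (wide["rt_post"] - wide["rt_pre"]) / wide["rt_pre"]
    for key, res in prepost.items():
        if res is None or res["p_bonferroni"] > config.alpha:
            continue
        group, parameter, cls = key.split("/")
        sub = params[(params["group"] == group)
                     & (params["parameter"] == parameter)
                     & (params["class"] == cls)]
        pw = sub.pivot_table(index="participant", columns="stage",
                             values="value")
        pw = pw[pw["pre"] != 0]
        delta = ((pw["post"] - pw["pre"]) / pw["pre"]).rename("d_param")
        merged = wide[wide["group"] == group].merge(delta, on="participant")
        for bcol in ("d_acc", "d_rt"):
            try:
                fit = linear_fit(merged[bcol].to_numpy(),
                                 merged["d_param"].to_numpy())
            except Exception:
                continue
            out[f"{key}~{bcol}"] = {"slope": fit.slope,
                                    "intercept": fit.intercept,
                                    "r2": fit.r2, "p": fit.p,
                                    "n": int(len(merged))}
    return out
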