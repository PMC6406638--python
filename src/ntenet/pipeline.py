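"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
graphs -> statistics -> classification.

Outputs land in a run directory with one sub-directory per stage
(``raw/``, ``preprocessed/``, ``nte/``, ``graphs/``, ``stats/``,
``classify/``, ``logs/``); the validated config and its hash are archived
next to them, and every table carries the producing config hash. A stage
failure aborts the run with a stage-named error and leaves an
``INCOMPLETE`` marker.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import graphs as gm
from .channels import CHANNELS
from .classify import SequentialForwardSelector, evaluate
from .config import RunConfig
from .connectivity import NTEMatrix, nte_matrix
from .datasets import STATES, make_cohort
from .features import WindowFeatureExtractor, cohort_windows, FEATURE_NAMES
from .flows import (anova_multicompare, hemisphere_flows,
                    mean_information_flow, region_flows, welch_ttest)
from .io import write_csv, write_sidecar
from .preprocess import filter_recording
from .recording import epoch_by_state, reject_bad_epochs

logger = logging.getLogger(__name__)

TASK_STATES = ("drawing", "manipulation")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise stage-named
                raise StageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@dataclasses.dataclass
class RunReport:
    run_dir: Path
    config_hash: str
    nte: dict          # (subject_id, state) -> NTEMatrix
    metrics: pd.DataFrame
    stats: dict[str, pd.DataFrame]
    classification: dict | None


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    run_dir = Path(out_dir) if out_dir is not None else \
        Path(f"ntenet-run-{datetime.now():%Y%m%d-%H%M%S}")
    for sub in ("raw", "preprocessed", "nte", "graphs", "stats", "classify",
                "logs"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    marker = run_dir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    log_handler = logging.FileHandler(run_dir / "logs" / "run.log")
    logging.getLogger("ntenet").addHandler(log_handler)
    chash = config.config_hash()
    config.to_yaml(run_dir / "config.yaml")
    (run_dir / "config.hash").write_text(chash + "\n")
    try:
        cohort = _simulate(config, run_dir)
        clean = _preprocess(config, cohort, run_dir)
        nte = _connectivity(config, clean, run_dir, chash)
        metrics = _graphs(config, nte, run_dir, chash)
        stats = _stats(config, nte, run_dir, chash)
        classification = _classify(config, clean, run_dir, chash)
    finally:
        logging.getLogger("ntenet").removeHandler(log_handler)
        log_handler.close()
    marker.unlink()
    return RunReport(run_dir, chash, nte, metrics, stats, classification)


@_stage("simulate")
def _simulate(config: RunConfig, run_dir: Path):
    s = config.synthetic
    cohort = make_cohort(s.n_novice, s.n_expert, seed=config.seed, fs=s.fs,
                         duration_scale=s.duration_scale,
                         noise_sd=s.noise_sd,
                         line_noise_amplitude=s.line_noise_amplitude)
    for rec, profile, coupling in cohort:
        base = run_dir / "raw" / profile.subject_id
        write_csv(rec, base.with_suffix(".csv"))
        write_sidecar(base.with_suffix(".csv"), rec.fs, profile, coupling)
    return cohort


@_stage("preprocess")
def _preprocess(config: RunConfig, cohort, run_dir: Path):
    p = config.preprocess
    out = []
    for rec, profile, coupling in cohort:
        filtered = filter_recording(rec, order=p.filter_order,
                                    lowpass=p.lowpass_hz,
                                    highpass=p.highpass_hz,
                                    notches=tuple(p.notch_hz))
        write_csv(filtered, run_dir / "preprocessed"
                  / f"{profile.subject_id}.csv")
        write_sidecar(run_dir / "preprocessed" / f"{profile.subject_id}.csv",
                      filtered.fs, profile)
        out.append((filtered, profile, coupling))
    return out


@_stage("connectivity")
def _connectivity(config: RunConfig, cohort, run_dir: Path, chash: str):
    p, c = config.preprocess, config.connectivity
    nte: dict[tuple[str, str], NTEMatrix] = {}
    for rec, profile, _ in cohort:
        for state in config.states:
            es = epoch_by_state(rec, state, p.epoch_seconds,
                                p.epoch_step_seconds)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                es = reject_bad_epochs(es, p.amplitude_limit)
            if len(es) == 0:
                logger.warning("%s/%s: no clean epochs, skipping",
                               profile.subject_id, state)
                continue
            m = nte_matrix(es, B=c.B, n_shuffles=c.n_shuffles,
                           seed=config.seed)
            m.to_tsv(run_dir / "nte" / f"{profile.subject_id}_{state}.tsv")
            nte[(profile.subject_id, state)] = m
    return nte


@_stage("graphs")
def _graphs(config: RunConfig, nte, run_dir: Path, chash: str):
    g = config.graphs
    rows = []
    for (subject, state), m in nte.items():
        dg = gm.binarize(m, g.threshold)
        gm.write_graphml(dg, run_dir / "graphs" / f"{subject}_{state}.graphml")
        sw = gm.small_world_index(dg, n_random=g.n_random, seed=config.seed)
        census = gm.motif_census(dg)
        strengths = gm.node_strengths(m)
        rows.append({
            "subject": subject, "state": state,
            "connectivity_density": gm.connectivity_density(dg),
            "motif_total": census.total,
            "C_d": sw.C_d, "C_rand": sw.C_rand,
            "L_d": sw.L_d, "L_rand": sw.L_rand, "sigma": sw.sigma,
            **{f"strength_{ch}": v
               for ch, v in strengths.as_dict().items()},
        })
    df = pd.DataFrame(rows)
    df["config_hash"] = chash
    df.to_csv(run_dir / "graphs" / "metrics.csv", index=False)
    return df


@_stage("stats")
def _stats(config: RunConfig, nte, run_dir: Path, chash: str):
    subjects = sorted({s for s, _ in nte})
    out: dict[str, pd.DataFrame] = {}

    # Per-electrode mean information flow per subject and state.
    if_rows = []
    for (subject, state), m in nte.items():
        flows = mean_information_flow(m)
        if_rows.append({"subject": subject, "state": state,
                        **dict(zip(CHANNELS, flows))})
    if_df = pd.DataFrame(if_rows)
    if_df["config_hash"] = chash
    if_df.to_csv(run_dir / "stats" / "mean_information_flow.csv", index=False)
    out["mean_information_flow"] = if_df

    # ANOVA with multiple comparison across states, per subject.
    anova_rows = []
    for subject in subjects:
        groups, labels = [], []
        for state in config.states:
            if (subject, state) in nte:
                groups.append(mean_information_flow(nte[(subject, state)]))
                labels.append(state)
        if len(groups) < 2:
            continue
        res = anova_multicompare(groups, labels)
        for cmp in res.comparisons:
            anova_rows.append({
                "subject": subject, "state_a": cmp.group_a,
                "state_b": cmp.group_b,
                "mean_difference": cmp.mean_difference,
                "ci_low": cmp.ci_low, "ci_high": cmp.ci_high,
                "p": cmp.p, "stars": "*" if cmp.significant else "",
                "F": res.f, "p_overall": res.p,
            })
    anova_df = pd.DataFrame(anova_rows)
    anova_df["config_hash"] = chash
    anova_df.to_csv(run_dir / "stats" / "anova_mean_if.csv", index=False)
    out["anova_mean_if"] = anova_df

    # Pairwise Welch t-tests between states: per-electrode clustering
    # coefficients and hemisphere-wise outflows.
    g_thr = config.graphs.threshold
    welch_rows = []
    state_pairs = [(b, a) for i, a in enumerate(config.states)
                   for b in config.states[i + 1:]]
    for subject in subjects:
        per_state = {}
        for state in config.states:
            if (subject, state) not in nte:
                continue
            m = nte[(subject, state)]
            per_state[state] = {
                "clustering": gm.clustering_coefficients(
                    gm.binarize(m, g_thr)),
                **{f"flow_{k}": v for k, v in
                   hemisphere_flows(m).outflows.items()},
            }
        for b, a in state_pairs:
            if a not in per_state or b not in per_state:
                continue
            for measure in per_state[a]:
                res = welch_ttest(per_state[b][measure],
                                  per_state[a][measure])
                welch_rows.append({
                    "subject": subject, "state_a": b, "state_b": a,
                    "measure": measure,
                    "mean_difference": res.mean_difference,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "df": res.df, "t": res.t, "p": res.p,
                    "stars": "*" if res.significant else "",
                })
    welch_df = pd.DataFrame(welch_rows)
    welch_df["config_hash"] = chash
    welch_df.to_csv(run_dir / "stats" / "welch_state_comparisons.csv",
                    index=False)
    out["welch_state_comparisons"] = welch_df

    # Region flows shaped like the study's lobe-wise table.
    region_rows = []
    for (subject, state), m in nte.items():
        rf = region_flows(m)
        region_rows.append({"subject": subject, "state": state, **rf.flows,
                            "Max": rf.max_pair, "Min": rf.min_pair})
    region_df = pd.DataFrame(region_rows)
    region_df["config_hash"] = chash
    region_df.to_csv(run_dir / "stats" / "region_flows.csv", index=False)
    out["region_flows"] = region_df
    return out


@_stage("classify")
def _classify(config: RunConfig, cohort, run_dir: Path, chash: str):
    cls = config.classify
    task_present = [s for s in TASK_STATES if s in config.states]
    if not task_present:
        logger.info("classification skipped: no task state requested")
        (run_dir / "classify" / "SKIPPED").write_text(
            "no task state in config.states\n")
        return None
    windows = cohort_windows(cohort, tuple(task_present),
                             win_seconds=cls.window_seconds,
                             step_seconds=cls.window_step_seconds)
    labels = np.array([w.label for w in windows])
    if len(np.unique(labels)) < 2:
        logger.warning("classification skipped: only one class present")
        (run_dir / "classify" / "SKIPPED").write_text("single class\n")
        return None
    extractor = WindowFeatureExtractor(
        B=config.connectivity.B, n_shuffles=config.connectivity.n_shuffles,
        seed=config.seed)
    X = extractor.fit(windows).transform(windows)
    feat_df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    feat_df.insert(0, "label", labels)
    feat_df.to_csv(run_dir / "classify" / "features.csv", index=False)
    sfs = SequentialForwardSelector(cls.classifier, cls.cv_folds,
                                    cls.max_features, config.seed, cls.k)
    sfs.fit(X, labels)
    report = evaluate(X, labels, cls.classifier, sfs.selected_features_,
                      cls.cv_folds, config.seed)
    payload = {"config_hash": chash, "classifier": cls.classifier,
               "accuracy_trace": sfs.trace_,
               "elapsed_seconds": sfs.elapsed_seconds_,
               **report.as_dict()}
    (run_dir / "classify" / "report.json").write_text(
        json.dumps(payload, indent=1))
    return payload
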