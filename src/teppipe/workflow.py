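"""End-to-end orchestration: simulate -> preprocess -> features ->
classify -> permutation statistics, driven by one seeded config."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clf as clf_mod
from . import features as feat_mod
from . import io as io_mod
from . import permstat, prep, synthgen
from .containers import Cohort
from .montage import ROIS, TIME_WINDOWS, RoiSpec, make_default_layout

logger = logging.getLogger("teppipe")

__all__ = ["RunConfig", "RunReport", "run_all", "make_fixtures",
           "preprocess_cohort", "simulate_group_features", "subject_traces"]

_KNOWN_KEYS = {
    "n_ci", "n_hc", "n_trials", "sfreq", "noise_sd", "seed", "smooth_len",
    "classifiers", "reduction", "n_dims", "mode", "perplexity",
    "n_perm", "adjacency_radius", "out_dir", "lmfp_calibration",
    "per_trial_jitter",
}


@dataclass(frozen=True)
class RunConfig:
    """One knob per pipeline stage; a single master seed drives everything."""

    n_ci: int = 21
    n_hc: int = 22
    n_trials: int = 100
    sfreq: float = 1000.0
    noise_sd: float = 2.0
    per_trial_jitter: float = 0.0
    lmfp_calibration: bool = True
    seed: int = 0
    smooth_len: int = 20
    classifiers: tuple[str, ...] = ("svm_linear", "rf", "knn")
    reduction: str = "none"
    n_dims: int = 3
    mode: str = "leakage_safe"
    perplexity: float = 10.0
    n_perm: int = 1000
    adjacency_radius: float = permstat.DEFAULT_RADIUS
    out_dir: str = "teppipe_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "classifiers" in raw:
            raw = dict(raw)
            raw["classifiers"] = tuple(raw["classifiers"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def gen_params(self) -> synthgen.GenParams:
        return synthgen.GenParams(
            noise_sd=self.noise_sd,
            n_trials=self.n_trials,
            sfreq=self.sfreq,
            seed=self.seed,
            per_trial_jitter=self.per_trial_jitter,
            lmfp_target=dict(synthgen.DEFAULT_LMFP_TARGET)
            if self.lmfp_calibration else None,
        )

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    features_path: str
    report_path: str
    clusters_path: str
    metrics: dict
    skipped_stages: tuple[str, ...] = prep.SKIPPED_STAGES


def preprocess_cohort(cohort: Cohort,
                      config: prep.PrepConfig | None = None) -> Cohort:
    """Preprocess every subject's epochs; metadata is preserved."""
    cfg = config or prep.PrepConfig()
    out = []
    for s in cohort:
        out.append(dataclasses.replace(s, epochs=prep.preprocess(s.epochs, cfg)))
    return Cohort(out)


def simulate_group_features(group: str, n_subjects: int,
                            params: synthgen.GenParams,
                            prep_config: prep.PrepConfig | None = None,
                            smooth_len: int = 20) -> pd.DataFrame:
    """Simulate, preprocess and feature-extract a single-group cohort,
    streaming one subject at a time (memory stays flat in cohort size).

    Subject seeds match :func:`teppipe.synthgen.simulate_group` exactly.
    """
    cfg = prep_config or prep.PrepConfig()
    master = np.random.default_rng(params.seed)
    seeds = master.integers(0, 2**31 - 1, size=n_subjects)

    def stream():
        for i in range(n_subjects):
            rec = synthgen.simulate_subject(group, params, int(seeds[i]),
                                            subject_id=f"{group}{i + 1:03d}")
            yield dataclasses.replace(rec, epochs=prep.preprocess(rec.epochs, cfg))

    return feat_mod.build_feature_table(stream(), smooth_len)


def subject_traces(cohort: Cohort, smooth: bool = False,
                   smooth_len: int = 20) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-subject all-trial TEP traces: (n_subjects, channels, samples)."""
    traces = []
    groups = []
    times = None
    for s in cohort:
        tr = feat_mod.average_trials(s.epochs)
        if smooth:
            tr = feat_mod.gaussian_smooth(tr, smooth_len)
        traces.append(tr.data)
        groups.append(s.group)
        times = tr.times
    return np.stack(traces), times, groups


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write features.csv / report.json /
    clusters.json (plus a run log) into the configured output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    try:
        return _run_all(config, out_dir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run_all(config: RunConfig, out_dir: Path) -> RunReport:
    chash = config.hash()
    logger.info("run %s: simulating %d+%d subjects", chash,
                config.n_ci, config.n_hc)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    # Subjects are simulated, preprocessed and feature-extracted one at a
    # time; only the feature rows and the per-subject all-trial average
    # traces (needed by the permutation test) are retained.
    params = stage("synth", config.gen_params)
    prep_cfg = prep.PrepConfig()
    master = np.random.default_rng(params.seed)
    n_total = config.n_ci + config.n_hc
    seeds = master.integers(0, 2**31 - 1, size=n_total)
    roster = ([("CI", f"CI{i + 1:03d}") for i in range(config.n_ci)]
              + [("HC", f"HC{i + 1:03d}") for i in range(config.n_hc)])
    traces: list[np.ndarray] = []
    groups: list[str] = []
    times = None
    layout = params.layout

    def stream():
        nonlocal times
        for (group, sid), seed in zip(roster, seeds):
            logger.info("run %s: subject %s", chash, sid)
            rec = synthgen.simulate_subject(group, params, int(seed),
                                            subject_id=sid)
            rec = dataclasses.replace(
                rec, epochs=prep.preprocess(rec.epochs, prep_cfg))
            avg = feat_mod.average_trials(rec.epochs)
            traces.append(avg.data)
            groups.append(group)
            times = avg.times
            yield rec

    table = stage("features", feat_mod.build_feature_table, stream(),
                  config.smooth_len)
    features_path = io_mod.save_features(table, out_dir / "features.csv",
                                         config_hash=chash)

    red = clf_mod.ReductionSpec(method=config.reduction, n_dims=config.n_dims,
                                mode=config.mode, perplexity=config.perplexity,
                                seed=config.seed)
    metrics = {}
    per_subject = {}
    for algo in config.classifiers:
        logger.info("run %s: LOOCV with %s", chash, algo)
        spec = clf_mod.ClassifierSpec(algorithm=algo, seed=config.seed)
        report = stage(f"classify[{algo}]", clf_mod.loocv_vote, table, spec, red)
        metrics[algo] = {"confusion": report.confusion, **report.metrics,
                         "leakage_flag": report.leakage_flag}
        per_subject[algo] = report.per_subject

    report_path = io_mod.write_json({
        "config_hash": chash,
        "config": dataclasses.asdict(config),
        "skipped_stages": list(prep.SKIPPED_STAGES),
        "metrics": metrics,
        "per_subject": per_subject,
    }, out_dir / "report.json")

    logger.info("run %s: permutation statistics", chash)
    trace_stack = np.stack(traces)
    group_arr = np.asarray(groups)
    adjacency = permstat.build_adjacency(layout, config.adjacency_radius)
    cluster_out = {"config_hash": chash, "windows": {}}
    for wname, window in TIME_WINDOWS.items():
        res = stage(f"permtest[{wname}]", permstat.permutation_test,
                    trace_stack[group_arr == "CI"],
                    trace_stack[group_arr == "HC"],
                    times, adjacency, window,
                    config.n_perm, config.seed)
        cluster_out["windows"][wname] = [
            {
                "channels": [adjacency.names[c] for c in cl.channels],
                "time_extent_ms": [float(res.times[cl.sample_range[0]] * 1e3),
                                   float(res.times[cl.sample_range[1]] * 1e3)],
                "mass": cl.mass,
                "p_perm": cl.p_perm,
                "tail": cl.tail,
                "significant": cl.p_perm < res.alpha_perm,
            }
            for cl in res.clusters
        ]
    clusters_path = io_mod.write_json(cluster_out, out_dir / "clusters.json")

    return RunReport(config_hash=chash,
                     features_path=str(features_path),
                     report_path=str(report_path),
                     clusters_path=str(clusters_path),
                     metrics=metrics)


def fixture_rois() -> dict[str, RoiSpec]:
    """Seven overlapping two-channel ROIs over the 8 fixture channels."""
    return {
        "Fl": RoiSpec("Fl", ("F1", "F3", "FC3", "FC5")),
        "Fr": RoiSpec("Fr", ("F2", "F4", "FC4", "FC6")),
        "C": RoiSpec("C", ("F1", "F2")),
        "Cp": RoiSpec("Cp", ("F3", "F4")),
        "Pl": RoiSpec("Pl", ("FC3", "FC5")),
        "Pr": RoiSpec("Pr", ("FC4", "FC6")),
        "O": RoiSpec("O", ("FC5", "FC6")),
    }


def make_fixtures(out_dir: str | Path | None = None
                  ) -> tuple[Cohort, dict[str, RoiSpec]]:
    """A 4-subject, 9-trial, 8-channel micro-cohort for fast tests.

    The eight channels are the bilateral frontal ROI members; the seven
    analysis ROIs are remapped onto (overlapping) pairs of them so the
    full 98-column feature surface still exists.  Byte-stable across runs.
    """
    layout = make_default_layout().subset(
        list(ROIS["Fl"].channels) + list(ROIS["Fr"].channels))
    params = synthgen.GenParams(
        layout=layout, n_trials=9, noise_sd=1.0, seed=2024,
        lmfp_target=dict(synthgen.DEFAULT_LMFP_TARGET),
    )
    cohort = synthgen.simulate_cohort(2, 2, params)
    if out_dir is not None:
        io_mod.save_cohort(cohort, out_dir)
    return cohort, fixture_rois()
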