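"""End-to-end orchestration: simulate -> preprocess -> QPP detection ->
projection -> regression -> FC -> classification.

Everything is driven by a :class:`PipelineConfig` and a single master seed;
re-running with the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import fc as fcmod
from .core import concat_group, split_concat
from .detect import QPPDetector, StcSeries
from .fc import NetworkSpec, fc_matrix, network_fc
from .metrics import compare_rates, occurrence_rates, qpp_contrast, template_similarity
from .preprocess import run_preprocess
from .regress import regress_qpp
from .simulate import CohortConfig, synthesize_cohort

log = logging.getLogger("qppdyn")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

ALL_STAGES = ["simulate", "preprocess", "qpp", "regress", "fc", "classify"]

# canonical QPP roster: name -> (group whose series it is derived from,
# window length in seconds)
DEFAULT_QPPS = {
    "QPP_WT": ("WT", 3.0),
    "QPP_TG": ("TG", 3.0),
    "QPP_GS": ("WT", 6.0),
}


@dataclass
class PipelineConfig:
    """All knobs of the full analysis, nested by stage."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    qpps: dict = field(default_factory=lambda: dict(DEFAULT_QPPS))
    # preprocessing
    trim: int = 20
    low_hz: float = 0.01
    high_hz: float = 0.2
    smooth_sigma: float = 0.75  # sigma=2 at a 128-wide matrix, rescaled to 48
    gsr: bool = False
    # detection
    n_starts: int = 500
    threshold: float = 0.2
    max_iter: int = 20
    min_separation: int | None = None  # None: one full window between peaks
    # classification
    repeats: int = 10
    folds: int = 10
    n_boot: int = 2000
    compare_models: str = "combined_vs_single"  # or "all_pairs" / "none"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    @classmethod
    def fast(cls, **overrides) -> "PipelineConfig":
        """Reduced profile: 10-minute scans and 50 restarts."""
        cfg = cls(cohort=CohortConfig(n_frames=1200), n_starts=50)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    config: PipelineConfig
    seed: int
    truth: object = None
    atlas: object = None
    raw: list = field(default_factory=list)
    preprocessed: list = field(default_factory=list)
    concats: dict = field(default_factory=dict)  # group -> ConcatSeries
    qpps: dict = field(default_factory=dict)  # name -> dict
    fc_before: dict = field(default_factory=dict)  # sid -> FcMatrix
    fc_after: dict = field(default_factory=dict)  # (sid, qpp) -> FcMatrix
    measures: dict = field(default_factory=dict)  # sid -> measure dict
    table: pd.DataFrame | None = None
    rate_tests: pd.DataFrame | None = None
    report: clf.ClassificationReport | None = None


class StageError(RuntimeError):
    """A stage was requested whose inputs were not produced."""


def _require(condition, stage: str, what: str):
    if not condition:
        raise StageError(f"stage {stage!r} is missing its input: {what}")


def _subject_stc_segment(stc: StcSeries, start: int, end: int) -> StcSeries:
    return StcSeries(
        values=stc.values[start:end].copy(),
        valid=stc.valid[start:end].copy(),
        peaks=stc.peaks[(stc.peaks >= start) & (stc.peaks < end)] - start,
        threshold=stc.threshold,
    )


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0,
                 outdir=None) -> PipelineResult:
    """Run the configured stages end to end on a synthetic cohort.

    Returns the in-memory result bundle; when ``outdir`` is given the
    standard artefacts (ground truth JSON, measure table CSV, QPP record
    HDF5, rate statistics CSV, classification report JSON) are written.
    """
    config = config if config is not None else PipelineConfig()
    res = PipelineResult(config=config, seed=int(seed))
    stages = list(config.stages)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config_used.yaml")
    seeds = np.random.SeedSequence([int(seed), 901])
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(["detect", "classify", "boot"], seeds.spawn(3))
    }

    # ---- simulate ----------------------------------------------------
    if "simulate" in stages:
        log.info("simulate: %d+%d subjects, T=%d, TR=%.3gs", config.cohort.n_wt,
                 config.cohort.n_tg, config.cohort.n_frames, config.cohort.tr_seconds)
        res.raw, res.truth, res.atlas = synthesize_cohort(config.cohort, seed=seed)
        if out is not None:
            res.truth.to_json(out / "ground_truth.json")
            res.atlas.to_files(out / "atlas.nii", out / "atlas_labels.json")

    # ---- preprocess --------------------------------------------------
    if "preprocess" in stages:
        _require(res.raw, "preprocess", "raw series (run simulate first)")
        for s in res.raw:
            motion = res.truth.motion.get(s.subject_id) if res.truth else None
            res.preprocessed.append(
                run_preprocess(s, motion=motion, low=config.low_hz,
                               high=config.high_hz, trim=config.trim,
                               smooth_sigma=config.smooth_sigma, gsr=config.gsr)
            )
        for group in ("WT", "TG"):
            members = [s for s in res.preprocessed if s.group == group]
            if members:
                res.concats[group] = concat_group(members)

    # ---- qpp detection + projection ---------------------------------
    if "qpp" in stages:
        _require(res.concats, "qpp", "preprocessed group series")
        tr = config.cohort.tr_seconds
        det_root = np.random.SeedSequence([stage_seed["detect"]])
        children = det_root.spawn(len(config.qpps))
        for (name, (src_group, win_sec)), child in zip(config.qpps.items(), children):
            src = res.concats[src_group]
            other_group = "TG" if src_group == "WT" else "WT"
            W = int(round(win_sec / tr))
            det = QPPDetector(
                window_frames=W, n_starts=config.n_starts,
                threshold=config.threshold, max_iter=config.max_iter,
                min_separation=(config.min_separation
                                if config.min_separation is not None else W),
                tr_seconds=tr,
                random_state=int(child.generate_state(1)[0] % (2**31 - 1)),
            )
            det.fit(src.data.T, boundaries=src.boundaries)
            record = det.best_record_
            record.template.name = name
            record.template.group = src_group
            entry = {
                "detector": det, "record": record, "source_group": src_group,
                "window_frames": W,
                "contrast": qpp_contrast(record.template),
                "stc": {src_group: record.stc},
                "rates": occurrence_rates(record.stc, src.boundaries, tr),
            }
            if other_group in res.concats:
                tgt = res.concats[other_group]
                pstc = det.project(tgt.data.T, boundaries=tgt.boundaries)
                entry["stc"][other_group] = pstc
                entry["rates"].update(occurrence_rates(pstc, tgt.boundaries, tr))
            res.qpps[name] = entry
            log.info("qpp %s: %d peaks in %s, peak_sum=%.2f, contrast=%.3g",
                     name, record.stc.n_peaks, src_group, record.peak_sum,
                     entry["contrast"])
        # group comparison of occurrence rates
        rows = []
        for name, entry in res.qpps.items():
            by_group = {"WT": [], "TG": []}
            for s in res.preprocessed:
                by_group[s.group].append(entry["rates"][s.subject_id])
            if len(by_group["WT"]) >= 2 and len(by_group["TG"]) >= 2:
                t, p = compare_rates(by_group["WT"], by_group["TG"])
                rows.append({
                    "qpp": name, "mean_rate_wt": float(np.mean(by_group["WT"])),
                    "mean_rate_tg": float(np.mean(by_group["TG"])), "t": t, "p": p,
                })
        res.rate_tests = pd.DataFrame(rows)

    # ---- regression + fc --------------------------------------------
    if "regress" in stages or "fc" in stages:
        _require(res.qpps, "regress/fc", "selected QPP records")
        spec = NetworkSpec.from_atlas(res.atlas)
        for s in res.preprocessed:
            sid = s.subject_id
            fcm = fc_matrix(s, res.atlas)
            res.fc_before[sid] = fcm
            meas = {
                "FC_DMN": network_fc(fcm, spec, "DMN"),
                "FC_TPN": network_fc(fcm, spec, "TPN"),
                "FC_DMN_TPN": network_fc(fcm, spec, "DMN_TPN"),
            }
            for name, entry in res.qpps.items():
                meas[f"rate_{name}"] = entry["rates"][sid]
                stc = entry["stc"][s.group]
                start, end = res.concats[s.group].segment(sid)
                seg = _subject_stc_segment(stc, start, end)
                resid = regress_qpp(s, entry["record"], stc_segment=seg)
                fca = fc_matrix(resid, res.atlas, condition=f"after_{name}")
                res.fc_after[(sid, name)] = fca
                meas[f"FC_DMN_after_{name}"] = network_fc(fca, spec, "DMN")
                meas[f"FC_DMN_TPN_after_{name}"] = network_fc(fca, spec, "DMN_TPN")
                meas[f"dFC_DMN_{name}"] = meas[f"FC_DMN_after_{name}"] - meas["FC_DMN"]
                meas[f"dFC_DMN_TPN_{name}"] = (
                    meas[f"FC_DMN_TPN_after_{name}"] - meas["FC_DMN_TPN"])
            res.measures[sid] = meas
        groups = {s.subject_id: s.group for s in res.preprocessed}
        columns = [c for c in clf.DEFAULT_MEASURES
                   if all(q in res.qpps for q in _needed_qpps(c))]
        res.table = clf.build_measure_table(res.measures, groups, columns=columns)

    # ---- classification ---------------------------------------------
    if "classify" in stages:
        _require(res.table is not None, "classify", "measure table")
        rng = np.random.default_rng(stage_seed["classify"])
        models = {}
        measure_cols = [c for c in res.table.columns if c != "group"]
        for name in measure_cols + ["combined"]:
            predictors = measure_cols if name == "combined" else [name]
            models[name] = clf.elastic_net_cv(
                res.table, predictors=predictors, repeats=config.repeats,
                folds=config.folds,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
        report = clf.ClassificationReport(models=models)
        report.betas = pd.DataFrame(models["combined"]["betas"], columns=measure_cols)
        if config.compare_models != "none":
            if config.compare_models == "all_pairs":
                pairs = [(a, b) for i, a in enumerate(models) for b in list(models)[i + 1:]]
            else:
                pairs = [("combined", m) for m in measure_cols]
            rows = []
            brng = np.random.default_rng(stage_seed["boot"])
            for a, b in pairs:
                p = clf.compare_auc_bootstrap(
                    models[a]["oof_scores"], models[b]["oof_scores"],
                    models[a]["labels"], n_boot=config.n_boot,
                    random_state=int(brng.integers(0, 2**31 - 1)),
                )
                rows.append({"model_a": a, "model_b": b,
                             "auc_a": models[a]["mean_auc"],
                             "auc_b": models[b]["mean_auc"], "p": p})
            comp = pd.DataFrame(rows)
            comp["p_bonferroni"] = clf.bonferroni(comp["p"].to_numpy(), m=len(rows))
            report.comparisons = comp
        res.report = report

    # ---- artefacts ---------------------------------------------------
    if out is not None:
        _write_outputs(res, out)
    return res


def _needed_qpps(column: str) -> list[str]:
    return [q for q in ("QPP_WT", "QPP_TG", "QPP_GS") if q in column]


def _write_outputs(res: PipelineResult, out: Path) -> None:
    if res.table is not None:
        res.table.to_csv(out / "measure_table.csv", float_format="%.10g")
    if res.rate_tests is not None:
        res.rate_tests.to_csv(out / "rate_tests.csv", index=False,
                              float_format="%.10g")
    if res.qpps:
        with h5py.File(out / "qpp_records.h5", "w") as fh:
            for name, entry in res.qpps.items():
                g = fh.create_group(name)
                rec = entry["record"]
                g.create_dataset("template", data=rec.template.data, track_times=False)
                g.attrs["window_frames"] = entry["window_frames"]
                g.attrs["source_group"] = entry["source_group"]
                g.attrs["contrast"] = entry["contrast"]
                g.attrs["converged"] = rec.converged
                g.attrs["iterations"] = rec.iterations
                g.attrs["start_frame_seed"] = rec.start_frame_seed
                g.attrs["peak_sum"] = rec.peak_sum
                for grp, stc in entry["stc"].items():
                    sg = g.create_group(f"stc_{grp}")
                    sg.create_dataset("values", data=stc.values, track_times=False)
                    sg.create_dataset("valid", data=stc.valid, track_times=False)
                    sg.create_dataset("peaks", data=stc.peaks, track_times=False)
                rg = g.create_group("rates")
                for sid, rate in sorted(entry["rates"].items()):
                    rg.attrs[sid] = rate
    if res.report is not None:
        with open(out / "classification_report.json", "w") as fh:
            json.dump(res.report.to_json_dict(), fh, indent=1, sort_keys=True)
        res.report.betas.to_csv(out / "combined_model_betas.csv", index=False,
                                float_format="%.10g")


def recovery_summary(res: PipelineResult) -> dict:
    """Score recovered patterns and rates against the planted ground truth.

    Returns, per canonical QPP, the best spatial correlation to the planted
    template (over lags and sign) and the median relative error of
    per-subject occurrence-rate estimates against planted rates.
    """
    planted_of = {"QPP_WT": "WT_like", "QPP_TG": "TG_like", "QPP_GS": "GS_like"}
    cfg = res.config.cohort
    out = {}
    # planted occurrences are counted on the same analysed span the peak
    # counts cover: the scan minus the two transient-trim passes at each end
    start = 2 * res.config.trim
    span = cfg.n_frames - 4 * res.config.trim
    minutes = span * cfg.tr_seconds / 60.0
    for name, entry in res.qpps.items():
        kind = planted_of.get(name)
        if kind is None or res.truth is None:
            continue
        r, lag, sign = template_similarity(
            entry["record"].template, res.truth.templates[kind],
            max_lag=entry["window_frames"],
        )
        rel_errors = []
        for sid, grp in res.truth.groups.items():
            if grp != entry["source_group"]:
                continue  # rates are scored in the group the QPP came from
            occ = np.asarray(res.truth.occurrences.get((sid, kind), []))
            # only events whose window lies fully inside the analysed span
            # are observable by the estimator
            W = res.truth.templates[kind].window_frames
            n_planted = int(np.sum((occ >= start) & (occ <= start + span - W)))
            est = entry["rates"].get(sid)
            if est is None or n_planted == 0:
                continue
            planted_rate = n_planted / minutes
            rel_errors.append(abs(est - planted_rate) / planted_rate)
        out[name] = {
            "spatial_r": r, "lag": lag, "sign": sign,
            "rate_median_rel_error": float(np.median(rel_errors)) if rel_errors else float("nan"),
            "analysed_minutes": minutes,
        }
    return out
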