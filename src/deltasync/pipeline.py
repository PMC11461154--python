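"""End-to-end orchestration: simulate or ingest, preprocess, PSV, inference.

Stages per participant: common-average reference -> broadband (0.5-40 Hz)
FIR filter -> band split -> epoching by events -> Hilbert phase per epoch
-> windowed PSV under both stimulus segmentation schemes (plus rest spans)
-> hierarchical averaging to one PSV per condition x pair. The cohort PSV
tables then feed the per-pair mixed RM-ANOVA with BH-FDR over pairs, and a
significance report with baseline (rest, eyes open) screening.

Everything is driven by a YAML config with exactly one input mode
(``simulate`` or ``ingest``); a run is deterministic given its seed and
leaves a JSON provenance record with per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import psv as _psv
from .core_data import (
    CONDITIONS,
    REST_STATES,
    EventStream,
    Recording,
    default_montage,
    electrode_pairs,
    read_events,
    read_manifest,
    read_recording,
    slice_epoch,
)
from .preprocess import (
    BROADBAND,
    DEFAULT_BANDS,
    FilterSpec,
    fir_bandpass,
    rereference_common_average,
)
from .psv import SCHEMES, EpochSkipped, phase_matrix_batch
from .stats_inference import (
    add_design_columns,
    anova_by_pair,
    format_report,
    significance_report,
)
from .synthetic_eeg import CohortConfig, ParticipantBundle, iter_cohort

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "validate_config",
    "run_pipeline",
    "participant_condition_psv",
    "cohort_psv_table",
]

log = logging.getLogger("deltasync")

PSV_COLUMNS = ["participant", "group", "condition", "band", "scheme",
               "pair_a", "pair_b", "psv"]


@dataclass
class PipelineConfig:
    mode: str = "simulate"                    # simulate | ingest
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ingest_manifest: str | None = None        # manifest YAML (ingest mode)
    ingest_dir: str | None = None             # dir of <pid>.{npz|edf} + <pid>_events.csv
    bands: tuple = ("delta", "theta", "alpha")
    schemes: tuple = ("whole_stimuli", "first_two_seconds")
    include_rest: bool = True
    alpha: float = 0.05
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    psv_table: pd.DataFrame
    anova_tables: dict      # (band, scheme) -> DataFrame
    reports: dict           # (band, scheme) -> DataFrame
    provenance: dict


def validate_config(source) -> PipelineConfig:
    """Normalise a YAML path / dict into a PipelineConfig.

    All violations are collected and raised together as one ValueError.
    Validation is a fixpoint: re-validating the echoed config is a no-op.
    """
    if isinstance(source, PipelineConfig):
        doc = asdict(source)
        doc["cohort"] = asdict(source.cohort)
        doc["cohort"]["coupling"] = source.cohort.coupling
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
    errors = []
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        errors.append(f"unknown config fields: {sorted(unknown)}")
    mode = doc.get("mode", "simulate")
    if mode not in ("simulate", "ingest"):
        errors.append(f"mode must be 'simulate' or 'ingest', got {mode!r}")
    if mode == "ingest":
        for key in ("ingest_manifest", "ingest_dir"):
            path = doc.get(key)
            if not path:
                errors.append(f"ingest mode requires {key}")
            elif not os.path.exists(path):
                errors.append(f"{key}: no such path {path!r}")
    cohort_doc = doc.get("cohort", {})
    cohort = None
    if isinstance(cohort_doc, CohortConfig):
        cohort = cohort_doc
    else:
        coupling = cohort_doc.pop("coupling", None) if isinstance(
            cohort_doc, dict) else None
        if coupling is not None and not isinstance(coupling, dict):
            errors.append("cohort.coupling must be a mapping")
            coupling = None
        if coupling:
            coupling = {
                tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
                for k, v in coupling.items()
            }
        try:
            cohort = CohortConfig(**{**(cohort_doc or {}),
                                     **({"coupling": coupling} if coupling else {})})
        except (TypeError, ValueError) as exc:
            errors.append(f"cohort: {exc}")
    for band in doc.get("bands", ("delta", "theta", "alpha")):
        if band not in DEFAULT_BANDS or band == "broadband":
            errors.append(f"unknown analysis band {band!r}")
    for scheme in doc.get("schemes", ("whole_stimuli", "first_two_seconds")):
        if scheme not in SCHEMES or scheme == "rest":
            errors.append(f"unknown stimulus scheme {scheme!r}")
    alpha = doc.get("alpha", 0.05)
    if not 0 < alpha <= 1:
        errors.append(f"alpha must be in (0, 1], got {alpha}")
    if errors:
        raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    cfg = PipelineConfig(
        mode=mode,
        cohort=cohort,
        ingest_manifest=doc.get("ingest_manifest"),
        ingest_dir=doc.get("ingest_dir"),
        bands=tuple(doc.get("bands", ("delta", "theta", "alpha"))),
        schemes=tuple(doc.get("schemes", ("whole_stimuli", "first_two_seconds"))),
        include_rest=bool(doc.get("include_rest", True)),
        alpha=float(alpha),
        out_dir=doc.get("out_dir"),
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "INFO")),
    )
    if cfg.mode == "simulate":
        cfg.cohort = replace(cfg.cohort, seed=cfg.seed)
    return cfg


# ---------------------------------------------------------------------------
# Per-participant computation
# ---------------------------------------------------------------------------

def participant_condition_psv(rec: Recording, events: EventStream,
                              cond_map: dict, *, bands=("delta",),
                              schemes=("whole_stimuli",),
                              include_rest: bool = True,
                              roi=None, montage=None,
                              rest_offset_s: float = 15.0,
                              rest_span_s: float = 75.0,
                              counts: dict | None = None) -> pd.DataFrame:
    """One participant's PSV per (band, scheme, condition, pair).

    ``cond_map`` maps event labels to conditions (stimulus cells and rest
    states). The continuous recording is referenced and filtered before
    epoching; phase is computed once per epoch, then windowed.
    """
    montage = montage or default_montage()
    if roi is not None:
        montage = replace(montage, roi=tuple(roi))
    pairs = electrode_pairs(montage)
    if rec.reference == "raw":
        rec = rereference_common_average(rec)
    # the reference needs every channel; everything after only the ROI
    roi_idx = [rec.labels.index(ch) for ch in montage.roi]
    rec = rec.copy_with(data=rec.data[roi_idx], labels=montage.roi)
    broad = fir_bandpass(rec, BROADBAND, FilterSpec())
    roi_idx = list(range(len(montage.roi)))

    # epoch table: (condition, onset, duration, scheme kind)
    demo_epochs, rest_epochs = [], []
    for ev in events:
        cond = cond_map.get(ev.label)
        if cond in CONDITIONS:
            demo_epochs.append((cond, ev.time_s, ev.duration_s, ev.label))
        elif cond in REST_STATES and include_rest:
            span = min(rest_span_s, ev.duration_s - rest_offset_s)
            if span > 0:
                rest_epochs.append(
                    (cond, ev.time_s + rest_offset_s, span, ev.label)
                )
    rows = []
    idx = {ch: i for i, ch in enumerate(montage.roi)}
    all_epochs = demo_epochs + (rest_epochs if include_rest else [])
    for band_name in bands:
        banded = fir_bandpass(broad, DEFAULT_BANDS[band_name], FilterSpec())
        # phase once per epoch (batched over epochs), windowed per scheme
        slices = [slice_epoch(banded, onset, dur)
                  for _, onset, dur, _ in all_epochs]
        phases = phase_matrix_batch([s.data for s in slices])
        demo_phases = phases[: len(demo_epochs)]
        rest_phases = phases[len(demo_epochs):]

        for scheme_name in schemes:
            scheme = SCHEMES[scheme_name]
            per_cond = {}
            for (cond, onset, dur, label), ph, sl in zip(
                    demo_epochs, demo_phases, slices):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mat = _psv.psv_epoch_matrix(
                            ph, banded.rate, sl.duration_s, scheme,
                            epoch_id=label,
                        )
                except EpochSkipped:
                    if counts is not None:
                        counts["epochs_skipped"] = counts.get(
                            "epochs_skipped", 0) + 1
                    log.debug("skipped epoch %s under %s", label, scheme_name)
                    continue
                per_cond.setdefault(cond, []).append(mat)
            for cond, mats in per_cond.items():
                mean_mat = np.mean(mats, axis=0)
                for p in pairs:
                    rows.append((cond, band_name, scheme_name, p.a, p.b,
                                 float(mean_mat[idx[p.a], idx[p.b]])))
        if include_rest:
            for (cond, onset, dur, label), ph, sl in zip(
                    rest_epochs, rest_phases, slices[len(demo_epochs):]):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mat = _psv.psv_epoch_matrix(
                            ph, banded.rate, sl.duration_s, _psv.REST,
                            epoch_id=label,
                        )
                except EpochSkipped:
                    continue
                for p in pairs:
                    rows.append((cond, band_name, "rest", p.a, p.b,
                                 float(mat[idx[p.a], idx[p.b]])))
    if counts is not None:
        counts["epochs_used"] = counts.get("epochs_used", 0) + len(demo_epochs)
    return pd.DataFrame(
        rows, columns=["condition", "band", "scheme", "pair_a", "pair_b", "psv"]
    )


def _iter_ingest(cfg: PipelineConfig):
    manifest = read_manifest(cfg.ingest_manifest)
    for pid, group in manifest.participants:
        base = os.path.join(cfg.ingest_dir, pid)
        rec_path = base + ".npz" if os.path.exists(base + ".npz") else base + ".edf"
        rec = read_recording(rec_path)
        events = read_events(base + "_events.csv")
        yield (ParticipantBundle(pid, group, rec, events),
               manifest.epochs.get(pid, []))


def cohort_psv_table(bundle_iter, *, bands, schemes, include_rest=True,
                     roi=None, rest_offset_s=15.0, rest_span_s=75.0,
                     counts=None) -> pd.DataFrame:
    """Tidy cohort PSV table from an iterator of (bundle, epoch entries)."""
    frames = []
    for bundle, entries in bundle_iter:
        table = participant_condition_psv(
            bundle.recording, bundle.events, dict(entries),
            bands=bands, schemes=schemes, include_rest=include_rest,
            roi=roi, rest_offset_s=rest_offset_s, rest_span_s=rest_span_s,
            counts=counts,
        )
        table.insert(0, "participant", bundle.participant_id)
        table.insert(1, "group", bundle.group)
        frames.append(table)
        if counts is not None:
            counts["participants"] = counts.get("participants", 0) + 1
    return pd.concat(frames, ignore_index=True)[PSV_COLUMNS]


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _baseline_anova(psv_table: pd.DataFrame, band: str) -> pd.DataFrame | None:
    """Per-pair Group ANOVA on eyes-open rest PSVs (within factor Posture)."""
    rest = psv_table[
        (psv_table.scheme == "rest")
        & (psv_table.band == band)
        & (psv_table.condition.isin(["sit-open", "stand-open"]))
    ]
    if rest.empty or rest.condition.nunique() < 2:
        return None  # needs both eyes-open postures
    rest = rest.copy()
    rest["posture"] = rest["condition"].map(
        {"sit-open": "Sitting", "stand-open": "Standing"}
    )
    return anova_by_pair(rest, within=("posture",))


def run_pipeline(config) -> PipelineResult:
    """Run the full analysis and (optionally) write run artifacts."""
    cfg = validate_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    file_handler = None
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        file_handler = logging.FileHandler(
            os.path.join(cfg.out_dir, "run.log"), mode="w")
        file_handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        file_handler.setLevel(logging.INFO)
        log.addHandler(file_handler)
        if log.level in (logging.NOTSET, logging.WARNING):
            log.setLevel(logging.INFO)
    t0 = time.time()
    counts = {}
    if cfg.mode == "simulate":
        bundle_iter = iter_cohort(cfg.cohort)
        rest_offset = cfg.cohort.rest_analysis_offset_s
        rest_span = cfg.cohort.rest_analysis_span_s
    else:
        bundle_iter = _iter_ingest(cfg)
        rest_offset, rest_span = 15.0, 75.0

    t_stage = time.time()
    log.info("stage: psv tables (bands=%s schemes=%s)", cfg.bands, cfg.schemes)
    psv_table = cohort_psv_table(
        bundle_iter, bands=cfg.bands, schemes=cfg.schemes,
        include_rest=cfg.include_rest, rest_offset_s=rest_offset,
        rest_span_s=rest_span, counts=counts,
    )
    counts["psv_rows"] = len(psv_table)
    log.info("stage: psv tables done in %.1fs (%d rows)",
             time.time() - t_stage, len(psv_table))

    anova_tables, reports = {}, {}
    for band in cfg.bands:
        baseline = _baseline_anova(psv_table, band) if cfg.include_rest else None
        for scheme in cfg.schemes:
            sub = psv_table[(psv_table.band == band)
                            & (psv_table.scheme == scheme)]
            if sub.empty:
                continue
            design = add_design_columns(sub)
            anova = anova_by_pair(design)
            report = significance_report(
                anova, design, alpha=cfg.alpha, baseline_df=baseline
            )
            anova_tables[(band, scheme)] = anova
            reports[(band, scheme)] = report
            log.info("stage: inference %s/%s -> %d significant rows",
                     band, scheme, len(report))
    counts["report_rows"] = int(sum(len(r) for r in reports.values()))

    cfg_doc = asdict(cfg)
    cfg_doc["cohort"]["coupling"] = {
        "/".join(k): v for k, v in cfg.cohort.coupling.items()
    }
    provenance = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_doc, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": cfg_doc,
        "counts": counts,
        "runtime_s": round(time.time() - t0, 3),
    }

    if cfg.out_dir:
        psv_table.to_csv(os.path.join(cfg.out_dir, "psv_table.csv"),
                         index=False)
        for (band, scheme), anova in anova_tables.items():
            anova.to_csv(
                os.path.join(cfg.out_dir, f"anova_{band}_{scheme}.csv"),
                index=False,
            )
        for (band, scheme), report in reports.items():
            stem = os.path.join(cfg.out_dir, f"report_{band}_{scheme}")
            report.to_csv(stem + ".csv", index=False)
            with open(stem + ".txt", "w") as fh:
                fh.write(format_report(report, f"{band} / {scheme}"))
        with open(os.path.join(cfg.out_dir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
    log.info("run complete in %.1fs", provenance["runtime_s"])
    if file_handler is not None:
        log.removeHandler(file_handler)
        file_handler.close()
    return PipelineResult(psv_table, anova_tables, reports, provenance)
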