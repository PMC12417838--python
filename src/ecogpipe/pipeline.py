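"""End-to-end orchestration: synth -> preprocess -> spectra -> features ->
connectivity -> statistics -> classification, as a configured, seeded run.

Every stage writes its artifacts under the run directory and the manifest
records the configuration, seeds and per-stage bookkeeping (channel/row
counts), so a run is reproducible from the manifest alone.  The default
configuration generates a scaled-down synthetic cohort (30 channels per
compartment, 60 s at a 500 Hz analysis rate) that exercises every stage in a
few minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aperiodic import aperiodic_feature_block
from .classify import (FEATURE_COLUMNS, SplitSpec, assemble_features,
                       collapse_labels, cross_validate, evaluate,
                       feature_matrix, make_model, split_train_test)
from .connectivity import PLV_BANDS, compartment_plv_summary, plv_matrix
from .io import Recording, bandpass_zero_phase, reject_artifacts, resample, write_plain
from .spectral import band_powers, remove_line_noise, welch_psd
from .stats import compartment_summary, stratify_and_correlate
from .synth import SynthConfig, generate_infiltration_table, generate_recording

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Synthetic-cohort sizes default to a desk-scale study: 30 channels per
    compartment, 60 s at 500 Hz.  All analysis parameters carry their
    standard defaults (0.1 Hz high-pass, Chebyshev II order 4 / 40 dB, 2 s
    Hann Welch windows with 50% overlap, 50 Hz mains +/- 1 Hz, 70/30
    stratified split, 5-fold CV).
    """

    seed: int = 0
    # synthetic cohort
    channels_per_compartment: dict[str, int] = field(default_factory=lambda: {
        "tumoral": 30, "close_peritumoral": 30,
        "far_peritumoral": 30, "healthy": 30})
    sampling_rate: float = 500.0
    duration: float = 60.0
    n_patients: int = 1
    # stage toggles
    do_preprocess: bool = True
    do_plv: bool = True
    do_stats: bool = True
    do_classify: bool = True
    write_recording: bool = False
    # preprocessing
    filter_low_hz: float = 0.1
    filter_high_hz: float = 250.0
    filter_order: int = 4
    stopband_atten_db: float = 40.0
    resample_hz: float | None = None
    amplitude_z_threshold: float = 6.0
    flatline_epsilon: float = 1e-15
    # spectra
    welch_window_seconds: float = 2.0
    welch_overlap: float = 0.5
    mains_hz: float = 50.0
    mains_half_width_hz: float = 1.0
    # infiltration
    n_biopsies: int = 26
    infiltration_feature: str = "abs_beta"
    infiltration_rho: float = -0.5
    # classification
    train_fraction: float = 0.7
    cv_folds: int = 5
    models: tuple[str, ...] = ("knn_ensemble", "svm")
    two_class_scheme: str = "tumoral_vs_nontumoral"

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            sampling_rate=self.sampling_rate, duration=self.duration,
            channels_per_compartment=dict(self.channels_per_compartment),
            seed=self.seed, n_patients=self.n_patients)


def compute_feature_table(recording: Recording, config: PipelineConfig,
                          ) -> tuple[pd.DataFrame, dict]:
    """Preprocess a recording and compute its 38-column feature table.

    Returns the table and a bookkeeping dict (removed channels, dropped rows).
    """
    info: dict = {}
    rec = recording
    if config.do_preprocess:
        high = min(config.filter_high_hz, 0.45 * rec.sampling_rate)
        if high < config.filter_high_hz:
            logger.info("passband high edge capped at %.1f Hz", high)
        rec = bandpass_zero_phase(rec, config.filter_low_hz, high,
                                  order=config.filter_order,
                                  stopband_atten_db=config.stopband_atten_db)
        if config.resample_hz and config.resample_hz < rec.sampling_rate:
            rec = resample(rec, config.resample_hz)
    mask = reject_artifacts(rec, config.amplitude_z_threshold,
                            config.flatline_epsilon)
    info["removed_channels"] = list(mask.removed_channels)
    spectrum = welch_psd(rec, mask, config.welch_window_seconds,
                         config.welch_overlap)
    spectrum = remove_line_noise(spectrum, config.mains_hz,
                                 config.mains_half_width_hz)
    bp = band_powers(spectrum)
    ap = aperiodic_feature_block(spectrum)
    table = assemble_features(bp, ap, rec.meta_frame())
    info["n_channels"] = rec.n_channels
    info["n_feature_rows"] = len(table)
    return table, info


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured run, write artifacts, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": _config_dict(config),
        "stages": {},
    }

    rec, gt = generate_recording(config.synth_config())
    manifest["stages"]["synth"] = {
        "n_channels": rec.n_channels,
        "duration_s": rec.duration,
        "sampling_rate_hz": rec.sampling_rate,
    }
    if config.write_recording:
        write_plain(rec, out / "recording")
        gt.to_json(out / "recording" / "ground_truth.json")

    table, info = compute_feature_table(rec, config)
    manifest["stages"]["features"] = info
    table.to_csv(out / "features.tsv", sep="\t", index=False,
                 float_format="%.10g")

    if config.do_stats:
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        summary, pairwise = compartment_summary(table, FEATURE_COLUMNS)
        summary.to_csv(stats_dir / "compartment_summary.tsv", sep="\t",
                       index=False, float_format="%.6g")
        pairwise.to_csv(stats_dir / "dunn_pairwise.tsv", sep="\t",
                        index=False, float_format="%.6g")
        biopsies = generate_infiltration_table(
            table, config.infiltration_feature, config.infiltration_rho,
            config.n_biopsies, seed=config.seed + 1)
        biopsies.to_csv(stats_dir / "biopsies.tsv", sep="\t", index=False)
        corr = stratify_and_correlate(biopsies, table)
        corr.to_csv(stats_dir / "infiltration_correlations.tsv", sep="\t",
                    index=False, float_format="%.6g")
        manifest["stages"]["stats"] = {
            "n_features_tested": len(summary),
            "n_biopsies": len(biopsies),
        }

    if config.do_plv:
        plv_dir = out / "plv"
        plv_dir.mkdir(exist_ok=True)
        labels = [gt.labels[c] for c in rec.channel_ids]
        summaries = {}
        for band_name in PLV_BANDS:
            m = plv_matrix(rec, band_name)
            m.frame().to_csv(plv_dir / f"plv_{band_name}.tsv", sep="\t",
                             float_format="%.6g")
            s = compartment_plv_summary(m, labels)
            summaries[band_name] = json.loads(s.matrix.to_json())
        (plv_dir / "summary.json").write_text(json.dumps(summaries, indent=1))
        manifest["stages"]["plv"] = {"bands": list(PLV_BANDS)}

    if config.do_classify:
        cls_dir = out / "classify"
        cls_dir.mkdir(exist_ok=True)
        reports = _classification_stage(table, config, cls_dir)
        manifest["stages"]["classify"] = reports

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _classification_stage(table: pd.DataFrame, config: PipelineConfig,
                          out_dir: Path) -> dict:
    spec = SplitSpec(train_fraction=config.train_fraction, stratified=True,
                     seed=config.seed + 2)
    train, test = split_train_test(table, spec)
    X_tr, y_tr4 = feature_matrix(train)
    X_te, y_te4 = feature_matrix(test)
    results: dict = {"n_train": len(train), "n_test": len(test)}
    for model_kind in config.models:
        for scheme in ("4class", "2class"):
            if scheme == "4class":
                ytr, yte, Xtr, Xte = y_tr4, y_te4, X_tr, X_te
            else:
                ytr, keep_tr = collapse_labels(y_tr4, config.two_class_scheme)
                yte, keep_te = collapse_labels(y_te4, config.two_class_scheme)
                Xtr, ytr = X_tr[keep_tr], ytr[keep_tr]
                Xte, yte = X_te[keep_te], yte[keep_te]
            cv = cross_validate(Xtr, ytr, model_kind, k=config.cv_folds,
                                seed=config.seed + 3)
            model = make_model(model_kind, seed=config.seed + 4,
                               **cv["best_params"])
            model.fit(Xtr, ytr)
            report = evaluate(yte, model.predict(Xte), scheme=scheme)
            doc = report.to_dict()
            doc["cv_best_params"] = cv["best_params"]
            doc["cv_mean_macro_f1"] = cv["mean_score"]
            name = f"{model_kind}_{scheme}"
            (out_dir / f"report_{name}.json").write_text(
                json.dumps(doc, indent=1, default=str))
            report.confusion.to_csv(out_dir / f"confusion_{name}.tsv", sep="\t")
            results[name] = {
                "f1_macro": report.f1_macro,
                "precision_macro": report.precision_macro,
                "recall_macro": report.recall_macro,
                "accuracy": report.accuracy,
                "cv_best_params": cv["best_params"],
            }
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["models"] = list(d["models"])
    return d


def config_from_dict(doc: dict) -> PipelineConfig:
    """Build a config from a plain (YAML/JSON) mapping; unknown keys error."""
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "models" in doc:
        doc = dict(doc)
        doc["models"] = tuple(doc["models"])
    return PipelineConfig(**doc)
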