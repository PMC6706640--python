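"""End-to-end pipeline: simulate (or load) -> windows -> quantify -> ROC ->
classify -> report, from a single validated configuration.

All randomness flows from one root seed split per stage, every artifact
records the configuration fingerprint, and a run is byte-reproducible:
identical config + seed give identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .benchmark import auc, confusion_at_cutoff, roc_curve, select_cutoff
from .classify import classification_summary, classify_binding_mode
from .interactions import quantify_study, write_interaction_table
from .mixdesign import MixDesign, compile_peak_windows, overlap_score
from .processing import Thresholds
from .simulate import simulate_screen
from .spectra import read_spectrum, SampleMeasurement
from .tables import (
    ReferenceSet,
    read_reference_set,
    read_similarity_table,
    read_windows,
    write_windows,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see :func:`validate_config`)."""

    seed: int
    thresholds: Thresholds = Thresholds()
    target_fpr: float = 0.05
    similarity_threshold: float = 0.5
    aggregation_policy: str = "mean"
    synthesis: dict | None = None
    inputs: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def fingerprint(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


_SYNTHESIS_KEYS = {
    "n_proteins",
    "n_metabolites",
    "binder_fraction",
    "kd_min",
    "kd_max",
    "noise_sd",
    "n_mixes",
    "shift_offset_sd",
    "r_free",
    "r_bound",
    "protein_conc",
    "metabolite_conc",
}


def validate_config(config) -> tuple[RunConfig | None, list]:
    """Validate a config mapping (or YAML text); errors are collected, not
    raised one at a time."""
    if isinstance(config, str):
        try:
            config = yaml.safe_load(config)
        except yaml.YAMLError as exc:
            return None, [f"config is not valid YAML: {exc}"]
    if not isinstance(config, dict):
        return None, ["config must be a mapping"]
    errors: list[str] = []

    seed = config.get("seed")
    synthesis = config.get("synthesis")
    if synthesis is not None and not isinstance(synthesis, dict):
        errors.append("synthesis block must be a mapping")
        synthesis = None
    if seed is None and synthesis is not None:
        errors.append("seed is required for any stochastic stage (synthesis present)")
    if seed is not None and not isinstance(seed, int):
        errors.append("seed must be an integer")

    th = config.get("thresholds", {}) or {}
    stability_max = th.get("stability_max", 0.05)
    gain_min = th.get("gain_min", -0.05)
    snr_min = th.get("snr_min", 2.0)
    target_fpr = th.get("target_fpr", 0.05)
    similarity_threshold = th.get("similarity_threshold", 0.5)
    if not isinstance(stability_max, (int, float)) or stability_max < 0:
        errors.append("stability_max must be >= 0")
    if not isinstance(snr_min, (int, float)) or snr_min < 0:
        errors.append("snr_min must be >= 0")
    if not isinstance(gain_min, (int, float)) or gain_min > 0:
        errors.append("gain_min must be <= 0")
    if not isinstance(target_fpr, (int, float)) or not 0 <= target_fpr <= 1:
        errors.append("target_fpr must lie in [0, 1]")
    if not isinstance(similarity_threshold, (int, float)) or not (
        0 <= similarity_threshold <= 1
    ):
        errors.append("similarity_threshold must lie in [0, 1]")

    policy = config.get("aggregation_policy", "mean")
    if policy not in ("mean", "median", "max"):
        errors.append(f"unknown aggregation_policy {policy!r}")

    if synthesis is not None:
        unknown = set(synthesis) - _SYNTHESIS_KEYS
        if unknown:
            errors.append(f"unknown synthesis keys: {sorted(unknown)}")

    inputs = config.get("inputs", {}) or {}
    if synthesis is None and "measurements_dir" not in inputs:
        errors.append("either a synthesis block or inputs.measurements_dir is required")
    if synthesis is None and "measurements_dir" in inputs and "windows" not in inputs:
        errors.append("loading measured spectra requires inputs.windows")

    if errors:
        return None, errors
    cfg = RunConfig(
        seed=int(seed) if seed is not None else 0,
        thresholds=Thresholds(
            stability_max=float(stability_max),
            gain_min=float(gain_min),
            snr_min=float(snr_min),
        ),
        target_fpr=float(target_fpr),
        similarity_threshold=float(similarity_threshold),
        aggregation_policy=policy,
        synthesis=synthesis,
        inputs=inputs,
        raw=config,
    )
    return cfg, []


# ----------------------------------------------------------------------


def load_measurements(directory: str | Path) -> list:
    """Group spectrum files of a directory into sample measurements.

    Expects three spin-lock spectra (short_a, long, short_b) per sample_id.
    """
    directory = Path(directory)
    by_sample: dict = {}
    for path in sorted(directory.glob("*.txt")):
        spec = read_spectrum(path)
        by_sample.setdefault(spec.sample_id, {})[spec.experiment] = spec
    measurements = []
    for sid, specs in sorted(by_sample.items()):
        needed = {"t1rho_short_a", "t1rho_long", "t1rho_short_b"}
        if not needed.issubset(specs):
            raise ValueError(f"sample {sid!r}: missing {sorted(needed - set(specs))}")
        long = specs["t1rho_long"]
        measurements.append(
            SampleMeasurement(
                sample_id=sid,
                role=long.role,
                short_a=specs["t1rho_short_a"],
                short_b=specs["t1rho_short_b"],
                long=long,
                protein_id=long.protein_id,
                mix_id=long.mix_id,
                long_delay_ms=long.spin_lock_ms,
            )
        )
    return measurements


def design_from_assignment(mix_of: dict, peak_lists: dict) -> MixDesign:
    """Wrap an existing mix assignment (mix ids 'mix1', 'mix2', ...) as a
    MixDesign with its recomputed overlap score."""
    mixes = sorted(set(mix_of.values()))
    index = {mx: i for i, mx in enumerate(mixes)}
    assignment = {met: index[mx] for met, mx in mix_of.items()}
    score = overlap_score(assignment, peak_lists)
    return MixDesign(assignment=assignment, score=score, n_mixes=len(mixes))


def run_pipeline(config: RunConfig, output_dir: str | Path) -> dict:
    """Execute all pipeline stages and write artifacts plus a JSON report.

    Stages: synthesize (or load) measurements, compile peak windows,
    calibrate/filter/quantify into the interaction matrix, calibrate the
    detection cutoff on the reference set at the target FPR, and classify
    binding modes when a similarity table is available (otherwise that stage
    is recorded as skipped).
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "t1screen", "version": __version__},
        "config_fingerprint": config.fingerprint(),
        "seed": config.seed,
        "stages": {},
    }

    # --- stage: measurements -----------------------------------------
    reference: ReferenceSet | None = None
    if config.synthesis is not None:
        syn = dict(config.synthesis)
        kd_min = syn.pop("kd_min", 10.0)
        kd_max = syn.pop("kd_max", 500.0)
        truth_kwargs = {
            k: syn.pop(k)
            for k in ("r_free", "r_bound", "protein_conc", "metabolite_conc")
            if k in syn
        }
        study = simulate_screen(
            seed=config.seed, kd_range=(kd_min, kd_max), **syn, **truth_kwargs
        )
        measurements = study.measurements
        peak_lists = study.peak_lists
        mix_of = study.mix_of
        reference = ReferenceSet(
            {pair: "regulatory" for pair in sorted(study.truth.binders())}
        )
        report["stages"]["simulate"] = {
            "n_measurements": len(measurements),
            "n_proteins": len(study.proteins),
            "n_metabolites": len(study.metabolites),
            "n_true_binders": len(study.truth.binders()),
        }
    else:
        measurements = load_measurements(config.inputs["measurements_dir"])
        peak_lists = {}
        mix_of = {}
        report["stages"]["load"] = {"n_measurements": len(measurements)}

    # --- stage: windows ----------------------------------------------
    if "windows" in config.inputs:
        windows = read_windows(config.inputs["windows"])
        uncovered: list = []
    else:
        design = design_from_assignment(mix_of, peak_lists)
        windows, uncovered = compile_peak_windows(design, peak_lists)
    write_windows(windows, outdir / "windows.csv")
    report["stages"]["windows"] = {
        "n_windows": len(windows),
        "uncovered_metabolites": list(uncovered),
    }

    # --- stage: quantify ---------------------------------------------
    matrix, quants = quantify_study(
        measurements,
        windows,
        thresholds=config.thresholds,
        policy=config.aggregation_policy,
    )
    flag_counts = Counter(flag for q in quants for flag in sorted(q.flags))
    report["stages"]["quantify"] = {
        "n_pairs": matrix.n_pairs,
        "n_evaluable": len(matrix.evaluable_pairs()),
        "n_peak_quants": len(quants),
        "peaks_flagged": dict(sorted(flag_counts.items())),
        "aggregation_policy": matrix.policy,
    }

    # --- stage: roc ---------------------------------------------------
    if reference is None and "reference_set" in config.inputs:
        reference = read_reference_set(config.inputs["reference_set"])
    if reference is not None and len(reference):
        roc = roc_curve(matrix, reference)
        cutoff, tpr, fpr = select_cutoff(roc, config.target_fpr)
        counts = confusion_at_cutoff(matrix, reference, cutoff)
        detections = matrix.detections(cutoff)
        report["stages"]["roc"] = {
            "target_fpr": config.target_fpr,
            "selected_cutoff": cutoff,
            "tpr": tpr,
            "fpr": fpr,
            "auc": auc(roc),
            "confusion": {
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
            },
            "n_detections": len(detections),
        }
        import pandas as pd

        pd.DataFrame(
            [(pt.cutoff, pt.tpr, pt.fpr) for pt in roc],
            columns=["cutoff", "tpr", "fpr"],
        ).to_csv(outdir / "roc.csv", index=False)
        pd.DataFrame(detections, columns=["protein_id", "metabolite_id", "delta_rf"]).to_csv(
            outdir / "detections.csv", index=False
        )
    else:
        cutoff = 0.0
        detections = matrix.detections(cutoff)
        report["stages"]["roc"] = {"skipped": "no reference set provided"}

    write_interaction_table(matrix, outdir / "interactions.csv", cutoff=cutoff)

    # --- stage: classify ----------------------------------------------
    if "similarity_table" in config.inputs:
        similarity = read_similarity_table(config.inputs["similarity_table"])
        classified = classify_binding_mode(
            detections, similarity, reference, config.similarity_threshold
        )
        report["stages"]["classify"] = classification_summary(classified)
    else:
        report["stages"]["classify"] = {"skipped": "no similarity table provided"}

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for stage, info in report["stages"].items():
        keys = "skipped" if "skipped" in info else ", ".join(sorted(info))
        logger.info("stage=%s fingerprint=%s %s", stage, report["config_fingerprint"], keys)
    return report
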