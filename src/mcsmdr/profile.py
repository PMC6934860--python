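"""Integrated multidrug-resistance call per cell line.

The pipeline's endpoint combines four evidence streams per subject:

* ic50 rank across the cohort's shared drugs (higher = more resistant),
* accumulated calcein (dye retention; lower = stronger efflux = more
  resistant), min-max normalised across the cohort,
* the ROS decay flag (observable ROS activity marks the sensitive
  phenotype),
* the mean inhibitor retention ratio (inhibitors barely change
  retention in resistant, transporter-overexpressing lines).

No published numeric decision rule exists for combining these; the
classifier uses a declared, configurable weighted score

    score = 0.4*(1 - accumulated_norm) + 0.3*ic50_rank_norm
          + 0.2*(1 - ros_decay)       + 0.1*(1 - retention_norm)

with class thresholds at 1/3 (sensitive/moderate) and 2/3
(moderate/high).  Missing evidence streams are dropped and the
remaining weights renormalised; the weights used are logged in every
report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import SegMask, TimeLapseStack
from .dose_response import DoseResponseFit, fit_dose_response, plate_to_viability, \
    resistance_rank_from_ic50
from .flow_mdr import TransporterReport, analyze_flow
from .quantification import ros_timeseries, uptake_timeseries
from .segmentation import PNet, baseline_segment, segment
from .synthetic import (
    PHENOTYPES,
    SpheroidGeometry,
    flow_spec_for,
    make_flow_events,
    make_plate,
    make_ros_stack,
    make_spheroid_stack,
    plate_spec_for,
)

CLASSES = ("sensitive", "moderately_resistant", "highly_resistant")

DEFAULT_WEIGHTS = {
    "accumulated": 0.4,
    "ic50_rank": 0.3,
    "ros": 0.2,
    "retention": 0.1,
}
DEFAULT_THRESHOLDS = (1.0 / 3.0, 2.0 / 3.0)


@dataclass
class EvidenceVector:
    subject: str
    accumulated_calcein: float | None = None
    accumulated_calcein_norm: float | None = None
    ic50_mean_rank: float | None = None
    ic50_rank_norm: float | None = None
    ros_decay: bool | None = None
    mean_retention_ratio: float | None = None
    retention_norm: float | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class ResistanceProfile:
    subject: str
    resistance_class: str
    score: float
    evidence: EvidenceVector
    rationale: str
    weights_used: dict[str, float] = field(default_factory=dict)


def build_evidence(
    subject: str,
    accumulated_calcein: float | None = None,
    ic50_mean_rank: float | None = None,
    ros_decay: bool | None = None,
    transporter_report: TransporterReport | None = None,
) -> EvidenceVector:
    """Assemble one subject's raw (un-normalised) evidence.

    The calcein kinetics stream is the only required one; anything
    else missing is marked so and noted.
    """
    if accumulated_calcein is None:
        raise ValueError("calcein kinetics evidence is required")
    ev = EvidenceVector(subject=subject, accumulated_calcein=float(accumulated_calcein),
                        ic50_mean_rank=ic50_mean_rank, ros_decay=ros_decay)
    if transporter_report is not None:
        ev.mean_retention_ratio = float(
            np.mean(list(transporter_report.retention_ratio.values()))
        )
    for name, val in (("ic50", ic50_mean_rank), ("ros", ros_decay),
                      ("flow", ev.mean_retention_ratio)):
        if val is None:
            ev.notes.append(f"{name} evidence missing")
    return ev


def _minmax(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.5] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def normalize_cohort(cohort: list[EvidenceVector]) -> list[EvidenceVector]:
    """Fill the min-max-normalised fields across a cohort (>= 2 subjects).

    Rank/normalised fields map the most sensitive end to 0 and the
    most resistant to 1.  A cohort of one cannot be normalised; the
    fields stay None and a note is added.
    """
    if len(cohort) < 2:
        for ev in cohort:
            ev.notes.append("cohort of 1: normalization skipped")
        return cohort
    acc = [ev.accumulated_calcein for ev in cohort]
    for ev, v in zip(cohort, _minmax(acc)):
        ev.accumulated_calcein_norm = v
    ranks = [ev.ic50_mean_rank for ev in cohort]
    if all(r is not None for r in ranks):
        for ev, v in zip(cohort, _minmax(ranks)):
            ev.ic50_rank_norm = v
    rets = [ev.mean_retention_ratio for ev in cohort]
    if all(r is not None for r in rets):
        for ev, v in zip(cohort, _minmax(rets)):
            ev.retention_norm = v
    return cohort


def classify_resistance(
    evidence: EvidenceVector,
    weights: dict[str, float] | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> ResistanceProfile:
    """Weighted-score classification of one subject's evidence.

    Each evidence component contributes its weight times a 0-1
    "resistance direction" term; missing components are dropped and
    the remaining weights renormalised.  Score < thresholds[0] is
    sensitive, < thresholds[1] moderately resistant, else highly
    resistant.
    """
    w = dict(weights or DEFAULT_WEIGHTS)
    if evidence.accumulated_calcein_norm is None:
        raise ValueError("normalized accumulated calcein is required for classification")

    terms: dict[str, float] = {"accumulated": 1.0 - evidence.accumulated_calcein_norm}
    if evidence.ic50_rank_norm is not None:
        terms["ic50_rank"] = evidence.ic50_rank_norm
    if evidence.ros_decay is not None:
        terms["ros"] = 0.0 if evidence.ros_decay else 1.0
    if evidence.retention_norm is not None:
        terms["retention"] = 1.0 - evidence.retention_norm

    used = {k: w[k] for k in terms}
    total = sum(used.values())
    if total <= 0:
        raise ValueError("no usable evidence weights")
    used = {k: v / total for k, v in used.items()}
    score = float(sum(used[k] * terms[k] for k in terms))

    if score < thresholds[0]:
        cls = "sensitive"
    elif score < thresholds[1]:
        cls = "moderately_resistant"
    else:
        cls = "highly_resistant"

    bits = [f"accumulated calcein norm={evidence.accumulated_calcein_norm:.3f} "
            f"(retention of dye; lower favours resistance)"]
    if "ic50_rank" in terms:
        bits.append(f"IC50 rank norm={evidence.ic50_rank_norm:.3f}")
    else:
        bits.append("IC50 evidence missing")
    if "ros" in terms:
        bits.append(f"ROS decay={'yes' if evidence.ros_decay else 'no'}")
    else:
        bits.append("ROS evidence missing")
    if "retention" in terms:
        bits.append(f"inhibitor retention norm={evidence.retention_norm:.3f}")
    else:
        bits.append("flow evidence missing")
    rationale = (f"score {score:.3f} -> {cls}; " + "; ".join(bits)
                 + f"; weights {json.dumps(used, sort_keys=True)}")
    return ResistanceProfile(subject=evidence.subject, resistance_class=cls,
                             score=score, evidence=evidence, rationale=rationale,
                             weights_used=used)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Simulation-backed pipeline run.

    subjects maps a label to a synthetic phenotype name; stages can be
    toggled; the segmentation method is one of ground_truth, baseline
    or pnet (which requires ``pnet_model``).
    """

    subjects: dict[str, str] = field(default_factory=lambda: {
        "MCS_17": "sensitive", "MCS_02": "moderate", "MCS_08": "resistant"})
    seed: int = 0
    image_size: int = 128
    radius_px: float = 40.0
    frame_interval_min: float = 20.0
    duration_h: float = 12.0
    ros_duration_h: float = 1.0
    inhomogeneity_amplitude: float = 0.3
    segmentation: str = "baseline"     # ground_truth | baseline | pnet
    pnet_model: PNet | None = None
    drugs: tuple[str, ...] = ("doxorubicin", "cisplatin", "methotrexate")
    culture_mode: str = "MCS"
    plate_noise_sd: float = 0.03
    flow_events: int = 10_000
    run_flow: bool = True
    run_plates: bool = True
    run_ros: bool = True
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))


def _segment_stack(stack: TimeLapseStack, gt: list[SegMask], method: str,
                   model: PNet | None) -> list[SegMask]:
    if method == "ground_truth":
        return gt
    if method == "baseline":
        return [baseline_segment(stack.phase[k]) for k in range(stack.n_frames)]
    if method == "pnet":
        if model is None:
            raise ValueError("segmentation='pnet' requires a trained model")
        return [segment(model, stack.phase[k]) for k in range(stack.n_frames)]
    raise ValueError(f"unknown segmentation method {method!r}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """segment -> quantify -> ic50 -> flow -> classify, per subject.

    Returns the cohort report as a plain dict (JSON-serialisable); if
    ``out_dir`` is given, writes report.json and tidy kinetics CSVs
    there.  Any stage failure is recorded in the per-subject stage
    status instead of aborting the run.
    """
    report: dict = {
        "seed": config.seed,
        "weights": config.weights,
        "segmentation": config.segmentation,
        "subjects": {},
    }
    evidences: list[EvidenceVector] = []
    fits_by_line: dict[str, dict[str, DoseResponseFit]] = {}
    kin_rows = []

    for i, (label, pheno_name) in enumerate(sorted(config.subjects.items())):
        pheno = PHENOTYPES[pheno_name]
        sub_seed = (config.seed * 1000 + i * 97) % (2**31 - 1)
        stages: dict[str, str] = {}
        sub: dict = {"phenotype": pheno_name, "stages": stages}

        geo = SpheroidGeometry(
            center=(config.image_size / 2, config.image_size / 2),
            radius=config.radius_px,
            inhomogeneity_amplitude=config.inhomogeneity_amplitude,
        )

        accumulated = None
        try:
            stack, gt = make_spheroid_stack(
                pheno, geo, config.frame_interval_min, config.duration_h,
                seed=sub_seed, image_size=config.image_size)
            masks = _segment_stack(stack, gt, config.segmentation, config.pnet_model)
            # fall back to ground truth if a segmenter loses the spheroid
            masks = [g if m.is_empty() else m for m, g in zip(masks, gt)]
            series = uptake_timeseries(stack, masks)
            accumulated = series.accumulated
            sub["accumulated_calcein"] = accumulated
            sub["final_mean_fluorescence"] = series.final_value
            stages["kinetics"] = "ok"
            for t, v in zip(series.times_h, series.mean_fluorescence):
                kin_rows.append((label, "green", float(t), float(v)))
        except Exception as exc:  # pragma: no cover - defensive
            stages["kinetics"] = f"failed: {exc}"

        ros_flag = None
        if config.run_ros:
            try:
                ros_stack, ros_gt = make_ros_stack(
                    pheno, geo, config.frame_interval_min, config.ros_duration_h,
                    seed=sub_seed + 1, image_size=config.image_size)
                ros_masks = _segment_stack(ros_stack, ros_gt, config.segmentation,
                                           config.pnet_model)
                ros_masks = [g if m.is_empty() else m for m, g in zip(ros_masks, ros_gt)]
                _, ros_flag = ros_timeseries(ros_stack, ros_masks)
                sub["ros_decay"] = ros_flag
                stages["ros"] = "ok"
            except Exception as exc:
                stages["ros"] = f"failed: {exc}"
        else:
            stages["ros"] = "skipped"

        if config.run_plates:
            try:
                fits: dict[str, DoseResponseFit] = {}
                for j, drug in enumerate(config.drugs):
                    spec = plate_spec_for(pheno_name, drug, config.culture_mode,
                                          noise_sd=config.plate_noise_sd)
                    plate = make_plate(spec, seed=sub_seed + 10 + j,
                                       mode=config.culture_mode)
                    fits[drug] = fit_dose_response(plate_to_viability(plate))
                fits_by_line[label] = fits
                sub["ic50"] = {d: f.ic50 for d, f in fits.items()}
                stages["dose_response"] = "ok"
            except Exception as exc:
                stages["dose_response"] = f"failed: {exc}"
        else:
            stages["dose_response"] = "skipped"

        flow_report = None
        if config.run_flow:
            try:
                spec = flow_spec_for(pheno_name, n_events=config.flow_events)
                events = make_flow_events(spec, seed=sub_seed + 50)
                flow_report = analyze_flow(events)
                sub["retention_ratios"] = flow_report.retention_ratio
                sub["transporter_ranking"] = flow_report.ranking
                stages["flow"] = "ok"
            except Exception as exc:
                stages["flow"] = f"failed: {exc}"
        else:
            stages["flow"] = "skipped"

        report["subjects"][label] = sub
        if accumulated is not None:
            evidences.append(build_evidence(
                label, accumulated_calcein=accumulated, ros_decay=ros_flag,
                transporter_report=flow_report))

    # cohort-level ic50 ranks
    if fits_by_line and len(fits_by_line) >= 2:
        try:
            ranks = resistance_rank_from_ic50(fits_by_line)
            for ev in evidences:
                if ev.subject in ranks.index:
                    ev.ic50_mean_rank = float(ranks.loc[ev.subject, "mean_rank"])
        except ValueError:
            pass

    normalize_cohort(evidences)
    for ev in evidences:
        prof = classify_resistance(ev, weights=config.weights)
        report["subjects"][ev.subject]["profile"] = {
            "class": prof.resistance_class,
            "score": prof.score,
            "rationale": prof.rationale,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        import pandas as pd

        pd.DataFrame(kin_rows, columns=["subject", "channel", "time_h", "mean_fl"]) \
            .to_csv(out / "kinetics.csv", index=False)
    return report
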