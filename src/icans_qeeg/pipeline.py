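"""End-to-end glue: simulate -> preprocess -> features -> grade -> risk.

These helpers chain the module-level operations the way the analysis scripts
use them, and give tests a single entry point for the integrated direction-of-
effect checks (does background slowing, injected at simulation time, surface
as elevated risk through both the qualitative and quantitative arms?).
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import risk
from .features import RecordFeatures, summarize_record
from .preprocess import apply_filters, assemble_epoch, make_windows
from .records import EpochRejection, PatientTimeline
from .simulate import CohortSimSpec, EEGSimSpec, simulate_cohort, simulate_eeg


def features_from_spec(spec: EEGSimSpec) -> RecordFeatures:
    """Run the full signal path for one simulated record.

    simulate -> band-pass/comb filter -> artifact excision -> 2 s windows ->
    per-record feature medians. Raises if the record is rejected for
    insufficient clean signal.
    """
    record, artifacts = simulate_eeg(spec)
    filtered = apply_filters(record)
    epoch = assemble_epoch(filtered, [(on, dur) for on, dur, _ in artifacts])
    if isinstance(epoch, EpochRejection):
        raise RuntimeError(f"record rejected: {epoch.reason}")
    return summarize_record(make_windows(epoch))


def attach_derived_covariates(timelines: Sequence[PatientTimeline],
                              theta_field: str = "med_e_theta") -> None:
    """Attach per-EEG derived covariates used by the risk analyses.

    ``abnormal``: indicator grade >= 1. ``theta_norm``: post-infusion theta
    energy normalized (ratio) to the patient's baseline EEG; the baseline
    EEG itself gets ratio 1 by definition.
    """
    for tl in timelines:
        tl.covariates["abnormal"] = [1.0 if g >= 1 else 0.0 for g in tl.grades]
        base = [getattr(f, theta_field) for d, f in zip(tl.eeg_days, tl.features)
                if d <= 0]
        b = base[-1] if base else getattr(tl.features[0], theta_field)
        tl.covariates["theta_norm"] = [getattr(f, theta_field) / b
                                       for f in tl.features]


def run_risk_analysis(timelines: Sequence[PatientTimeline]) -> dict:
    """The study's main risk analyses on a cohort of timelines.

    Returns fixed- and time-dependent Cox results for the qualitative
    (grade >= 1) covariate, time-dependent results for baseline-normalized
    theta energy, and its upper-tertile dichotomization.
    """
    attach_derived_covariates(timelines)
    out = {}

    base = risk.baseline_table(timelines, "abnormal")
    out["baseline_abnormal_fixed"] = risk.fit_cox(
        base, ["abnormal"], model="fixed")[0]

    cp_grade = risk.expand_counting_process(timelines, "abnormal")
    out["postinfusion_abnormal_timedep"] = risk.fit_cox(
        cp_grade, ["abnormal"], model="time_dependent")[0]

    cp_theta = risk.expand_counting_process(timelines, "theta_norm")
    out["theta_norm_timedep"] = risk.fit_cox(
        cp_theta, ["theta_norm"], model="time_dependent")[0]
    # tertile cut-offs from per-record post-infusion values (one value per
    # usable EEG), not from the row-weighted counting-process table
    post_values = [v for tl in timelines
                   for d, v, ex in zip(tl.eeg_days, tl.covariates["theta_norm"],
                                       tl.excluded)
                   if d > 0 and not ex]
    cuts, tert = risk.tertile_analysis(cp_theta, "theta_norm",
                                       model="time_dependent",
                                       values=post_values)
    out["theta_norm_tertile_cutoffs"] = cuts
    out["theta_norm_above_t3_timedep"] = tert
    return out


def simulate_and_analyze(n_patients: int = 1000, seed: int = 0,
                         spec: Optional[CohortSimSpec] = None) -> dict:
    """Convenience wrapper: simulate a cohort and run the risk analyses."""
    if spec is None:
        spec = CohortSimSpec(n_patients=n_patients, seed=seed)
    timelines = simulate_cohort(spec)
    result = run_risk_analysis(timelines)
    result["n_patients"] = len(timelines)
    result["n_events"] = int(sum(tl.event for tl in timelines))
    result["incidence"] = result["n_events"] / len(timelines)
    onsets = [tl.icans_day for tl in timelines if tl.event]
    result["median_onset_day"] = float(np.median(onsets)) if onsets else float("nan")
    return result
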