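"""Simulate the study cohort: 68 patients, EEGs at baseline/T1/T3/T7/T14.

Writes the long-format cohort table and the per-EEG evaluation forms under
results/, and a sample of raw EEG records as EDF (+ artifact annotation CSVs)
under scratch/edf/. Prints the cohort-level numbers the downstream analyses
start from.
"""
from pathlib import Path

import numpy as np

from icans_qeeg.simulate import (CohortSimSpec, cohort_to_frame, simulate_eeg,
                                 write_annotations_csv, write_edf,
                                 write_forms_json, simulate_cohort)

RESULTS = Path("results")
SCRATCH = Path("scratch/edf")
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    spec = CohortSimSpec(n_patients=68, seed=SEED)
    timelines = simulate_cohort(spec)

    frame = cohort_to_frame(timelines)
    frame.to_csv(RESULTS / "cohort.csv", index=False)
    write_forms_json(RESULTS / "forms.json", timelines)

    # raw signals for a handful of patients (first EEG each), with artifacts
    for tl in timelines[:3]:
        eeg_spec = tl.eeg_specs[0]
        eeg_spec.artifact_fraction = 0.1
        record, annotations = simulate_eeg(eeg_spec)
        record.patient_id = tl.patient_id
        stem = SCRATCH / f"{tl.patient_id}_baseline"
        write_edf(stem.with_suffix(".edf"), record)
        write_annotations_csv(stem.with_suffix(".csv"), annotations)

    events = [tl.icans_day for tl in timelines if tl.event]
    n_abn_base = sum(tl.grades[0] >= 1 for tl in timelines)
    print(f"patients: {len(timelines)}")
    print(f"ICANS events: {len(events)} ({len(events) / len(timelines):.1%})")
    if events:
        print(f"onset days: mean {np.mean(events):.1f}, "
              f"range {min(events):.1f}-{max(events):.1f}")
    print(f"abnormal baseline EEG (grade >= 1): {n_abn_base}/{len(timelines)}")
    print(f"wrote {RESULTS/'cohort.csv'}, {RESULTS/'forms.json'}, "
          f"and {len(list(SCRATCH.glob('*.edf')))} EDFs under {SCRATCH}/")


if __name__ == "__main__":
    main()
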