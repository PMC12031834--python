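"""Rule-based qualitative EEG grading for CAR T-cell therapy recipients.

A structured visual-read form (predominant background frequency, prevalence of
theta/delta slowing, state changes, reactivity, epileptiform abnormalities, ...)
is mapped to a severity grade from 0 (normal) to 3 (severely abnormal).  The
scale is deliberately coarse — grades hinge on the background frequency band
and on gross abnormalities — so that independent raters agree strongly; Cohen's
kappa quantifies that agreement.

Grading rules
-------------
With a *normal* background (alpha or beta predominant):

* grade 0 — at most low-prevalence theta and physiological state changes;
* grade 1 — moderate-prevalence theta, and/or low-prevalence delta, and/or
  pathological state changes (long-lasting diffuse delta replacing the
  posterior alpha rhythm after eye closure);
* grade 2 — high-prevalence theta.

Independently of the background:

* grade 2 — theta-predominant background, absent reactivity,
  moderate-prevalence delta, or low-prevalence epileptiform abnormalities;
* grade 3 — delta-predominant background, high-prevalence delta (polymorphic
  or rhythmic), or moderate/high-prevalence epileptiform abnormalities.

Several findings may coexist; the final grade is the MAXIMUM over triggered
rules (the worst finding drives severity).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from sklearn.metrics import cohen_kappa_score

from .exceptions import DataError, SizeError

# Ordered descriptor vocabularies (worsening left to right).
PBF_LEVELS = ("beta", "alpha", "theta", "delta")
PREVALENCE_LEVELS = ("none", "low", "moderate", "high")
STATE_CHANGE_LEVELS = ("absent", "physiological", "pathological")
SYMMETRY_LEVELS = ("symmetric", "mild_asymmetry", "marked_asymmetry")
CONTINUITY_LEVELS = ("continuous", "nearly_continuous", "discontinuous", "burst_suppression")
VOLTAGE_LEVELS = ("normal", "attenuated", "suppressed")
EA_TYPES = ("sporadic", "rhythmic_periodic", "seizure", "status")

#: Background frequencies counted as a normal background.
NORMAL_PBF = ("beta", "alpha")


@dataclass(frozen=True)
class EEGEvalForm:
    """Structured visual-read descriptors of one routine EEG.

    ``theta_prevalence`` / ``delta_prevalence`` classify non-epileptiform
    slowing; ``ea_prevalence``/``ea_type`` classify epileptiform abnormalities
    (``ea_type`` present iff any are seen). ``delta_prevalence`` covers both
    polymorphic and rhythmic delta; the morphology is a separate descriptor
    with no grading weight.
    """

    pbf: str
    theta_prevalence: str = "none"
    delta_prevalence: str = "none"
    state_changes: str = "absent"
    reactivity_present: bool = True
    ea_prevalence: str = "none"
    ea_type: Optional[str] = None
    symmetry: str = "symmetric"
    pdr_present: bool = True
    continuity: str = "continuous"
    voltage: str = "normal"
    iic_flag: bool = False

    def __post_init__(self):
        checks = (
            (self.pbf, PBF_LEVELS, "pbf"),
            (self.theta_prevalence, PREVALENCE_LEVELS, "theta_prevalence"),
            (self.delta_prevalence, PREVALENCE_LEVELS, "delta_prevalence"),
            (self.ea_prevalence, PREVALENCE_LEVELS, "ea_prevalence"),
            (self.state_changes, STATE_CHANGE_LEVELS, "state_changes"),
            (self.symmetry, SYMMETRY_LEVELS, "symmetry"),
            (self.continuity, CONTINUITY_LEVELS, "continuity"),
            (self.voltage, VOLTAGE_LEVELS, "voltage"),
        )
        for value, levels, name in checks:
            if value not in levels:
                raise DataError(f"{name}={value!r} not in {levels}")
        if (self.ea_prevalence != "none") != (self.ea_type is not None):
            raise DataError("ea_type must be present iff ea_prevalence != 'none'")
        if self.ea_type is not None and self.ea_type not in EA_TYPES:
            raise DataError(f"ea_type={self.ea_type!r} not in {EA_TYPES}")


@dataclass(frozen=True)
class Grade:
    """A 0-3 severity grade with the list of rules that fired."""

    value: int
    triggered_rules: tuple[str, ...]


# (rule id, grade, predicate) — final grade is the max over triggered rules.
_RULES = (
    ("g1_moderate_theta_normal_bg",
     1, lambda f: f.pbf in NORMAL_PBF and f.theta_prevalence == "moderate"),
    ("g1_low_delta",
     1, lambda f: f.delta_prevalence == "low"),
    ("g1_pathological_state_changes",
     1, lambda f: f.state_changes == "pathological"),
    ("g2_theta_pbf",
     2, lambda f: f.pbf == "theta"),
    ("g2_high_theta",
     2, lambda f: f.theta_prevalence == "high"),
    ("g2_absent_reactivity",
     2, lambda f: not f.reactivity_present),
    ("g2_moderate_delta",
     2, lambda f: f.delta_prevalence == "moderate"),
    ("g2_low_ea",
     2, lambda f: f.ea_prevalence == "low"),
    ("g3_delta_pbf",
     3, lambda f: f.pbf == "delta"),
    ("g3_high_delta",
     3, lambda f: f.delta_prevalence == "high"),
    ("g3_moderate_or_high_ea",
     3, lambda f: f.ea_prevalence in ("moderate", "high")),
)


def grade_record(form: EEGEvalForm) -> Grade:
    """Grade one evaluation form on the 0-3 scale.

    Every rule whose finding is present fires; the grade is the maximum over
    fired rules, or 0 ("normal") when none fires.
    """
    fired = [(rid, g) for rid, g, pred in _RULES if pred(form)]
    if not fired:
        return Grade(0, ("g0_normal_background",))
    value = max(g for _, g in fired)
    return Grade(value, tuple(rid for rid, _ in fired))


def classify_prevalence(rate_per_min: float) -> str:
    """Classify an abnormality rate (events/minute) as low / moderate / high.

    Low: < 1/min. Moderate: >= 1/min but less than 1 per 10 s. High: >= 1 per
    10 s (i.e. >= 6/min).
    """
    if rate_per_min < 0:
        raise DataError("rate must be non-negative")
    if rate_per_min < 1.0:
        return "low"
    if rate_per_min < 6.0:
        return "moderate"
    return "high"


def cohens_kappa(ratings_a: Sequence[int], ratings_b: Sequence[int]) -> float:
    """Unweighted Cohen's kappa between two raters' grade lists."""
    if len(ratings_a) != len(ratings_b):
        raise SizeError("rating lists must have equal length")
    if len(ratings_a) < 2:
        raise SizeError("need at least 2 rated records")
    return float(cohen_kappa_score(list(ratings_a), list(ratings_b)))


# Descriptors that the grading rules actually consult; the remaining form
# fields are free and never change the grade.
GRADING_FIELDS = ("pbf", "theta_prevalence", "delta_prevalence",
                  "state_changes", "reactivity_present", "ea_prevalence")

_GRADING_SPACE = (
    PBF_LEVELS, PREVALENCE_LEVELS, PREVALENCE_LEVELS,
    STATE_CHANGE_LEVELS, (True, False), PREVALENCE_LEVELS,
)


def iter_grading_forms() -> Iterator[EEGEvalForm]:
    """Enumerate the full finite space of grade-relevant descriptor combinations.

    Free descriptors (symmetry, PDR, continuity, voltage, EA morphology) are
    held at defaults; ``ea_type`` is set to 'sporadic' whenever EA are present
    to satisfy the form invariant.
    """
    for combo in itertools.product(*_GRADING_SPACE):
        kwargs = dict(zip(GRADING_FIELDS, combo))
        kwargs["ea_type"] = "sporadic" if kwargs["ea_prevalence"] != "none" else None
        yield EEGEvalForm(**kwargs)


def forms_by_grade() -> dict[int, list[EEGEvalForm]]:
    """Partition the grade-relevant form space by assigned grade."""
    buckets: dict[int, list[EEGEvalForm]] = {0: [], 1: [], 2: [], 3: []}
    for form in iter_grading_forms():
        buckets[grade_record(form).value].append(form)
    return buckets
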