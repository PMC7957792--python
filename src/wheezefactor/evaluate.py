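"""Accuracy metrics and multi-run experiment orchestration.

Confusion terminology for the two-class problem (PP is the "positive"
column, MP subtypes partition MP):

    TP  PP segments correctly classified      FP  PP misclassified as MP
    TM  MP segments correctly classified      FM  MP misclassified as PP
    TM1/FM1, TM2/FM2  the same split restricted to MP Type 1 / Type 2

Rates (percent): ACCG = (TP+TM)/(TP+TM+FP+FM), ACCP = TP/(TP+FP),
ACCM = TM/(TM+FM), ACCM1 = TM1/(TM1+FM1), ACCM2 = TM2/(TM2+FM2).
Arithmetic is exact (Fractions); zero-denominator rates are reported as
undefined (None), never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from fractions import Fraction

import numpy as np

from .audio import AudioSegment
from .pipeline import WheezeClassifier

__all__ = ["ConfusionCounts", "AccuracyReport", "compute_accuracies",
           "tally_confusion", "run_experiment", "ExperimentResult"]

log = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int = 0
    TM: int = 0
    FP: int = 0
    FM: int = 0
    TM1: int = 0
    TM2: int = 0
    FM1: int = 0
    FM2: int = 0

    def validate(self) -> None:
        vals = asdict(self)
        if any(v < 0 for v in vals.values()):
            raise ValueError("confusion counts must be non-negative")
        if self.TM != self.TM1 + self.TM2 or self.FM != self.FM1 + self.FM2:
            raise ValueError("MP subtype counts must partition TM and FM")


@dataclass
class AccuracyReport:
    """Accuracy rates in percent; None marks an undefined (0/0) rate."""

    ACCG: float | None
    ACCP: float | None
    ACCM: float | None
    ACCM1: float | None
    ACCM2: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def _rate(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return float(Fraction(num, den) * 100)


def compute_accuracies(counts: ConfusionCounts) -> AccuracyReport:
    """Exact accuracy rates from a confusion table."""
    counts.validate()
    return AccuracyReport(
        ACCG=_rate(counts.TP + counts.TM, counts.TP + counts.TM + counts.FP + counts.FM),
        ACCP=_rate(counts.TP, counts.TP + counts.FP),
        ACCM=_rate(counts.TM, counts.TM + counts.FM),
        ACCM1=_rate(counts.TM1, counts.TM1 + counts.FM1),
        ACCM2=_rate(counts.TM2, counts.TM2 + counts.FM2),
    )


def tally_confusion(
    true_labels: list[str], true_subtypes: list[str | None], predicted: list[str]
) -> ConfusionCounts:
    """Count classification outcomes against ground-truth labels."""
    c = ConfusionCounts()
    for label, subtype, pred in zip(true_labels, true_subtypes, predicted):
        if label == "PP":
            if pred == "PP":
                c.TP += 1
            else:
                c.FP += 1
        else:
            if pred == "MP":
                c.TM += 1
                if subtype == "Type1":
                    c.TM1 += 1
                elif subtype == "Type2":
                    c.TM2 += 1
            else:
                c.FM += 1
                if subtype == "Type1":
                    c.FM1 += 1
                elif subtype == "Type2":
                    c.FM2 += 1
    return c


@dataclass
class ExperimentResult:
    averaged: AccuracyReport
    per_run: list[AccuracyReport]
    confusions: list[ConfusionCounts]
    pooled: AccuracyReport = field(default=None)  # rates over summed counts


def _average(reports: list[AccuracyReport]) -> AccuracyReport:
    out = {}
    for key in ("ACCG", "ACCP", "ACCM", "ACCM1", "ACCM2"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if len(vals) < len(reports):
            log.warning("rate %s undefined in %d run(s); excluded from the average",
                        key, len(reports) - len(vals))
        out[key] = float(np.mean(vals)) if vals else None
    return AccuracyReport(**out)


def run_experiment(
    dataset: list[AudioSegment],
    classifier: WheezeClassifier | None = None,
    n_runs: int = 5,
    base_seed: int = 0,
) -> ExperimentResult:
    """Classify every segment ``n_runs`` times and average the rates.

    Run r reseeds the factorisation with ``base_seed + r``, classifies
    the whole dataset once, and tallies a confusion table; the final
    report is the arithmetic mean of the per-run rates (a pooled-count
    view is also attached).
    """
    if not dataset:
        raise ValueError("empty dataset")
    if classifier is None:
        classifier = WheezeClassifier()
    labels = [s.label for s in dataset]
    subtypes = [s.subtype for s in dataset]
    per_run, confusions = [], []
    for r in range(n_runs):
        clf = classifier.__class__(**{**classifier.get_params(),
                                      "random_state": base_seed + r, "n_runs": 1})
        predicted = list(clf.fit().predict(dataset))
        counts = tally_confusion(labels, subtypes, predicted)
        confusions.append(counts)
        per_run.append(compute_accuracies(counts))
        log.info("run %d confusion: %s", r, counts)
    pooled_counts = ConfusionCounts(*[
        sum(getattr(c, k) for c in confusions)
        for k in ("TP", "TM", "FP", "FM", "TM1", "TM2", "FM1", "FM2")
    ])
    return ExperimentResult(
        averaged=_average(per_run),
        per_run=per_run,
        confusions=confusions,
        pooled=compute_accuracies(pooled_counts),
    )
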