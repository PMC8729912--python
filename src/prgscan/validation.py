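"""Criterion-based agreement analysis and confusion-matrix metrics.

Predictions are compared against a reference domain annotation at the
protein level, on the HMM-detected resistance domains only (TIR, NBS,
LRR, LYSM, LECM) -- CC and TM come from external predictors and are
excluded from the comparison.  Two agreement levels are tallied:

* criterion 1 -- the predicted domain set equals the reference set;
* criterion 2 -- the predicted set contains the reference set
  (predicted "equally or better").

Per (protein, domain) cell the confusion matrix counts TP/FP/TN/FN,
from which accuracy, precision, sensitivity, specificity and F-score
are derived; ratios with a zero denominator are reported as
not-applicable (None), never as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Domains entering the comparison: the HMM-detected resistance domains.
RESISTANCE_LABELS = ("TIR", "NBS", "LRR", "LYSM", "LECM")


@dataclass(frozen=True)
class CriterionFlags:
    criterion1: bool  # identical domain set
    criterion2: bool  # equal-or-superset domain set


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def metrics(self) -> Dict[str, Optional[float]]:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn

        def ratio(num: int, den: int) -> Optional[float]:
            return num / den if den else None

        accuracy = ratio(tp + tn, tp + tn + fp + fn)
        precision = ratio(tp, tp + fp)
        sensitivity = ratio(tp, tp + fn)
        specificity = ratio(tn, tn + fp)
        if precision is None or sensitivity is None or precision + sensitivity == 0:
            f_score = None
        else:
            f_score = 2 * precision * sensitivity / (precision + sensitivity)
        return {
            "accuracy": accuracy,
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "f_score": f_score,
        }


@dataclass(frozen=True)
class ValidationReport:
    per_class: Dict[str, Dict[str, int]]  # class -> {n_criterion1, n_criterion2, n_total}
    per_domain: Dict[str, ConfusionCounts]
    pooled: ConfusionCounts
    excluded: Tuple[str, ...]  # protein ids absent from the reference

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "per_domain": {
                d: {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn, **c.metrics()}
                for d, c in self.per_domain.items()
            },
            "pooled": {
                "tp": self.pooled.tp, "fp": self.pooled.fp,
                "tn": self.pooled.tn, "fn": self.pooled.fn,
                **self.pooled.metrics(),
            },
            "excluded": list(self.excluded),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")


def _restrict(domains: Set[str], vocabulary: Sequence[str]) -> Set[str]:
    return set(domains) & set(vocabulary)


def compare_to_reference(
    predicted: Mapping[str, Set[str]],
    reference: Mapping[str, Set[str]],
    vocabulary: Sequence[str] = RESISTANCE_LABELS,
) -> Tuple[Dict[str, CriterionFlags], List[str]]:
    """Per-protein criterion flags on the resistance-domain vocabulary.

    Proteins present in the predictions but absent from the reference
    are excluded and logged; the excluded ids are returned alongside.
    """
    flags: Dict[str, CriterionFlags] = {}
    excluded: List[str] = []
    for pid, pred in predicted.items():
        if pid not in reference:
            log.warning("protein %s absent from the reference annotation; excluded", pid)
            excluded.append(pid)
            continue
        p = _restrict(pred, vocabulary)
        r = _restrict(reference[pid], vocabulary)
        flags[pid] = CriterionFlags(criterion1=(p == r), criterion2=(p >= r))
    if not flags:
        raise ValidationError("no proteins shared between predictions and reference")
    return flags, excluded


def confusion_metrics(
    predicted: Mapping[str, Set[str]],
    reference: Mapping[str, Set[str]],
    vocabulary: Sequence[str] = RESISTANCE_LABELS,
) -> Tuple[Dict[str, ConfusionCounts], ConfusionCounts]:
    """Per-domain and pooled TP/FP/TN/FN over shared proteins."""
    shared = [pid for pid in predicted if pid in reference]
    if not shared:
        raise ValidationError("empty evaluation set")
    per_domain: Dict[str, ConfusionCounts] = {}
    pooled = dict(tp=0, fp=0, tn=0, fn=0)
    for domain in vocabulary:
        c = dict(tp=0, fp=0, tn=0, fn=0)
        for pid in shared:
            in_pred = domain in predicted[pid]
            in_ref = domain in reference[pid]
            key = ("tp" if in_ref else "fp") if in_pred else ("fn" if in_ref else "tn")
            c[key] += 1
            pooled[key] += 1
        per_domain[domain] = ConfusionCounts(**c)
    return per_domain, ConfusionCounts(**pooled)


def build_validation_report(
    predicted: Mapping[str, Set[str]],
    reference: Mapping[str, Set[str]],
    class_of: Optional[Mapping[str, str]] = None,
    vocabulary: Sequence[str] = RESISTANCE_LABELS,
) -> ValidationReport:
    """Assemble criterion tallies (per class, if classes given) and metrics."""
    flags, excluded = compare_to_reference(predicted, reference, vocabulary)
    per_class: Dict[str, Dict[str, int]] = {}
    for pid, fl in flags.items():
        cls = (class_of or {}).get(pid, "all")
        row = per_class.setdefault(cls, {"n_criterion1": 0, "n_criterion2": 0, "n_total": 0})
        row["n_total"] += 1
        row["n_criterion1"] += int(fl.criterion1)
        row["n_criterion2"] += int(fl.criterion2)
    per_domain, pooled = confusion_metrics(predicted, reference, vocabulary)
    return ValidationReport(
        per_class=per_class,
        per_domain=per_domain,
        pooled=pooled,
        excluded=tuple(excluded),
    )


def read_reference_tsv(path: str | Path) -> Dict[str, Set[str]]:
    """Reference TSV: one (protein_id, domain_label) pair per row."""
    ref: Dict[str, Set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "domain_label"]:
            raise ValidationError(f"bad reference table header in {path}: {header}")
        for line in fh:
            pid, dom = line.rstrip("\n").split("\t")
            ref.setdefault(pid, set()).add(dom)
    if not ref:
        raise ValidationError(f"empty reference annotation in {path}")
    return ref


def write_report_tsv(report: ValidationReport, path: str | Path) -> None:
    """Human-readable per-domain metric table."""
    with open(path, "w") as fh:
        fh.write("domain\ttp\tfp\ttn\tfn\taccuracy\tprecision\tsensitivity\tspecificity\tf_score\n")
        rows = list(report.per_domain.items()) + [("pooled", report.pooled)]
        for dom, c in rows:
            m = c.metrics()
            vals = "\t".join(
                "NA" if m[k] is None else f"{m[k]:.4f}"
                for k in ("accuracy", "precision", "sensitivity", "specificity", "f_score")
            )
            fh.write(f"{dom}\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}\t{vals}\n")
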