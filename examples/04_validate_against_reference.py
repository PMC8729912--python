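"""Benchmark predicted domain sets against a reference annotation.

Uses hand-made predictions to show the two agreement criteria
(identical set; equal-or-superset) and the confusion-matrix metrics on
the HMM-detected resistance domains.
"""

from prgscan import build_validation_report

predicted = {
    "At1": {"TIR", "NBS", "LRR"},         # identical to reference
    "At2": {"TIR", "NBS", "LRR"},         # extra TIR: superset only
    "At3": {"NBS"},                        # missing LRR: neither criterion
}
reference = {
    "At1": {"TIR", "NBS", "LRR"},
    "At2": {"NBS", "LRR"},
    "At3": {"NBS", "LRR"},
}
classes = {"At1": "TNL", "At2": "CNL", "At3": "CNL"}

report = build_validation_report(predicted, reference, class_of=classes)
for cls, row in sorted(report.per_class.items()):
    print(f"{cls}: criterion1 {row['n_criterion1']}/{row['n_total']}, "
          f"criterion2 {row['n_criterion2']}/{row['n_total']}")
m = report.pooled.metrics()
print(f"pooled: TP={report.pooled.tp} FP={report.pooled.fp} "
      f"TN={report.pooled.tn} FN={report.pooled.fn}")
print(f"accuracy {m['accuracy']:.3f}, precision {m['precision']:.3f}, "
      f"sensitivity {m['sensitivity']:.3f}, F-score {m['f_score']:.3f}")
# Criterion 1 counts proteins predicted identically to the reference;
# criterion 2 those predicted equally or better (superset). The confusion
# matrix counts each (protein, domain) presence/absence cell.
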