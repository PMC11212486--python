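"""Imbalanced-evaluation conventions on a hand-sized score set.

Shows the threshold-at-recall rule (largest threshold reaching the target
recall, which maximises precision there), the FP-per-correct identity with
precision, and the step-summed AUPR.
"""

from cppmine import (confusion_at, imbalanced_metrics, pr_curve_and_aupr,
                     threshold_for_recall)

scores = {"p1": 0.92, "p2": 0.75, "p3": 0.41, "p4": 0.12,
          "n1": 0.80, "n2": 0.35, "n3": 0.30, "n4": 0.22, "n5": 0.05}
labels = {"p1": 1, "p2": 1, "p3": 1, "p4": 1,
          "n1": 0, "n2": 0, "n3": 0, "n4": 0, "n5": 0}

for target in (0.5, 0.75, 1.0):
    t = threshold_for_recall(scores, labels, target)
    c = confusion_at(scores, labels, t)
    precision, recall, f1, fpc = imbalanced_metrics(c)
    print(f"target recall {target:.2f}: threshold {t:.2f} -> "
          f"recall {recall:.2f}, precision {precision:.2f}, "
          f"F1 {f1:.2f}, FP/C {fpc:.2f}")

curve = pr_curve_and_aupr(scores, labels)
print(f"AUPR: {curve.auc:.4f}")
print("PR points (recall, precision):",
      [(round(float(r), 2), round(float(p), 2))
       for r, p in zip(curve.recalls, curve.precisions)])
# Raising the recall target forces the threshold down, trading precision
# for coverage — exactly the trade-off FP/C quantifies for screening.
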