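"""Per-class and macro metrics from a stored confusion matrix.

Feeds a 2x2 confusion matrix (rows true, columns predicted, order
benign/malignant) through the metrics module and prints the per-class
precision/recall/F1 table with macro averages, plus overall accuracy.
"""

import numpy as np

from fuzzyvit import ConfusionMatrix, metrics_report

cm = ConfusionMatrix(np.array([[343, 27], [37, 321]]))
report = metrics_report(cm)
print(report.format_table())
print()
print("The 'Total' row is the unweighted (macro) mean over the two classes;")
print("accuracy is the diagonal fraction of all", cm.total, "test images.")
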