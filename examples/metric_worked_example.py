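"""Three-class metrics from confusion matrices of the cascaded classifier.

Builds the raw-image and segmented-image confusion matrices from their
misclassification counts (100 test images per class) and reports the
weighted one-vs-rest metrics: superimposing the predicted tumor mask
before classification removes most errors.
"""

import numpy as np

from mwbrain.evaluation import classwise_metrics

raw = np.array([[97, 3, 0],      # non-tumor: 3 -> single
                [6, 86, 8],      # single: 6 -> non, 8 -> double
                [3, 14, 83]])    # double: 3 -> non, 14 -> single
segmented = np.array([[100, 0, 0],
                      [1, 96, 3],
                      [0, 1, 99]])

for name, cm in (("raw images", raw), ("segmented images", segmented)):
    pct = classwise_metrics(cm).as_percent()
    errors = int(cm.sum() - np.trace(cm))
    print(f"{name} ({errors} errors of {cm.sum()}):")
    for k, v in pct.items():
        print(f"  {k:12s} {v:6.2f} %")
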