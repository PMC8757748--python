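"""Fit the curved borders and train the bagged SVM group classifier.

Four borders SBP = c / PTT partition training data into five groups at
ratio 1:1:3:3:2 (a point's band is decided by kappa = SBP x PTT). At
estimation time the group comes from a 35-member bagged SVM ensemble,
since the reference SBP is unknown.
"""

import numpy as np

from cufflessbp import assign_group, fit_group_boundaries
from cufflessbp.grouping import predict_group, train_group_classifier

rng = np.random.default_rng(0)
ptt = rng.uniform(180, 320, 500)
sbp = rng.uniform(85, 185, 500)

b = fit_group_boundaries(ptt, sbp)
print("border coefficients (mmHg*ms): c1=%.0f > c2=%.0f > c3=%.0f > c4=%.0f"
      % (b.c1, b.c2, b.c3, b.c4))
labels = assign_group(ptt, sbp, b)
shares = np.bincount(labels, minlength=6)[1:] / len(labels)
print("group shares:", np.round(100 * shares, 1), "% (target 10/10/30/30/20)")

# classifier on simple informative features (here: kappa-correlated columns)
X = np.column_stack([1.0 / ptt, sbp * ptt / 1000 + rng.normal(0, 1, 500)])
clf = train_group_classifier(X, labels, rng_seed=1)
pred = predict_group(clf, X)
print(f"ensemble members: {len(clf.members)}")
print(f"training-set vote accuracy vs border labels: "
      f"{(pred == labels).mean():.2f}")
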