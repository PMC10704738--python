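"""Balance a modulator-poor library by SMOTE oversampling.

Shows the class accounting for the canonical 351-vs-9,640 imbalance: the
minority is interpolated up to the majority count, giving 19,280 rows."""

import numpy as np

from rosscreen import SmoteConfig, amplification_factor, fit_scaler, smote_resample

rng = np.random.default_rng(0)
X = rng.normal(size=(9991, 47))
labels = np.zeros(9991, dtype=bool)
labels[rng.choice(9991, size=351, replace=False)] = True

scaler = fit_scaler(X)  # SMOTE distances are Euclidean on z-scored features
X_aug, labels_aug, provenance = smote_resample(
    scaler.transform(X), labels, SmoteConfig(k_neighbors=5, seed=42)
)

print(f"before: {labels.sum()} modulators vs {(~labels).sum()} others")
print(f"after:  {labels_aug.sum()} vs {(~labels_aug).sum()}  "
      f"({len(X_aug)} rows total)")
print(f"amplification: {amplification_factor(351, 9640):.2f}-fold "
      f"(~{round(amplification_factor(351, 9640))}x)")
print("first synthetic row provenance:")
print(provenance.head(1).to_string(index=False))
# Each synthetic row is parent + u*(neighbour - parent): a point on the
# segment between a modulator and one of its 5 nearest modulator neighbours.
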