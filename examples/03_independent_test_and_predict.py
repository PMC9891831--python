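"""Train once, evaluate on an unseen draw, and score new sequences.

Mirrors the train / independent-test protocol: the model never sees the test
sequences, so the reported metrics measure generalization rather than fit.
"""

import numpy as np

from fegsnet import CascadeConfig, GeneratorConfig, generate_dataset
from fegsnet.evaluation import independent_test
from fegsnet.hdnet import fit_cascade, predict, predict_proba
from fegsnet.pipeline import featurize

train = generate_dataset(GeneratorConfig(50, 50, length_range=(50, 120), effect=0.5, seed=1))
test = generate_dataset(GeneratorConfig(25, 25, length_range=(50, 120), effect=0.5, seed=2))
# the two draws share no ids; independent_test enforces that
test.sequences = [s.__class__("t_" + s.id, s.residues) for s in test.sequences]

X_train, _ = featurize(train, "dpc")
X_test, _ = featurize(test, "dpc")
report = independent_test(
    X_train, np.array(train.labels), X_test, np.array(test.labels),
    config=CascadeConfig(seed=1),
    train_ids=train.ids, test_ids=test.ids,
)
print("independent test:", report)

model = fit_cascade(X_train, np.array(train.labels), CascadeConfig(seed=1))
proba = predict_proba(model, X_test[:5])
labels = predict(model, X_test[:5])
print(f"cascade kept {model.n_layers} layer(s); OOF history {np.round(model.history, 3)}")
for name, lab, p in zip(test.ids[:5], labels, proba[:, 1]):
    print(f"  {name}: predicted {'positive' if lab else 'negative'} (P={p:.3f})")
# P is the mean positive-class probability over the final layer's 18 learners.
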