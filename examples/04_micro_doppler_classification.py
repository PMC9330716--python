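"""Micro-Doppler gait classification at miniature scale: simulate five
classes, train the 4-layer CNN briefly, score held-out subjects.

Run:  python examples/04_micro_doppler_classification.py  (a few minutes)
"""

import numpy as np

from mmgait.datasets import make_gait_window_dataset
from mmgait.evaluate import confusion_matrix
from mmgait.har import build_classifier, predict_probabilities, \
    train_classifier
from mmgait.kinematics import GAIT_CLASSES

data = make_gait_window_dataset(n_subjects_per_class=4, duration=6.0, seed=0)
print(f"spectrogram windows: {len(data.images)} "
      f"({int(data.val_mask.sum())} from held-out subjects)")

model = build_classifier(seed=0)
hist = train_classifier(model, data.images, data.labels, epochs=8, seed=0,
                        val_mask=data.val_mask, patience=8)
p = predict_probabilities(model, data.images[data.val_mask])
pred = [GAIT_CLASSES[i] for i in np.argmax(p, axis=1)]
true = [GAIT_CLASSES[i] for i in data.labels[data.val_mask]]
acc = float(np.mean(np.array(pred) == np.array(true)))
print(f"held-out accuracy  : {100 * acc:.1f}%")
print("confusion matrix (% of true class):")
print(confusion_matrix(true, pred).round(1).to_string())

# Meaning: each 2 s window of tracked points becomes a 64x64 velocity-time
# image; even this abbreviated run (4 subjects per class, 8 epochs) lands
# far above the 20% chance level, though under-trained classes still
# collapse into one another.  The full-scale experiment in the test suite
# (8 subjects per class, early-stopped training) separates all five
# patterns at roughly 95% held-out accuracy.
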