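"""Train a small standard-decoder model and evaluate it with MCC,
precision, recall and a decision-threshold sweep.

Uses a reduced configuration (k=3, N=2, c=8) on a 60-protein corpus so the
run finishes in well under a minute on one CPU.
"""

import numpy as np

from seqsite import (
    NetworkConfig,
    SimulationConfig,
    StageConfig,
    TrainingConfig,
    confusion,
    mcc,
    precision_recall,
    predict,
    simulate_corpus,
    threshold_sweep,
    train_std,
)
from seqsite.features import feature_map_from_record

corpus = simulate_corpus(SimulationConfig(n_proteins=60, length_range=(50, 90), seed=1))
train, test = corpus.split(48)

net = NetworkConfig(k=3, blocks_per_stage=2, c=8, dropout=0.5)
schedule = TrainingConfig(
    gamma=0.0, batch_size=12, optimizer="adam",
    stages=(StageConfig(initial_rate=0.003, decay=0.6, interval=300, iterations=600),),
    seed=2)
weights, history = train_std(train.proteins, net, schedule)
print(f"trained {len(history.loss)} iterations; "
      f"loss {history.loss[0]:.3f} -> {history.loss[-1]:.3f}")

maps = [feature_map_from_record(p) for p in test.proteins]
results = predict(weights, maps)  # default threshold 0.4
labels = np.concatenate([p.labels for p in test.proteins])
scores = np.concatenate([r.positive_probability for r in results])
preds = np.concatenate([r.labels for r in results])
counts = confusion(labels, preds)
prec, rec = precision_recall(counts)
print(f"held-out MCC {mcc(counts):.3f}  precision {prec:.1f}%  recall {rec:.1f}%")

print("threshold sweep (recall falls as the threshold rises):")
for row in threshold_sweep(scores, labels, grid=(0.2, 0.4, 0.6, 0.8)):
    print(f"  thr {row['threshold']:.1f}: precision {row['precision']:5.1f}%  "
          f"recall {row['recall']:5.1f}%  MCC {row['mcc']:.3f}")
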