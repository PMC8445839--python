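"""Train the aux architecture and extract neural fingerprints + NP scores.

Trains one fold of the multi-task network (NP classification plus 48
surface-descriptor regressions) on a fixture dataset, then extracts the
64-dimensional fingerprint-layer activations and the NP output-neuron
score for new molecules.
"""

import numpy as np

from npfp import (
    FeaturizedDataset,
    ModelSpec,
    OptimizerConfig,
    ecfp4,
    extract_fingerprint,
    generate_np_like,
    generate_synthetic_like,
    make_folds,
    np_score,
    train_fold,
)

records = generate_np_like(400, seed=1) + generate_synthetic_like(400, seed=2)
data = FeaturizedDataset.from_records(records)
split = make_folds(records, k=5, seed=0)
spec = ModelSpec(arch="aux", seed=0,
                 optimizer=OptimizerConfig(epochs=15, batch_size=128))
model = train_fold(data, split, 0, spec)
print(f"held-out NP classification AUC: "
      f"{model.train_metrics['val_auc']:.4f}")

for rec in generate_np_like(2, seed=60) + generate_synthetic_like(2, seed=61):
    fp = extract_fingerprint(model, ecfp4(rec), molecule_id=rec.id)
    score = np_score(model, ecfp4(rec))
    print(f"  {rec.source_class:<10s} fp[:4]="
          f"{np.round(fp.values[:4], 3)}  logit={score.logit:+.2f} "
          f"p(NP)={score.probability:.3f}")

print("\nThe 64 fingerprint values lie in (-1, 1) (Tanh layer); the logit")
print("is the NP output neuron, its sigmoid the NP probability.")
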