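"""Pretrain a stacked sparse auto-encoder, fine-tune the softmax classifier,
and cross-validate it on the default synthetic dataset.

Uses the scaled-down geometry (3640-40-20-7) so the whole run takes well
under a minute on one CPU.
"""

import enoselearn as el
from enoselearn.pipelines import SSAEPipeline

dataset = el.generate_dataset(el.SynthConfig(rate_hz=1.0, seed=11))
print(f"dataset: {len(dataset)} samples, {len(dataset.class_names)} classes")

pipe = SSAEPipeline(hidden_sizes=(40, 20), pretrain_epochs=30,
                    finetune_epochs=30, seed=0)
result = el.cross_validate(pipe, dataset, k=10, seed=0)
print(f"SSAE-BPNN 10-fold CV accuracy: {result.mean_accuracy:.4f} "
      f"+/- {result.interval_half_width:.4f} (SEM across folds)")
print(f"per-fold accuracies: {[round(a, 3) for a in result.fold_accuracies]}")
print("each fold refits the unit scaler, the unsupervised pretraining and "
      "the supervised fine-tuning on the nine training folds only")
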