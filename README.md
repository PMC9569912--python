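# mildta

Multiple-instance learning for drug–target binding-affinity (DTA)
regression, with a private/public feature mechanism.

## The problem and the model

Predicting the binding affinity of a drug–target pair (Kd, Ki or
IC50-derived scores) from raw sequences — a SMILES string for the compound
and an amino-acid sequence for the protein — is a core step in
computational drug discovery. Most sequence-based predictors either encode
the two molecules independently and concatenate at the end (late fusion of
*private* features), or mix the two streams early through cross-attention
(*public*, interaction-aware features). Both signals are informative;
their individual contributions are usually hidden inside one network.

`mildta` treats one drug–target pair as a multiple-instance **bag** of four
learned feature vectors:

| instance | content |
|---|---|
| `public_dp` | multi-head cross-attention, drug queries over protein keys/values, max-pooled |
| `public_pd` | the reverse direction, max-pooled |
| `public_concat` | concatenation of the pooled drug and protein private features (late fusion) |
| `private_d` | the drug stream alone (a ligand-based view) |

The pipeline is: unigram subword tokenization of both sequences →
two independent transformer encoder stacks (post-norm, sinusoidal
positional encodings) → a residual dilated gated-convolution stack per
stream plus the two cross-attention modules → masked global max pooling.
Each instance vector is scored by its own MLP, and the affinity is a
learned linear fusion of the scores

    ŷ = w₁·s(public_dp) + w₂·s(public_pd) + w₃·s(public_concat) + w₄·s(private_d),

trained end to end with the mean-squared-error loss and AdamW
(lr 1e-3, betas (0.9, 0.999), eps 1e-8), with early stopping on validation
MSE. The fusion weights make each instance family's contribution explicit,
and an ablation harness retrains every subset of the three instance
families.

Evaluation follows the standard DTA protocol: concordance index (CI), MSE,
Pearson R and the rm² external-validation index (rm² ≥ 0.5 = "acceptable"),
under both *random* pair-level 5-fold splits and *blind* (cold) splits in
which no test drug or target is ever seen in training.

The neural network runs on a small numpy reverse-mode autodiff core that
ships with the package; there is no deep-learning framework dependency.

## Worked example

Generate a synthetic dataset with a planted drug×target motif-interaction
signal, fit a small model, and evaluate on held-out pairs:

```python
import numpy as np
from mildta import (SynthConfig, generate_dt_dataset,
                    MILBindingAffinityRegressor, compute_report, random_split)

cfg = SynthConfig(n_drugs=30, n_targets=20, density=0.5, noise_sd=0.1, seed=1)
ds, truth = generate_dt_dataset(cfg)
frame = ds.to_frame()
split = random_split(ds, seed=0)
train_df, test_df = frame.iloc[split.train + split.val], frame.iloc[split.test]

est = MILBindingAffinityRegressor(
    d_model=16, n_layers=1, n_heads=2, ffn_dim=32, n_gate_blocks=1,
    dilation_rates=(1,), scorer_hidden=(32,), drug_vocab_size=32,
    protein_vocab_size=64, drug_max_len=16, protein_max_len=32,
    max_epochs=40, patience=10, random_state=0)
est.fit(train_df[["smiles", "sequence"]], train_df["affinity"])

pred = est.predict(test_df[["smiles", "sequence"]])
report = compute_report(pred, test_df["affinity"])
print("test metrics:", {k: (round(v, 3) if isinstance(v, float) else v)
                        for k, v in report.to_dict().items()})
print("fusion weights:", np.round(est.fusion_weights_, 3))
```

Output of this exact script:

```
test metrics: {'ci': 0.663, 'mse': 0.603, 'pearson_r': 0.537, 'rm2': 0.167, 'n': 60, 'acceptable': False}
fusion weights: [0.301 0.296 0.296 0.29 ]
```

CI 0.663 means two thirds of comparable test pairs are ranked correctly by
this deliberately tiny 40-epoch model; rm² below 0.5 flags that a model of
this size/training budget is not yet externally predictive, which is the
expected reading of the acceptability rule. The four fusion weights stay
near their symmetric 0.25 start after short training, drifting as each
instance family picks up signal. Longer training at larger width drives
training CI above 0.99 on noiseless synthetic data (see
`tests/test_acceptance.py`).

The same workflow is available from the shell:

```bash
mildta simulate --out synth.tsv --n-drugs 30 --n-targets 20 --density 0.5 --seed 1
mildta split --dataset synth.tsv --strategy blind --seed 0 --out split.json
mildta train --dataset synth.tsv --split split.json --out ckpt/ \
    --config small.yaml   # a YAML of TrainConfig fields; omit for full-scale defaults
mildta evaluate --checkpoint ckpt/ --dataset synth.tsv --split split.json --partition test
mildta ablate --dataset synth.tsv --split split.json --out ablation.tsv
```

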