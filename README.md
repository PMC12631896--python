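# fusebci

Cross-subject decoding of two-class motor imagery (MI) from hybrid
EEG + fNIRS recordings, for brain–computer-interface researchers who need a
complete, tested reference implementation of a transfer-learning pipeline:

* modality-specific CNN base networks (1-D convolutions with a depthwise
  separable third block, batch norm, sigmoid activations, adaptive average
  pooling, linear two-logit head);
* **Wasserstein trusted-score source selection** — each subject *k* is
  scored by

  &nbsp;&nbsp;&nbsp;&nbsp;`T_k = Acc_k · (1 − Norm(Σ_i W(k, i)))`

  where `W(k, i)` is the mean channelwise order-1 Wasserstein distance
  between the subjects' preprocessed signal distributions and `Acc_k` the
  subject's own validation accuracy; the per-modality argmax becomes the
  source domain;
* **domain-adaptation losses** — Deep CORAL
  `L_coral = ‖C_s − C_t‖²_F / (4d²)` and DCCA
  `L_dcca = −Σ_top-k σ(H_ss^{−1/2} H_st H_tt^{−1/2})`, both with exact
  analytic gradients, plus an MMD baseline for ablations;
* **accuracy-weighted multimodal fusion** — extractors initialized from the
  selected sources, features fused as the weighted concatenation
  `[a·F_eeg, b·F_nirs]` with `a = A_eeg/(A_eeg+A_nirs)`,
  `b = A_nirs/(A_eeg+A_nirs)`, trained with
  `L = L_clf + a·L_trans_eeg + b·L_trans_fnirs` (Adam, lr 0.001);
* stratified 5-fold evaluation with accuracy/precision/recall/F1 and the
  Friedman rank test across methods;
* a **synthetic paired EEG+fNIRS simulator** (1/f background, planted
  contralateral alpha/beta event-related desynchronization, double-gamma
  hemodynamic responses, inter-subject variability, patient-like ERD
  attenuation) so every stage runs and is tested without any recorded data.

The neural-network layer (convolutions, batch norm, pooling, Adam,
cross-entropy) is implemented directly on numpy arrays with hand-derived
backward passes, all verified against finite differences in the test suite.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

## Worked example

```python
import numpy as np
from fusebci.experiments import (
    build_compact_population, compact_specs, transfer_gain_study)
from fusebci.fusion_training import pretrain_population, select_sources

specs = compact_specs()                      # 8-ch EEG @50 Hz, 12-ch fNIRS nets
pop = build_compact_population(6, master_seed=5)   # 6 subjects x 60 trials
pre = pretrain_population(pop, specs, epochs=30, seed=0)
sel = select_sources(pop, pre)
print("sources:", sel.eeg_source, sel.fnirs_source)

res = transfer_gain_study(pop, pre, specs, n_runs=10, n_labeled=20,
                          epochs=15, seed=0)
print("transfer   %.1f%%" % (100 * res["ours"].mean()))
print("no transfer %.1f%%" % (100 * res["no_transfer"].mean()))
```

Output from this exact script:

```
sources: S03 S02
transfer   77.8%
no transfer 58.5%
```

Interpretation: with only 20 labeled trials from each target subject, the
fusion model initialized from the trusted-score source subjects and
regularized by the DCCA+CORAL transfer losses decodes left- vs right-hand
MI at 78 % on the held-out trials, while the same architecture trained from
scratch on those 20 trials reaches 58 % — the cross-subject transfer gain
the framework is designed to deliver.

A command-line interface mirrors the workflow
(`fusebci simulate / tfmap / pretrain / select-source / transfer /
evaluate`); run any subcommand with `--help`.

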