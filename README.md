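# cohorttrf

Cohort-model predictors and boosted temporal response functions for
speech-evoked neural data.

## The problem

During spoken-word recognition a listener maintains, phoneme by phoneme,
the *cohort* of wordforms consistent with the input so far. Two
information-theoretic quantities derived from that cohort have become
standard probes of incremental lexical processing in M/EEG work:

- **phoneme surprisal**, `s_i = -log2 p(k_i | k_1 .. k_{i-1})` — how
  unexpected the incoming phoneme is given the frequency-weighted cohort;
- **cohort entropy**, `H_i = -Σ_w p(w | k_1..k_i) log2 p(w | k_1..k_i)` —
  how much uncertainty remains over word identity.

Whether these two measures track one automatic process or dissociate
(e.g. between isolated-word listening and continuous speech) is an open
scientific question. Testing it requires a full chain: cohort computation
from a pronunciation lexicon, continuous predictor construction, estimation
of multivariate temporal response functions (mTRFs), and permutation-based
model comparison. `cohorttrf` implements that chain, plus a synthetic-study
generator so the whole analysis can be validated by parameter recovery
without any neuroimaging data.

## The core model

The neural response is modelled as a sum of convolutions of predictor time
series `x_i` (on a 100 Hz clock) with per-predictor kernels `h_i` over
delays spanning -100 to +990 ms:

    ŷ_t = Σ_i Σ_τ h[i, τ] · x[i, t-τ]

Kernels live in a basis of 50 ms Hamming windows centered every 10 ms and
are estimated by coordinate-descent **boosting** under ℓ1 loss: every
basis coefficient is probed with a small ± step, the best proposal is
applied, and a validation segment stops training per predictor channel as
soon as a proposal would hurt held-out error. Model quality is the
held-out proportion of variability explained, `1 - Σ|y-ŷ| / Σ|y-ȳ|`, under
nested k-fold cross-validation. A predictor's **unique** contribution is
the drop in held-out power when the model is refit without it; group-level
inference uses threshold-free cluster enhancement (TFCE) with max-statistic
permutation tests, and the entropy/surprisal dissociation is tested as a
between-group comparison of the per-subject ratio of unique powers.

## Worked example

```python
import numpy as np
import pandas as pd
from cohorttrf import (
    load_lexicon, annotate_word, SimConfig, generate_lexicon,
    generate_session, ground_truth_trfs, simulate_recording,
    build_predictor_set, TemporalResponseModel,
)

table = pd.DataFrame({
    "wordform": ["cat", "cab", "dog"],
    "pronunciation": ["K AE T", "K AE B", "D AO G"],
    "frequency": [3, 1, 4],
})
lexicon = load_lexicon(table)
ann = annotate_word(lexicon, ("K", "AE", "T"), "cat")
for ph, s, h in zip(ann.phonemes, ann.surprisal, ann.entropy):
    print(f"{ph:3s}  surprisal {s:.3f} bits   entropy {h:.3f} bits")
```

```
K    surprisal 1.000 bits   entropy 0.811 bits
AE   surprisal 0.000 bits   entropy 0.811 bits
T    surprisal 0.415 bits   entropy 0.000 bits
```

Word-initial /K/ carries 1 bit (half the frequency mass starts with K);
/AE/ is a forced continuation (surprisal 0) while cat vs cab stays
undecided (entropy 0.811); /T/ resolves the word.

Fitting a TRF to a synthetic recording and checking recovery:

```python
cfg = SimConfig(seed=0, lexicon_size=300, grid_shape=(2, 2),
                roi_box=(0, 0, 0, 0), snr=3.0)
rng = np.random.default_rng(0)
lex = generate_lexicon(cfg, rng)
session = generate_session(lex, cfg, "continuous", rng, n_words=150)
ps = build_predictor_set(session, lex).subset(["surprisal", "entropy"])
truth = ground_truth_trfs({"surprisal": 1.0, "entropy": 1.0},
                          cfg.basis(), ps.feature_names)
recording, _ = simulate_recording(ps, truth, cfg.geometry(), cfg.snr, rng)
roi_source = int(np.flatnonzero(cfg.geometry().roi_mask)[0])

model = TemporalResponseModel(recording[roi_source], ps, basis=cfg.basis())
results = model.fit(k=3, step=0.02, max_iter=500)
print(results.summary())
```

```
Temporal response function fit (l1 boosting)
  delay basis:        <TRFBasis: [-100, 1000) ms, 110 x 50 ms Hamming @ 100 Hz>
  predictors:         surprisal, entropy
  folds (k):          3 (6 boosting runs)
  sources:            1

  held-out performance (per source):
    l1 explained:     0.6348
    l2 explained:     0.8911
    Pearson r:        0.9441
```

The recovered surprisal kernel correlates with the generating two-peak
kernel at r = 0.997. (Held-out power is high here because the synthetic
source is driven entirely by the two predictors at SNR 3; real
source-localized recordings sit near a few percent.)

The full pipeline — two simulated participant groups, full/reduced model
fits, TFCE tests, ROI effect sizes, and the entropy/surprisal ratio
interaction test — runs from one config:

```python
from cohorttrf.validation import dissociation_replicate
report = dissociation_replicate(seed=42)
print(report["ratio_interaction"])   # {'t': ..., 'df': 10, 'p': 1e-05, ...}
```

A `cohorttrf` command-line interface exposes `simulate`, `fit` and
`compare` for shell-driven use.

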