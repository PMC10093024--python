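# pmikit

Machine-learning estimation of the post-mortem interval (PMI) from body
cooling, driven entirely by synthetic data.

## The problem

Forensic practice estimates the time since death from a single rectal
temperature measurement using the Henssge model of post-mortem cooling: the
normalized temperature drop

```
(Tr − Ta) / (T0 − Ta) = A·e^{Bt} + (1 − A)·e^{(AB/(A−1))t},   T0 = 37.2 °C
```

with amplitude `A` set by the ambient regime (1.25 for Ta ≤ 23.2 °C, 1.11
for Ta ≥ 23.3 °C, with operational second exponents 5B and 10B) and rate
`B = −1.2815·m_eff^{−0.625} + 0.0284` h⁻¹ set by the effective body weight
`m_eff = cf·m` (body weight times a clothing/environment correction
factor).  The equation is transcendental in `t`; traditionally it is solved
graphically with Henssge's nomogram.

pmikit replaces the nomogram two ways:

1. **A classical numerical inverter** (`estimate_pmi_classical` / the
   `solve` CLI command): a bracketed root search on the forward curve.
2. **Learned inverse models**: a generator draws labelled cases
   (m, cf, Tr, Ta → t) from the forward model over realistic casework
   grids, and six regression strategies — a regression tree, bagging,
   random forests, extremely randomized trees, RBF-kernel support-vector
   regression, and AdaBoost-boosted SVR — are trained to invert the
   cooling curve directly from data.  The evaluation layer reports
   MAE/MSE/R², residual σ-coverage, correction-factor × 5-kg binned
   errors, learning curves and two small literature-comparison scenarios.

Intended users: forensic researchers benchmarking data-driven PMI
estimators, and developers who want a reproducible synthetic cooling
benchmark.

## Worked example

```
$ pmikit generate --count 1000 --seed 1 --out cases.csv
accepted 973 of 1000 requested cases -> cases.csv

$ pmikit train --data cases.csv --method extra_trees --seed 1 \
      --out model.joblib
extra_trees: n_train=730 n_test=243 MAE=0.8591 h MSE=1.5023 h^2 R2=0.9427 -> model.joblib

$ pmikit solve --Tr 31.4082 --Ta 20 --m 70 --cf 1.0
9.9999
```

The first command requests 1000 synthetic cases; 973 survive the body-weight
rejection step (weights are drawn from N(70, 10) kg and kept only in
[50, 100] kg).  The second trains an extremely-randomized-trees model on 75%
of them and reports hold-out errors in hours: with only ~700 training cases
the ensemble already estimates the interval to ~0.9 h mean absolute error.
The third inverts the cooling formula classically: a body of 70 kg at 20 °C
ambient that has cooled to 31.4082 °C rectally died 10.0 hours ago.

At the full benchmark size (~11,000 cases) the support-vector models reach
test MAE ≈ 0.16–0.19 h — about ±10 minutes — which is what
`scripts/acceptance.py` measures.

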