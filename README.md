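# edlseg — region-based evidential deep learning for segmentation

`edlseg` is a compact, fully-tested implementation of evidential deep
learning (EDL) for semantic segmentation with voxelwise uncertainty
quantification, built for researchers in medical image analysis who want
calibrated segmentation confidence from a *single* deterministic forward
pass — no ensembles, no Monte-Carlo dropout sampling.

## The model

A segmentation network's final softmax/sigmoid is replaced by a ReLU head
that emits non-negative **evidence** `e_ij` for assigning voxel `i` to
class `j`.  Evidence parameterizes a Dirichlet distribution over the
per-voxel class probabilities:

    alpha_ij = (e_ij + 1)^2        (squared map; `linear`: alpha = e + 1)
    S_i      = sum_j alpha_ij      (Dirichlet strength)
    p_ij     = alpha_ij / S_i      (expected probabilities)

Training minimizes Bayes risks of standard losses under `Dir(alpha_i)`.
Beyond the classical marginal-likelihood, cross-entropy and MSE risks, the
core objective is a **region-based soft-Dice risk** whose per-class
denominator carries the Dirichlet variance:

    L_DICE = 1 - (2/K) sum_j [ sum_i y_ij p_ij ]
                       / [ sum_i y_ij^2 + p_ij^2 + p_ij(1-p_ij)/(S_i+1) ]

plus an epoch-annealed KL regularizer `KL(Dir(alpha~) || Dir(1,...,1))`
(with correct-class evidence removed from `alpha~`) that shrinks
misleading evidence, weighted by `lambda(n) = 0.1 * min(1, n/ramp)^2`.
A weighted variant (`wDICE`) scales each class term by
`1 - foreground/background`.

Uncertainty is the **normalized predictive entropy**
`u_i = -(1/log K) sum_j p_ij log p_ij` in [0, 1].

The evaluation suite implements Dice overlap, brain-masked expected
calibration error (ECE), the threshold-free **soft uncertainty-error
overlap** (sUEO) between the uncertainty map and the binary error map, and
the confidence-filtered **BraS** score combining AUCs of Dice / filtered-
true-positive / filtered-true-negative curves.

Everything is exercised end-to-end on deterministic synthetic phantoms —
multi-channel images with nested tumor-like regions inside an ellipsoidal
brain — with three corruption operators (Gaussian blur sigma 1.5, additive
Gaussian noise variance 1.5, gamma correction gamma 5) for robustness
experiments.  A pure-numpy three-level encoder-decoder with a ReLU
evidence head serves as the trainable vehicle.

## Worked example

```python
from edlseg import RunConfig, run_experiment

report = run_experiment(
    RunConfig(seed=1, corruptions=({"kind": "blur", "parameter": 1.5},))
)
for name, row in report["variants"].items():
    print(name, {k: round(v, 4) for k, v in row["mean"].items()})
```

Output (40 phantoms of 96x96, 24 train / 8 val / 8 test, 50 epochs,
~1 minute on one CPU):

```
clean    {'dice': 0.9914, 'ece': 0.03,   'sueo': 0.3898, 'bras': 0.9624, 'sueo_uniform': 0.0057}
blur_1.5 {'dice': 0.9776, 'ece': 0.0335, 'sueo': 0.4645, 'bras': 0.9589, 'sueo_uniform': 0.0156}
```

Reading: the evidential model segments clean phantoms almost perfectly
(Dice 0.991) and stays well-calibrated (ECE 0.03).  Blurring the test
images degrades segmentation (Dice drops to 0.978) while the uncertainty
map gets *better* at localizing the errors — sUEO rises from 0.39 to 0.46
and dwarfs a uniform-uncertainty baseline (0.016): the model knows where
it is failing.

The same machinery is scriptable from the shell:

```bash
edlseg simulate --seed 1 --n-cases 10 --out data/
edlseg experiment --seed 1 --out runs/exp1/
edlseg evaluate --pred p.nii.gz --gt g.nii.gz --uncertainty u.nii.gz --out report.json
```

## Layout

| path | contents |
| --- | --- |
| `src/edlseg/fields.py` | evidence / Dirichlet / label / uncertainty containers |
| `src/edlseg/evidential.py` | evidence -> alpha -> probability -> entropy transforms |
| `src/edlseg/losses.py` | Bayes-risk losses, KL regularizer, MC oracle, theorem sweep |
| `src/edlseg/metrics.py` | Dice, brain-masked ECE, sUEO, BraS |
| `src/edlseg/synthetic.py` | phantom generator, corruption operators, dataset manifests |
| `src/edlseg/model.py` | numpy encoder-decoder with hand-written backprop |
| `src/edlseg/harness.py` | training loop, prediction, robustness experiments |
| `src/edlseg/cli.py` | `edlseg` command-line interface |
| `docs/methods.md` | modeling assumptions, defaults, and numerical choices |
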