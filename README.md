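# semgmoe

Bayesian mixture-of-experts modelling of multichannel surface EMG (sEMG)
for **simultaneous fingertip-force regression and movement
classification**, aimed at myoelectric control of dexterous hand
prostheses. One model does both jobs: local linear "experts" regress the
multi-DoF force from windowed sEMG features, while the Gaussian "gates"
that switch between experts cluster the feature space into movements —
classification falls out of the regression fit at no extra cost, and the
fully Bayesian treatment yields calibrated predictive uncertainty.

## Model

For features $x_n \in \mathbb{R}^{d_x}$ (one per analysis window) and
forces $y_n \in \mathbb{R}^{d_y}$,

$$y_n = \sum_{i=1}^{M} g_i(x_n)\, W_i^\top [x_n; 1], \qquad
g_i(x) = \frac{\pi_i\, \mathcal{N}(x \mid \mu_i, \Lambda_i^{-1})}
               {\sum_l \pi_l\, \mathcal{N}(x \mid \mu_l, \Lambda_l^{-1})},$$

with expert noise $y \mid x, i \sim \mathcal{N}(W_i^\top[x;1],
\chi_i^{-1})$. Conjugate priors — Gaussian–Wishart on $(\mu_i,
\Lambda_i)$, matrix-Normal–Wishart on $(W_i, \chi_i)$ with per-input
Gamma ARD precisions $a_{ij}$ — give closed-form variational Bayes EM
updates. The mixing weights $\pi_i$ are re-estimated each pass and
experts whose weight collapses are pruned, so the number of movements is
inferred rather than supplied. Automatic relevance determination (ARD)
shrinks the weight rows of uninformative channels, and a companion
sensitivity-analysis toolkit (regression-based first-order indices under
Iman–Conover rank-correlated Latin hypercube sampling) decomposes each
electrode's — or electrode group's — share of the output force variance
into uncorrelated (unique) and correlated parts for electrode-reduction
studies.

Predictions are winner-takes-all: the dominant gate selects an expert,
whose posterior predictive is a multivariate Student-t with
$\kappa_i = \lambda_i - d_y + 1$ degrees of freedom, mean
$[x;1]\hat W_i$ and covariance
$Q_i^{-1}\,(1 + [x;1] L_i [x;1]^\top)/(\kappa_i - 2)$ — uncertainty
inflates automatically when extrapolating.

## Worked example

```python
from semgmoe import BayesianMixtureOfExperts, metrics
from semgmoe.synthetic import make_ground_truth, sample_session

gt = make_ground_truth(3, 4, 2, separation=8.0, seed=42)       # 3 movements
train = sample_session(gt, n_per_block=250, n_repetitions=3,
                       rest_fraction=0.0, seed=43)
test = sample_session(gt, n_per_block=150, n_repetitions=1,
                      rest_fraction=0.0, seed=44)

model = BayesianMixtureOfExperts(n_experts=10, n_restarts=20,
                                 random_state=0).fit(train.X, train.Y)
print("surviving experts:", model.n_experts_)
print("held-out R2:", metrics.r2(test.Y, model.predict(test.X)).round(4))
```

Output:

```
surviving experts: 3
held-out R2: [1. 1.]
```

Ten initial experts collapse onto the three true movements (the surplus
weights are driven to zero and pruned), and the per-DoF held-out
coefficient of determination is essentially 1 on this cleanly separated
synthetic session.

The same pipeline is available from the shell:

```bash
semgmoe simulate --experts 9 --channels 12 --dof 6 --seed 0 --out session.tsv
semgmoe extract-features --session session.tsv --fe rms \
    --train-out train.tsv --test-out test.tsv
semgmoe fit --train train.tsv --experts 10 --restarts 20 --seed 0 --out model.json
semgmoe evaluate --model model.json --train train.tsv --test test.tsv \
    --report report.json
semgmoe sa --model model.json --train train.tsv \
    --groups forearm:1-8,flex:9-10,arm:11-12 --out sa.json
```

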