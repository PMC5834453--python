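# Methods

## Model and inference

The package fits a multivariate mixture of linear experts to paired
sEMG-feature / force data. Each expert $i$ owns a Gaussian gate component
$\pi_i\,\mathcal N(x\mid\mu_i,\Lambda_i^{-1})$ on the feature space and a
linear-Gaussian regression $y = W_i^\top[x;1] + e$, $e\sim\mathcal
N(0,\chi_i^{-1})$. The gate side is a Gaussian mixture model, so the
model clusters the feature space (one cluster per movement, unsupervised)
at the same time as it regresses force; a maximum-likelihood treatment of
such gates is ill-posed (components can collapse onto single points),
which is one reason the model is estimated by variational Bayes.

Conjugate priors make every variational update closed-form:

* gates: Gaussian–Wishart, $p(\mu_i,\Lambda_i)=\mathcal N(\mu_i\mid
  m_0,(\beta_0\Lambda_i)^{-1})\,\mathcal W(\Lambda_i\mid B_0,\nu_0)$;
* experts: matrix-Normal–Wishart, $p(W_i,\chi_i\mid a_i)=\mathcal{MN}(W_i\mid
  0, A_i^{-1}, \chi_i^{-1})\,\mathcal W(\chi_i\mid Q_0,\lambda_0)$ with
  $A_i=\mathrm{diag}(a_{i,1},\dots,a_{i,d_x+1})$;
* ARD: $a_{ij}\sim\mathrm{Ga}(c_0,d_0)$ per weight row, so an input channel
  whose posterior precision $E[a_{ij}]$ blows up is effectively removed
  from that expert's regression.

One VBEM pass evaluates the mixing weights $\pi_i = N_i/N$, updates the
gate, expert and ARD posteriors in that order, then refreshes the
responsibilities $r_{ni}$ in log space (log-sum-exp row normalization, so
rows never underflow to NaN). Experts with $\pi_i < 1/(2N)$ — supported
by less than half a data point — are pruned right after the mixing
update and the weights and responsibility rows are renormalized; this is
the automatic model-order selection: initializing with more experts than
movements and letting surplus weights collapse.

### Evidence lower bound

The bound $\mathcal L = E_q[\ln p(Y,X,Z,\mu,\Lambda,W,\chi,a\mid\pi)] -
E_q[\ln q]$ is assembled term by term from standard conjugate-exponential
results: the Gaussian–Wishart data and prior/entropy terms familiar from
VB Gaussian mixtures, the matrix-Normal–Wishart terms (where
$E_q[\mathrm{tr}(\chi W^\top A W)] = \sum_j \Upsilon_{jj}\,\xi_j$ with
$\xi_j$ the ARD statistic $d_y (L)_{jj} + \lambda\,\hat w_j Q \hat
w_j^\top$), and Gamma prior/entropy terms for the ARD precisions. Since
every update is exact coordinate ascent on this functional, the trace is
non-decreasing; the tests assert a per-step drop of no more than 1e-8
across seeds. Two independent verifications back the formula: the trace
monotonicity property, and exact agreement (machine precision in
practice, asserted at 1e-6 relative) with a separately coded one-component
Bayesian multivariate linear regression with ARD — with one expert the
mixture reduces to exactly that model.

### Stopping, restarts, initialization

Iteration stops when the relative bound change falls below `tol` (1e-6
default; the check is skipped on a pass where pruning changed the model)
or at `max_iter` = 200. Responsibilities initialize from row-normalized
U[0,1] draws; the gate prior means $m_0$ come from K-means on the
features (10 k-means++ restarts internally), run once per VBEM restart
with that restart's seed. Because the responsibility initialization is
nearly symmetric across experts, single runs can land in merged local
maxima (one expert straddling two movements while another splits a
cluster); the remedy is multiple restarts compared by their final bound —
on session-scale problems the complete solution, when found, carries the
largest bound, and 20 restarts locate it reliably where 5 or 6 may not.
The estimator default is 100 restarts, matching the protocol the method
was designed under; the tests and the acceptance study use 20 to keep
runtimes in seconds-to-minutes on one CPU.

### Hyperparameter defaults

On standardized features, broad priors need no tuning: $\beta_0=0.01$,
$B_0=I$, $\nu_0=d_x$, $Q_0=I$, $\lambda_0=d_y$, $c_0=0.01$,
$d_0=10^{-4}$. All are overridable on the estimator.

### Prediction

The predictive is winner-takes-all: gate probabilities are evaluated at
MAP gate estimates, with $\Lambda_{\text{MAP},i} = \nu_i B_i$ (the
Wishart posterior mean — always defined, unlike the mode which needs
$\nu > d_x+1$), and the winning expert's posterior predictive is
multivariate Student-t with $\kappa = \lambda - d_y + 1$ degrees of
freedom, mean $[x;1]\hat W$, scale $Q^{-1}(1+[x;1]L[x;1]^\top)/\kappa$
and covariance $Q^{-1}(1+[x;1]L[x;1]^\top)/(\kappa-2)$. This is the
exact matrix-T marginal of the matrix-Normal–Wishart posterior; a
100,000-draw Monte-Carlo test samples $(W,\chi)$ from the posterior and
confirms mean and covariance to within three Monte-Carlo standard
errors. Confidence intervals are per-DoF marginal Student-t quantiles;
their factor $1+[x;1]L[x;1]^\top$ widens them away from the training
data. Classification ties (exactly equal gate probabilities) break to the
lowest expert index.

## Feature extraction

Overlapping windows (default 400 ms length, 10 ms increment at 2 kHz)
with per-channel time-domain features — mean absolute value, waveform
length, root mean square — or the FILT feature: full-wave rectification,
zero-phase second-order Butterworth low-pass at 2 Hz, subsampled every
200 samples. Windows are labelled by their **last** sample: the feature
vector then only uses signal up to the labelled instant, keeping
prediction causal (the window/label alignment is a free choice; start or
center alignment would be anticausal). Preprocessing follows the force-
protocol convention: split raw rows by repetition (defaults hold out
repetitions 2 and 5), standardize the raw signals with training-set
statistics, extract features separately per side so no window straddles
the split, subsample training rows by 10 at regular intervals starting at
row 0, and standardize the features, again with training statistics only.
Raw-signal and feature standardization are two distinct steps, both
applied. A zero-variance training column is an error naming the column.

## Synthetic data

The generator is the study bed for every downstream stage, so its
defaults are the study conditions.

* **Feature-space sessions** mirror the model exactly: per-movement
  Gaussian clusters ($x\sim\mathcal N(\mu_i,\Lambda_i^{-1})$, covariance
  eigenvalues ≥ 1) and per-movement linear force maps with Gaussian
  noise, arranged in contiguous blocks per repetition with rest blocks
  interleaved. Rest is an explicit extra expert at the origin with zero
  force weights — consistent with initializing one expert per movement
  *plus rest*. Cluster means are nonnegative (windowed sEMG features are
  rectified amplitudes) and rescaled so the minimum pairwise distance
  equals `separation` (default 8, i.e. well-separated movements on the
  unit-scale cluster spread).
* **Observation noise** defaults to `noise_scale = 0.05` (noise SD ≈ 5%
  of the per-feature signal scale). Within a held movement, windowed
  sEMG features predict force with high signal-to-noise; at this level,
  expert-weight recovery at session-scale sample sizes (N ≈ 2000) is
  limited by sample size rather than noise — the binding constraint on
  recovery is the collinearity between each cluster's offset mean and
  the bias row, which inflates any estimator's error (an OLS oracle given
  the true labels shows the same floor).
* **Raw signal**: per channel, zero-mean Gaussian white noise amplitude-
  modulated by an envelope that is $(\mu_i + b)\exp(\sigma_{\rm rel}
  u(t))$ during movement $i$ and the flat baseline $b=0.05$ at rest,
  where $u(t)$ is a slow piecewise-linear Gaussian drift (500 ms knots,
  correlated across channels with the movement's cluster correlation,
  $\sigma_{\rm rel}=0.25$). The multiplicative drift keeps envelopes
  positive without the folding or clipping artifacts an additive drift
  would need, and it makes envelope and force co-vary within a movement:
  the force is the expert map at the *instantaneous* envelope,
  $y(t)=W_i^\top[\mathrm{env}(t);1]+e$. That within-movement covariation
  is what identifies each expert's weights — with a constant envelope per
  block, one linear map could fit two point-clusters exactly and the
  Bayesian Occam factor would favour merging them. Blocks default to 4 s
  of movement and 3 s of rest so that windows straddling block
  transitions (the ambiguous rows the center-segment protocol discounts)
  stay a small fraction of each block.
* What the raw generator does **not** emulate: motor-unit physiology,
  electrode shift, fatigue, crosstalk spectra, force-sensor dynamics.
  Passing end-to-end tests therefore demonstrates the correctness of the
  windowing/feature/model pipeline on signals with realistic block and
  envelope structure, not performance on physiological sEMG.

## Evaluation

NRMSE (RMS error over the reference range) and $R^2$ per force DoF;
$R^2$ may go negative on restricted segments. Gate classification is
unsupervised, so experts map to movements by majority vote over the
training rows each expert wins (ties to the lower movement id; experts
winning nothing map to rest). Confusion matrices are row-normalized with
rows = true class. Center-segment scoring splits every contiguous
non-rest block into three segments — remainder samples go to the middle
segment — and keeps only the middle one; rest blocks are retained whole.
Retaining rest means transition windows labelled rest still count, which
is why center-segment accuracy is dominated by rest/movement hand-off
ambiguity rather than movement confusion.

## Sensitivity analysis

First-order variance shares for correlated inputs, estimated by
regression on an Iman–Conover rank-correlated Latin hypercube sample of
the training-feature marginals (target Spearman matrix estimated from
training data unless supplied). For input (or electrode group) $j$:
$V_j$ is the variance of the OLS fit of the model output on $x_j$ alone;
$VU_j$ the variance of the fit on the residual of $x_j$ after regressing
it on all other inputs; $VC_j = V_j - VU_j$; shares are $S_j = V_j/V$,
$SU_j$, $SC_j$. A spurious channel shows $SU \approx 0$ with large $SC$.
The estimator is validated against the closed-form Gaussian-linear
decomposition ($V_j = (\Sigma w)_j^2/\Sigma_{jj}$, $VU_j = w_j^2 /
(\Sigma^{-1})_{jj}$) rather than against any reported figure, since the
source for the residual-regression construction is a cited method, not a
printed formula. The default 12-electrode grouping is forearm ring
{1–8}, finger extensor/flexor {9, 10}, upper arm {11, 12} (following the
electrode placement diagram; configurable).

## Numerical choices

All covariance-like matrices are handled via Cholesky factorizations
with symmetrization after every update and a single tiny-jitter retry
before raising. Gate and expert densities, gate probabilities and
responsibilities are computed in log space. Empty experts ($N_i <
10^{-10}$) keep their exact prior posterior until pruned. Negative ARD
statistics (numerically possible at convergence boundaries) clamp to
zero with a warning. Serialization is JSON (schema-versioned) for models
and TSV/NinaPro-dialect MATLAB for sessions.

## Problem sizes

The test suite and acceptance study run on one CPU in minutes: recovery
studies use N ≈ 2000–2700 feature rows (3 movements, 4 features, 2 DoF),
the end-to-end study a 12-channel/6-DoF raw session of ~790k samples
(nine movements + rest, 6 repetitions) yielding ~2600 training and
~13000 test windows, fitted with 20 restarts. These sizes were chosen as
the smallest at which the asymptotic claims (5% weight recovery,
interval calibration, expert-count recovery) hold with margin.

## Known limitations

Linear experts only; winner-takes-all prediction (no soft mixture
predictive); mixing weights are point estimates, not posteriors; the
bound-based model selection can need tens of restarts on many-movement
sessions; the raw-signal generator is a statistical emulator, not a
physiological model.
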