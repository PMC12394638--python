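# Methods

## Model

`personet` estimates *personal temporal symptom networks* from longitudinal
binary symptom panels. For subject $i$ with covariates
$x_i = (x_{i1},\dots,x_{id})$ and symptom vector
$y_i^t \in \{0,1\}^p$, the lag-1 logistic autoregression with
covariate-moderated effects is

$$
\mathrm{logit}\,P(y_{ij}^t = 1 \mid y_i^{t-1}, x_i)
 = \mu_j + \sum_l \alpha_{jl} x_{il}
 + \sum_{j'} \Big(\sigma^1_{jj'} + \sum_l \gamma^1_{jj'l}\, x_{il}\Big)
   y_{ij'}^{t-1} .
$$

* $\mu_j$ (log-odds): threshold — presence log-odds of symptom $j$ with all
  lagged symptoms absent and $x = 0$.
* $\alpha_{jl}$: shift in the threshold when covariate $l$ moves by one unit.
* $\sigma^1_{jj'}$: directed temporal edge $j' \to j$, the conditional
  log-odds-ratio of $y_j^t$ for $y_{j'}^{t-1}$ flipping 0 → 1 at $x = 0$.
* $\gamma^1_{jj'l}$: covariate moderation of that edge; $\exp(\gamma)$ is a
  ratio of odds ratios.

Matrix orientation is fixed throughout the package: **rows index the time-$t$
outcome, columns the $(t-1)$ predictor**, so $W[j,j']$ is the edge
$j' \to j$. The lag is fixed at one — the model the package exists for —
and the API takes no lag argument. The total log-likelihood over
transitions $t = 2..T$ factorizes exactly into $p$ node-wise Bernoulli
log-likelihoods, which is what licenses node-wise fitting (verified to
1e-10 in the tests).

A *personal network* for covariate profile $x$ is the realized pair
$W(x) = \Sigma^1 + \sum_l \gamma^1_{\cdot\cdot l} x_l$,
$\tau(x) = \mu + \alpha x$. With $x = 0$ it reduces to $(\Sigma^1, \mu)$
exactly.

## Estimation (eLasso)

Each node $j$ is fitted by an L1-penalized logistic regression of $y_j^t$ on
the $P = d + p + pd$ predictors $[x,\; y^{t-1},\; x \otimes y^{t-1}]$ with
an unpenalized intercept. The penalty level is chosen by minimizing the
extended BIC

$$\mathrm{eBIC}(\lambda) = -2\ell + |J|\log N + 2\eta|J|\log P,$$

with $N = n(T-1)$ transition observations, $|J|$ the number of nonzero
penalized coefficients at $\lambda$, and $\eta \ge 0$ a user-fixed sparsity
hyperparameter (default 0.25, the value that behaved best in the simulation
experiments; the simulations also sweep 0.5 and 1.0). The path has 100
log-spaced points from the data-derived $\lambda_{\max}$ (the smallest
penalty that zeroes every penalized coefficient) down to
$10^{-3}\lambda_{\max}$; eBIC ties resolve toward the larger penalty
(sparser model). The log-likelihood entering eBIC is evaluated at the
penalized path coefficients, and selected coefficients are reported
penalized, per eLasso convention; debiased estimates come only from the
data-splitting refits below. Predictors are left on their natural scale —
they are 0/1 indicators or products of indicators with an
already-standardized numeric covariate — so all coefficients remain
interpretable as log-odds and results are bit-for-bit reproducible.

### Solver

The penalized fits are performed by a compiled coordinate-descent solver
(`_solver.py`) specialized to these designs: transition rows are collapsed
to unique (covariate, lagged-pattern) rows with multiplicities shared by all
$p$ node regressions, column nonzeros are stored sparsely, and a single
quarter-bound Gram matrix ($X'X/4$ dominates the Bernoulli Hessian
globally) serves every node, penalty level, and iteration
(majorize–minimize with soft-thresholding, warm-started along the path;
outer tolerance 1e-5 on the max coefficient update). The test suite
cross-checks the solver against scikit-learn's saga L1 logistic regression
at fixed penalties (agreement ≈ 1e-5). Unpenalized refits use Newton
iteration with a separation guard: coefficients are capped at ±15 log-odds
and the replicate flagged, since refits on selected supports can separate
in small halves.

## Inference

**Data-splitting inference** (default 100 replicates; the simulation
studies use the replicate counts stated below): each replicate randomly
halves the subjects, selects each node's support by eLasso on half A, and
refits the unpenalized logistic regression on half B restricted to the
selected predictors plus intercept. Unselected parameters contribute 0 to
that replicate's draw. Reported are per-parameter means, 95% CIs by type-6
quantiles over replicate draws, and selection frequencies.

**Bootstrap CIs** (`bootstrap_edges`): subjects resampled with replacement,
the full eLasso re-estimated per resample, 95% CIs from type-6 quantiles.
Type-6 (plotting position $(m+1)p$) is used everywhere a quantile is
taken from draws; it is slightly wider than the default linear
interpolation, which protects the type-I error of the CI-based tests.
Resamples leaving a node single-class are redrawn (up to three attempts)
so every quantity has exactly B draws; the redraw count is reported.

**Pseudo-subjects**: numeric covariates at their sample means crossed with
all $2^b$ binary combinations (guarded at $b \le 12$), ordered as a
big-endian counter. These summarize the population of personal networks so
centrality stability does not require per-subject networks.

**Case-dropping stability**: the reference network is fitted on the full
panel; for each retention proportion $\Delta$ and bootstrap, a random
subject subset of size $\lceil \Delta n\rceil$ (without replacement) is
refitted and each centrality metric recomputed for every pseudo-subject.
The Spearman correlation between reference and subset centrality vectors is
computed per metric on the vector concatenated across pseudo-subjects and
nodes — one correlation per metric per bootstrap — then averaged.
Correlation with a zero-variance vector is undefined and returns 0
(flagged): conservative, and it keeps the identical-centrality ring
experiment computable.

**Difference tests**: paired by draw index (same resample or split
underlying both quantities), the type-6 95% CI of the differences is
formed and the null of equality rejected when 0 falls outside it.

## Centralities

In-strength of node $j$ is $\sum_{j'\ne j} |W[j,j']|$ and out-strength of
$j'$ is $\sum_{j\ne j'} |W[j,j']|$ — absolute values because estimated
log-odds edges can be negative. Betweenness is directed shortest-path
betweenness with edge distance $1/|w|$ and fractional counting over tied
shortest paths (Brandes, via networkx), the convention of psychometric
network software. Self-loops are excluded from all three: they encode
symptom persistence, not inter-symptom brokerage.

## Synthetic data

The generator reproduces the simulation designs used to validate the
method; its defaults are the study conditions, not tuning knobs.

* **Stable truth** (`make_temporal_truth`): the static ($t=1$) network is a
  Watts–Strogatz small-world graph (total lattice degree $k=2$, i.e. one
  neighbor per side, rewiring probability $\theta = 0.3$) with unit
  association weights. The temporal adjacency has 20 nonzero directed
  effects drawn uniformly without replacement from all $p^2$ ordered pairs
  (self-loops eligible — real symptom networks prominently feature
  persistence edges): 15 fixed at weight 1 and 5 moderated, each by one
  distinct Bernoulli(0.5) covariate with effect $\beta = 2$ (the moderated
  pairs have $\sigma^1 = 0$). Thresholds are $\mu = -2$ everywhere,
  $\alpha = 0$.
* **Unstable truth** (`make_ring_truth`): a covariate-free directed cycle
  $1\to2\to\cdots\to p\to 1$ with unit weights, so all nodes have identical
  in-strength, out-strength, and betweenness by construction. The static
  network is taken as the un-rewired ring lattice, preserving the
  all-nodes-identical symmetry at $t=1$ (the design leaves this free; any
  node-exchangeable choice works).
* **First timepoint**: drawn from the Ising model implied by the static
  adjacency and thresholds via systematic-scan Gibbs sampling, 200 sweeps
  of burn-in by default (the design specifies the model but not a sampler;
  200 sweeps is far past mixing for these 10-node graphs, checked against
  exact enumeration on 2-node models). Later timepoints follow the lag-1
  autoregression exactly.

What the generator does *not* emulate: missing data, ordinal or graded
symptom severity, time-varying covariates, informative drop-out, and
contemporaneous (within-wave) residual dependence beyond what the static
$t=1$ model induces. Passing tests therefore speak to the estimator's
behavior under the model's own assumptions, not to robustness against
those violations.

## Simulation studies and their scales

`run_simulation_study` replicates three experiments, each sub-seeded per
replicate so results are independent of execution order:

1. **Edge identification**: stable truths, $T=3$; TPR, FPR, FDR and MCC of
   the called $\sigma^1/\gamma^1$ support (an entry is called when its
   magnitude exceeds `tol`, default 0 — eLasso already zeroes negligible
   effects) jointly over all $p^2 + p^2 d$ entries. Both FDR and FPR are
   reported.
2. **Centrality stability**: stable vs ring truths; case-dropping
   correlations across $\Delta \in \{0.9,\dots,0.5\}$. The study halves
   each panel — the reference network is estimated on one half and
   case-dropping operates on the other. This matters: a 90%-retained
   subset of the *same* data shares 90% of the estimation noise with the
   reference, which alone produces strength-ordering correlations near
   0.8 on ring truths whose centralities are identical; with disjoint
   halves the two orderings are independent under the null and the
   correlations collapse toward zero, which is the diagnostic signal the
   procedure is meant to give.
3. **Difference-test type-I error**: ring truths, where every true edge
   weight and every centrality is identical, so each paired difference
   test is a draw under the null. Three draw machineries are provided,
   because no single one captures every facet of the procedure's
   behavior, and each is informative about a different failure mode:

   * `"split"` (default): each of the B draws selects on a random half
     and refits unpenalized on the other. Selection variability enters
     every draw but no draw conditions on a single possibly-wrong
     support; at n=1000 this machinery is well calibrated (pooled
     type-I ≈ 0.06, stable across seeds). At very small n it degrades
     conservatively: half-sample selection returns empty supports, draws
     are all zero, and nothing rejects.
   * `"refit"`: the full-panel eLasso fixes each node's support, and each
     draw refits the unpenalized selected model on a subject resample
     (conditional-on-selection bootstrap). This machinery exposes
     support misselection: conditioning on a wrong support turns
     truly-equal quantities into systematically different ones, so its
     type-I error is large at small n (≈ 0.5 at n=200) and falls toward
     the nominal level as selection stabilizes (≈ 0.07–0.1 at n=1000,
     with replicate-to-replicate bimodality from residual spurious
     edges). This is the machinery that reproduces the documented
     decreasing-in-n type-I trend and the lower-$\eta$-lower-error
     direction.
   * `"bootstrap"`: full re-selection on every subject resample. These
     draws are overdispersed for selected quantities (re-selection noise
     on top of sampling noise) and the tests become markedly
     conservative (pooled type-I ≈ 0.01 at n=1000).

   In refit/bootstrap modes edge pairs are restricted to true edges
   called in the reference fit; in split mode all truly-equal pairs are
   tested. The validation suite checks calibration at n=1000 under split
   draws and the sample-size trend under refit draws, each explicitly
   configured.

The package's own validation suite runs these at reduced scale, chosen so
the statistical signal is unambiguous at desk scale: study 3 at $n=1000$
with 200 draws and 50 replicates (plus $n \in \{200, 1000\}$ at 20
replicates under refit draws for the sample-size trend), study 2 at
$\Delta=0.9$ with 100 bootstraps and 20
replicates, study 1 at $n \in \{200, 500\}$ with 50 replicates, and
splitting inference with $R=50$ on a single $n=2000$ panel. The original
experiments used 200 replicates, 500 bootstraps and $n$ up to 2000;
summary bands (type-6 95%) are proportionally wider at the reduced
replication.

## Support-level aliasing

At a directed pair $(j, j')$ carrying a covariate-moderated effect
($\sigma^1_{jj'}=0$, $\gamma^1_{jj'l}=\beta$), the columns $y_{j'}^{t-1}$
and $x_l\,y_{j'}^{t-1}$ are strongly collinear (the interaction is the
main effect masked to the $x_l{=}1$ subjects), so eLasso may represent the
signal through the truly-zero main effect in an appreciable fraction of
split replicates (selection frequencies up to ~0.8 observed), and
symmetrically a fixed edge's signal can leak into its interaction columns.
Support recovery is therefore reliable at the level of *directed pairs*;
attributing an effect to the main versus the moderated column is only
partially identified at these sample sizes. Parameters on pairs carrying
no effect at all stay below 0.2 selection frequency. This also shows up as
the small FPR floor in the edge-identification study.

## Numerical choices and degenerate inputs

* Inverse logit is computed in overflow-safe form; it is total on the
  extended reals.
* A node whose outcome is single-class in the transition rows raises an
  error naming the node (no silent fit).
* eBIC ties toward the sparser model; `argmin` on a decreasing path makes
  this the first minimizer.
* MCC with any empty confusion-table margin is 0 by convention; FDR with
  nothing called is 0.
* Spearman correlation with zero-variance input returns 0 (flagged
  upstream).
* Bootstrap resamples or split halves that leave a node single-class are
  redrawn (bootstrap) or contribute a zero draw with the replicate flagged
  (splitting).

## Known limitations

* Lag-1 only; longer memory is out of scope by design.
* Binary symptoms only; ordinal/continuous severity requires a different
  likelihood.
* The covariate dimension enters the per-node predictor count as $pd$;
  large $d$ quickly outgrows what L1-logistic selection can support.
* Post-selection inference is approximate: splitting gives valid-by-
  construction selection/estimation separation per replicate, but the
  aggregation across replicates is summarization, not a formal
  simultaneous CI.
* The case-dropping correlation conflates estimation noise with genuine
  centrality instability when the reference fit itself is poor (small n).
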