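# Methods

## The model

`phagepop` models the evolution of a serially passaged virus population with a
Wright–Fisher process over *genotype classes*. A genotype class is the 6-tuple

```
k = (k_Is, k_Ins, k_s, k_ns, k_bs, k_bns)
```

counting, per genome: founder synonymous and founder non-synonymous SNVs
(standing variation carried over from the plaque-derived inoculum), de-novo
non-beneficial synonymous and non-synonymous SNVs, and beneficial synonymous
and non-synonymous SNVs. SNVs of the same type are exchangeable and share one
fitness effect, so the state of a population of N genomes is a frequency
vector over classes rather than over the astronomically many haplotypes.

**Founders.** The founder population carries Poisson-distributed SNV counts
with means `M_s` (synonymous) and `M_ns` (non-synonymous) and no beneficial
SNVs. The total-Poisson + binomial-split construction is equivalent to
independent Poisson counts per type; we implement the product form and verify
the equivalence by Monte Carlo in the tests.

**Mutation.** Each replication cycle adds `u ~ Poisson(U)` new SNVs per
genome, split multinomially over the four de-novo types with probabilities
`p_Δ = (p_s − p_bs, (1 − p_s) − p_bns, p_bs, p_bns)`. The resulting
Poisson-multinomial increment kernel factorizes into independent Poissons with
means `U·p_Δi`; increments with untruncated mass below `1/(100N)` are set to
exactly zero. After the convolution the class distribution is renormalized
(the truncation residual is logged) and additionally pruned at the same
`1/(100N)` threshold — classes below it have expected multinomial count
< 0.01 at the drift step, so the pruning error is below the truncation error
already accepted by the model, and it keeps the class support bounded.

**Selection.** Fitness is multiplicative:

```
w_k = w_s^(δ·k_Is + k_s) · w_ns^(δ·k_Ins + k_ns) · w_b^(η̃·(k_bs + k_bns))
```

with `η̃ = η` when the genome carries at least two beneficial SNVs and
`η̃ = 1` otherwise. `δ` correlates founder-SNV log-fitness with the
experimental fitness effects (0 = founder SNVs neutral in the experiment);
`η < 0` is reciprocal sign epistasis (two individually beneficial SNVs are
jointly deleterious). Frequencies are reweighted by `w_k / w̄`.

**Drift.** Exact multinomial resampling of N genomes (no Poisson
approximation; the sparse class support keeps this cheap even at N = 2·10⁷).

**Observation layer.** At each sequenced passage, sequencing errors are
applied as a second Poisson-multinomial kernel over the de-novo components
(founder counts are never altered by errors, and errors reuse the `p_Δ` type
split), followed by multinomial sampling of `N_s` reads at that passage's
coverage. The per-genome error-count mean is configurable
(`err_mean_mode`): the default `"as-printed"` uses `N_s · err_seq`
(coverage × per-base error rate), which is dimensionally odd but is kept as
the primary mode for fidelity to the source formulation; `"per-genome"` uses
`genome_length · err_seq`, the biologically natural alternative. For the MS2
defaults (coverage ≈ 2,589, genome 3,569 nt, err 5·10⁻⁵) the two differ by
~40%, which is small relative to posterior widths.

**Defaults** follow the MS2 passaging experiment: `N = 2·10⁷` virions,
10 passages with passages {3, 7, 10} sequenced, coverage 2,589 reads per
sequenced passage (the experiment's mean; per-passage coverages are
configurable), `p_s = 0.28`, `err_seq = 5·10⁻⁵` per base, genome length
3,569 nt, and one replication cycle per 120-minute passage
(`generations_per_passage = 1`; the possibility of two cycles per passage is
exposed through this knob). A hard cap of 25 SNVs per class component guards
pathological parameter draws (the summaries only resolve counts up to 10);
hitting it logs a warning and merges the overflow into the cap.

**Randomness.** One root `SeedSequence` per simulation; drift and each
sequenced passage get deterministically spawned child streams, so
trajectories are bit-reproducible and replicas independent.

## Summary statistics

* **SR** (6 entries for 3 passages): mean synonymous and non-synonymous SNV
  count per genome, per passage.
* **LR** (204): the joint (syn, non-syn) count spectrum up to 10 SNVs of each
  type — 66 cells per passage, lexicographically ordered — plus the SR
  entries.
* **L-LR** (3,009): the spectrum additionally resolved by the beneficial
  label — 1,001 lexicographic 4-tuples per passage — plus SR.

Genomes whose type totals exceed the cap of 10 are *excluded* from the
frequency cells (their mass is simply absent, so cells sum to ≤ 1); the SR
entries still carry their SNVs. Clipping into the boundary cells is available
behind nothing — exclusion was chosen because the count cap reads as a
resolution limit, not a censoring rule. Simulated populations carry the
beneficial label intrinsically (the `k_bs`/`k_bns` components); empirical
tables acquire it from trajectories: an SNV is labeled beneficial when it was
below 1% at the early passage and above 3% at the late passage in all replica
lines. The 1% rare threshold is the frequency a neutral SNV is expected to
reach by passage 10 at a per-base mutation rate of 10⁻³.

## Inference

**Priors.** Independent uniforms: `w_s, w_ns ~ U(0.1, 1)`, `w_b ~ U(1, 3)`,
`p_bs, p_bns ~ U(0, 0.01)`, `M_s ~ U(0.4, 0.6)`, `M_ns ~ U(0.7, 0.9)`,
`δ ~ U(0, 2)`, `η ~ U(−1, 3)`, and `U = 10^x` with `x ~ U(−4, 0.3)`.

**Rejection ABC.** Prior draws are simulated and the lowest ε-percentile by
root-mean-square error between simulated and observed summaries is accepted
(ε ∈ {0.1%, 1%, 5%}). The distance is taken on the raw summary scale by
default; per-entry z-scaling (fit on the simulation bank) is available via
`ABCConfig(standardize=True)`. The raw RMSE is the primary mode: it is the
stated distance of the method this package implements, and with z-scaling the
low-variance spectrum cells dominate the distance and qualitatively change
the ABC-versus-NPE comparison.

**Neural posterior estimation.** The conditional density estimator is a
mixture-density network written in NumPy: a two-layer tanh MLP (64 units)
maps the standardized summary vector to the weights, means and log-standard
deviations of an 8-component diagonal Gaussian mixture over the parameters in
an unbounded space (each parameter logit-transformed on its prior-normalized
coordinate; `U` first mapped to log10, matching its prior). Trained on
prior-drawn (parameter, summary) pairs by Adam (learning rate 5·10⁻⁴, batch
100, up to 1,200 epochs, early stopping on a 10% validation split with
patience 100, weight decay 10⁻⁶), the minimized negative log likelihood makes
the network output a direct amortized posterior: one trained network serves
any observation. Summaries are reduced to at most 256 entries before
training — non-constant entries ranked by absolute correlation with the
transformed parameters, the cut fit on the training set only — which keeps
CPU training in seconds without measurable loss on the recovery diagnostics.
A full-covariance (Cholesky) mixture variant was evaluated and *worsened*
point-estimate accuracy at these training budgets; the diagonal mixture is
the default. Hyperparameters were chosen by the calibration diagnostics below
(coverage and MAP-error of the mutation rate on synthetic data), not by any
external reference.

**Ensembles and replicas.** An ensemble trains several estimators on
non-overlapping slices of the simulation bank (8 × 10,000 at full scale) and
samples their equal-weight mixture; posteriors from replica experiments are
likewise averaged as equal-weight mixtures (equal draw counts per member;
remainders go one draw at a time to the leading members). Single-round,
amortized estimation only — no multi-round refinement.

**Diagnostics.** Marginal MAP = center of the modal bin of a 100-bin
histogram over the sample range (ties to the lower bin); HDI = narrowest
interval holding the stated mass; coverage = fraction of validation cases
whose HDI contains the truth; information gain = histogram-based
KL(posterior ‖ prior) per parameter on the prior's scale (log10 for `U`);
posterior predictive checks simulate at posterior draws and report per-entry
95% bands and the observation's band membership.

## Validation studies and their scale

The packaged studies run on one CPU by scaling the experiment down, a choice
of study design rather than a statement about the full-scale method:

* simulations for inference studies use `N = 10⁵` (not 2·10⁷) with the
  MS2 coverage and error defaults;
* the recovery study uses 100 synthetic datasets from the prior and an
  ensemble of 3 × 2,000 simulations (L-LR summaries). On this protocol the
  95% HDI for `U` covers the truth in ≳ 90% of cases and the median
  log2(MAP/true) is within ±0.5;
* the ABC-versus-NPE comparison uses one 8,000-simulation bank shared by both
  methods (ABC at ε = 1%; NPE as a 4 × 2,000 ensemble) and 5 repetitions that
  vary the observation realization and the NPE training; the recovery
  ensemble reuses the first 6,000 simulations of the same bank (common random
  numbers across studies).

## Synthetic data and what it does not emulate

The fixture generator runs the simulator and materializes every sequenced
read by assigning concrete genome positions/alleles from role-designated
pools (founder, beneficial, de-novo; synonymous and non-synonymous each),
classified against a synthetic ~900-nt toy genome with two CDSs whose reading
frames overlap — so the synonymous/non-synonymous labels and the
founder/beneficial designations hold by construction, and the table
round-trips to exactly the simulated class frequencies. The toy genome is
generated programmatically (no relation to any real sequence); its synonymous
fraction (~0.22) differs from the MS2 value of 0.28, which the model takes as
a config parameter anyway.

What the synthetic data does **not** emulate: alignment and assembly
artifacts, indels and large rearrangements, UTR variation, coverage
heterogeneity along the genome, barcode/demultiplexing errors, and
context-dependent error or mutation spectra. Passing tests therefore
demonstrate the correctness of the model, statistics and inference machinery
under the model's own assumptions — not robustness to real-data artifacts
outside them.

## Numerical choices and degenerate inputs

* Kernel and class truncation threshold `1/(100N)`; truncation residuals are
  redistributed by renormalization and logged.
* Drift and read sampling are exact multinomials; classes drawn to zero are
  dropped.
* `w̄ = 0` raises a degenerate-population error; `U = 0` short-circuits the
  mutation convolution; `M_s = M_ns = 0` founders collapse to a wildtype
  point mass.
* MAP tie-breaks to the lower bin; HDI on fewer than 2 draws errors (a single
  draw returns a zero-width interval).
* The MDN clamps log-standard-deviations to [−7, 3] and silences their
  gradient outside the clamp.

## Baselines

* **Premature-stop bound**: mean frequency per possible stop-creating SNV
  (stops / (reads × possible-stop site-allele pairs)) scaled by genome
  length; an upper bound because sequencing errors are indistinguishable from
  genuine stops. The synthetic census used in tests injects errors per
  possible SNV (per read), the convention under which the bound recovers the
  error floor exactly.
* **Single-locus neutral estimator**: rejection sampling over log-uniform
  per-site rates; candidate rates simulate neutral single-locus WF
  trajectories at all loci, distances are RMSE pooled over loci and passages
  (per-locus pooling available via a flag), and accepted rates are scaled by
  genome length. A deliberately minimal re-statement of the single-locus
  neutral approach — a contract, not a port of any existing tool.
* **Two-locus check**: a bi-allelic two-locus WF model with mutation, strong
  selection and drift but no epistasis and no recombination. The
  deterministic recursion preserves linkage equilibrium exactly
  (`x₁₁ = F(X)·F(Y)` — multiplicative selection cannot create association),
  while drift plus clonal interference drives the mean double-mutant
  frequency *below* that expectation. The check reports the simulated
  distribution of the double-mutant frequency and the quantile of the
  observed value, quantifying how unlikely an observed near-absence of double
  mutants is without epistasis.

## Known limitations

* The ten-parameter model compresses the distribution of fitness effects to
  single multipliers per SNV type; strongly bimodal effects (lethal plus
  nearly neutral) are averaged.
* No recombination, indels, UTR sites, host coevolution, or fluctuating N.
* The diagonal-mixture posterior can over-disperse marginals when the true
  posterior is strongly correlated between parameters.
* The printed-form error mean (`N_s · err_seq`) ties the error load to
  coverage; use `"per-genome"` when coverage varies widely across passages.
* Amortized estimators are only trustworthy for observations inside the
  support of the training simulations (here: prior-drawn).
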