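# Methods

This note documents the models, numerical choices and limitations behind
`rmtnet`. It is written for users deciding whether the pipeline's defaults
match their study design.

## Preprocessing and the similarity matrix

The input is an OTU × sample abundance table. Three steps precede
correlation:

* **Prevalence filter.** An OTU is kept if it is non-zero in at least
  `min_present` samples. The default rule is an absolute majority,
  `floor(n/2)+1` (8 of 15 for the 15-sample groups this pipeline targets);
  a fractional rule (e.g. 75% of samples) is selectable. The two
  conventions coexist in the MENA literature and can give different OTU
  sets; the majority rule is the worked parameterisation for 15-sample
  groups, which is why it is the default.
* **Blank fill.** Remaining zeros are replaced by 0.01 so the table can be
  log10-transformed. The fill value must be positive; 0.01 sits two orders
  of magnitude below a count of 1 and acts as a "below detection" floor.
* **log10 transform**, element-wise.

The similarity is `s_ij = |r_ij|`, the absolute Pearson correlation of the
log10 profiles, with `sign(r_ij)` retained separately so exported edges can
be annotated as positive or negative co-occurrence.

**Pairwise-complete correlations (default).** By default each `r_ij` is
computed only over the samples where *both* OTUs were originally observed;
the 0.01-filled cells never enter a correlation. The filled value maps to
log10 = −2, four-plus standard deviations below typical log-abundances, and
a single sample where two otherwise unrelated OTUs are both unobserved
would otherwise contribute a shared extreme point that inflates `|r|`
dramatically — enough to manufacture links between independent OTUs and to
fragment real modules. Pairs with fewer than three jointly observed samples
or degenerate variance get similarity 0. The unmasked variant
(`pairwise_valid=False`) reproduces the literal fill-then-correlate
reading. This choice follows the "paired valid values" behaviour of the
established web pipeline for this analysis.

## RMT threshold selection

For a candidate cutoff the similarity matrix is truncated: OTUs with no
entry ≥ cutoff drop out, surviving entries keep their value, others are
zeroed, the diagonal is 1 (a uniform shift that does not affect spacings).
The eigenvalue spectrum of the truncated matrix is then *unfolded*: a
polynomial of degree 5 (configurable) is fit to the empirical cumulative
spectral function, eigenvalues map through the fitted function, and the
result is affinely rescaled to the data range so the mean nearest-neighbour
spacing is exactly 1. Unfolding only needs the local eigenvalue scale, so
the global affine factor is a free normalisation; pinning it removes the
sensitivity of the mean spacing to polynomial overshoot at the spectrum
edges. If the fitted function is not monotone over the data range the
degree is lowered until it is. Exactly degenerate eigenvalues are split by
a deterministic ramp of ≤ 1e−10 before fitting (unfolding assumes a simple
spectrum); at least 20 distinct eigenvalues are required, below which the
spacing statistics are meaningless and an error is raised.

The spacing distribution is tested by χ² goodness-of-fit against two
universal laws, with 20 equal-probability bins under each null (bins with
expected count < 1 are merged and the degrees of freedom adjusted):

* Poisson, `P(s) = e^(−s)` — uncorrelated eigenvalues, the signature of a
  system of independent blocks (modular structure);
* the Wigner surmise, `P(s) = (π/2) s e^(−π s²/4)` — the GOE spacing law of
  noise-dominated, fully coupled spectra.

The scan walks the cutoff down from `scan_from` (default 0.99) in steps of
0.01 while the Poisson fit holds (p > α, default 0.05) and stops at the
first rejection; the selected threshold is the last cutoff that fitted.
For two-group comparisons a fixed threshold (default 0.81) is normally
imposed instead so both networks are built at the same cutoff.

The Wigner surmise is an approximation to the exact GOE spacing law (the
two differ by ~2%); at the spectrum sizes used here (hundreds of
eigenvalues) the χ² test cannot resolve that difference, which is exactly
why the surmise is an adequate reference.

## Topology, modules, roles

All panel metrics are computed on the unweighted skeleton — a link either
exists (similarity ≥ threshold) or not — matching how the reported panels
are defined; similarity weights and signs are retained for export only.
Average path distance averages over *reachable* unordered pairs; geodesic
efficiency averages `1/d` over *all* pairs with `1/∞ = 0`; connectedness is
the Krackhardt fraction of reachable pairs. The power-law R² is the OLS fit
of log10(frequency) on log10(degree) over degrees with non-zero frequency,
undefined (None) with fewer than 3 distinct degrees.

Module detection is greedy agglomerative modularity maximisation
(Clauset–Newman–Moore, via networkx) with nodes presented in sorted label
order, so results are reproducible; modules are numbered by decreasing size.
Q is Newman's modularity. Two module counts are reported: all modules, and
modules with more than `min_module_size_for_reporting` (default 5) nodes —
published module counts often use the latter convention, which is why both
are emitted without reconciliation.

`Zi` uses the population standard deviation of within-module degree over
the module's members (the convention of the role taxonomy the 2.5/0.62
thresholds come from); a module whose members all have equal within-module
degree — including singletons — gives `Zi = 0`, since its members are
topologically equivalent and none is a hub. `Pi = 1 − Σ_t (k_it/k_i)²`.
Classification is strict: boundary values (exactly 2.5 or 0.62) fall into
the ≤ branches.

## Environment linkage

Each module with more than 5 members is summarised by its eigengene: member
profiles (from the same filled, log10 table used for the network) are
standardized across samples, and the eigengene is the leading left singular
vector of the samples × members matrix, sign-fixed so its correlation with
the module's mean profile is non-negative. `variance_explained` is the
leading squared singular value over the total. Module–environment tables
report Pearson r with two-tailed t-based p per module × variable pair;
missing metadata values are dropped pairwise and never imputed; constant
variables are reported as missing. The eigengene hierarchy is average-
linkage clustering on distance 1 − r, exported as newick.

The Mantel test uses Bray–Curtis distance on relative abundances at the OTU
level against Euclidean distance on the standardized single variable. The
statistic is the Pearson correlation of the two lower triangles; the
one-tailed permutation p is `(#(r_perm ≥ r_obs) + 1)/(n_perm + 1)` with
sample labels of the variable permuted jointly, 999 permutations by
default, seeded. One test per variable; partial Mantel is out of scope.

Group contrasts of environmental variables use the pooled-variance
two-sample t-test (Welch selectable), two-tailed, with the usual
0.05/0.01/0.001 star tiers; a summary-statistics variant accepts printed
mean ± sd pairs.

## Diversity

Chao1 is `S_obs + F1²/(2F2)`, switching to the bias-corrected
`S_obs + F1(F1−1)/2` when there are no doubletons. ACE uses the classical
coverage formula with rare cutoff 10 (scikit-bio's implementation), falling
back to Chao1 with a warning when every rare taxon is a singleton. Shannon
uses the natural log (the common convention in ecology software; the base
is a parameter in the underlying call). Simpson is reported as dominance
`D = Σ p_i²` — so that *smaller* D means a more even community — with
`1 − D` alongside. Alpha diversity is computed on raw, unfiltered counts,
deliberately separate from the network's prevalence-filtered table.
Rarefaction subsamples without replacement (multivariate hypergeometric,
seeded); the analytic hypergeometric expectation is available as a
cross-check. NMDS is SMACOF with isotonic-regression disparities, classical
scaling initialisation plus seeded random restarts, minimising Kruskal
stress-1; the per-iteration stress trajectory is returned and is
non-increasing for the reported start.

## Synthetic data generator

The generator emulates the target study design: two groups of 15 samples,
200 OTUs of which four blocks of 25 form planted modules, block-structured
latent correlation (within 0.9, between 0; positive semi-definiteness is
checked at generation), and log-normal counts
`round(10^(2 + 0.5·z))` from the correlated standard-normal latents `z`.
Planting the correlation on the log10 scale makes the planted structure the
exact estimand of the pipeline's correlation step. Structural zeros are
created by zeroing the cells whose latent values fall below the
`zero_inflation` quantile (default 0.1), so zeros concentrate where
abundances would have been lowest, which is what the downstream blank-fill
confronts in real tables. Environmental drivers are
`strength·(standardized module latent mean) + sqrt(1−strength²)·noise`, so
`strength` is the target correlation with the module signal. Everything is
reproducible from the spec's seed.

What the generator does *not* emulate: compositionality (counts are not
normalised to a fixed depth, matching the pipeline's own indifference to
it), sequencing error, taxon-specific abundance distributions, and
overdispersion beyond the log-normal.

**Recovery conditions.** The planted-partition recovery tests (full chain
to detected modules, adjusted Rand index vs truth) run the generator with
`zero_inflation = 0`: recovery is a property of the planted *correlation*
structure, and latent-threshold censoring changes the estimand itself —
censored profiles genuinely correlate less, so heavily zero-inflated tables
cannot reproduce the planted partition at the same fidelity no matter the
implementation. Passing recovery therefore demonstrates that the
filter → fill → log10 → |r| → threshold → modules chain is faithful on
fully observed tables; it does not certify performance on sparse real
tables, where the pairwise-complete correlation default mitigates, but
cannot remove, the censoring effect. The null-control tests (independent
OTUs must leave < 5% of nodes connected at cutoffs ≥ 0.8) use 100 OTUs ×
15 samples; the expected false-positive fraction scales linearly with the
number of OTUs at fixed n, so this bound is a property of the tested size,
not a universal guarantee.

## Problem sizes in the standard checks

The spectral discrimination checks use 500×500 GOE draws and 25-block
superpositions (500 eigenvalues) over 100 seeded replicates; module
recovery uses 10 seeds of the default community; Mantel calibration uses
500 replicates of 40 OTUs × 15 samples with 999 permutations. These sizes
give Monte-Carlo error comfortably below the acceptance margins while
keeping the full suite fast.

## Known limitations

* Compositional effects are ignored throughout (correlations are taken on
  log abundances, not clr-transforms), mirroring the analysed pipeline.
* The RMT scan needs ≥ 20 active nodes at a cutoff before it can evaluate
  the NNSD; very sparse matrices simply skip those cutoffs.
* Polynomial unfolding assumes a smooth spectral density. Spectra with
  isolated clusters of outliers (e.g. Perron modes of several positive
  blocks) are not well unfolded by a single global polynomial; the
  discrimination contract is stated for smooth-density spectra.
* Published hub OTU identities cannot be reproduced without the underlying
  sequencing data; the pipeline reproduces the *method*, and its outputs
  are validated on synthetic truth.
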