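# Methods

## Two-pool incorporation model

The simulator and the analysis share one mechanistic picture.  Newly
synthesized ribosomal proteins (RPs) enter a small, fast-turning free
precursor pool; from there they either (i) are built into new ribosomes,
which join the mature pool after an assembly delay, or (ii) swap directly
onto pre-existing mature ribosomes (exchange).  For the labeled fraction
m(t) of a protein in the mature pool:

    df/dt = k_f (l(t) - f),      f(pulse_start) = 0
    dm/dt = k_r (g(t) - m) + k_ex (f(t) - m),   m(0) = 0
    g(t)  = l(t - tau)

* `l(t)` — label indicator, 1 while heavy amino acids are present.
* `k_f = ln2 / T_f` — free-pool relaxation.  Unassembled RPs are degraded
  quickly; T_f defaults to 2 h and is a configuration field (the
  literature constrains it only loosely).
* `k_r = ln2 / T_r` — biogenesis-driven replacement of the mature pool at
  steady state; T_r defaults to 8 days (brain RP average).  Blocking
  nuclear export of new ribosomes (leptomycin B) is modelled as k_r = 0.
* `tau` — assembly delay: the lag between synthesis and appearance in
  assembled ribosomes, implemented as a pure time shift of the label
  indicator.  This is the simplest mechanism that reproduces the
  chase-induced *increase* of slowly incorporating proteins.
* `k_ex` — exchange rate; zero for stable proteins.  With biogenesis
  blocked, exchange is the only route into the mature pool.

Assumptions: no amino-acid recycling (the heavy fraction is read as the
proportion of new protein; recycling would only rescale it), a
steady-state mature pool, first-order kinetics throughout.  All
trajectories are piecewise-exponential closed forms over the breakpoints
{pulse edges, delayed pulse edges, stress-window edges}; tests verify
them against `scipy.integrate.solve_ivp` to < 1e-6 relative error.

An acute-stress window scales both entry rates by an inhibition factor
s ∈ (0, 1] (global translation shutdown); proteins flagged as
stress-enhanced additionally get k_ex multiplied by an enhancement factor
inside the window (recruitment for ribosome repair).  Defaults: s = 0.25,
a 30-minute window starting 2 h into a 3 h labeling, enhancement 8.

## What the simulator emulates — and what it does not

One simulated measurement is H = A·m′·ε_H, L = A·(1 − m′)·ε_L with
m′ = b0 + (1 − b0)·m, a lognormal per-peptide abundance A, independent
unit-mean lognormal noises ε with CV `noise_cv` (default 0.10), and a
no-label background fraction b0 (default 0.002) that also generates the
negative-control channel.  The default panel plants 70 quantifiable RPs:

| group | n | k_ex (1/h) | tau (h) | class |
|---|---|---|---|---|
| A | 3  | 0.13  | 0 | exchanger |
| B | 4  | 0.05  | 0 | exchanger |
| C | 5  | 0.012 | 0 | exchanger |
| D | 11 | 0     | 0 | stable |
| E | 26 | 0     | 0.75 | stable |
| F | 21 | 0     | 1.75 | stable |

The 12 exchangers carry the names of the RPs identified as exchanging in
the neuronal experiments (RPLP0/1/2, RACK1, RPL10, RPL22, RPL24, RPL27,
RPL36, RPL36A, RPL38, RPS26; RACK1 counted with the small subunit); the
58 stable proteins take the remaining canonical RP names, 28 small / 30
large subunit.  Peptide counts are drawn uniformly in 1–10 (2–10 for
exchangers, which are well-covered targeted proteins).  Exchange rates
and delays were fixed once so that adjacent groups are separated by well
over five within-group spreads at 10% noise while stable-protein
amplitudes stay at the physiologic turnover expectation (~0.4%/h); they
are not fitted to any real dataset.

Not emulated: spectra, chromatograms, retention time, missing peptides,
between-replicate biological variability beyond measurement noise,
shared-peptide ambiguity, and dependence of noise on intensity.  Passing
recovery tests therefore demonstrate that the *analysis chain* is correct
and well-calibrated under the stated noise model — not that real data of
this difficulty would be resolved equally cleanly.

Seed handling: one master seed; the per-peptide abundance stream and each
condition's noise stream are independent child streams
(`SeedSequence(seed, spawn_key=...)`), so adding a condition never
perturbs the others and equal seeds give byte-identical tables.

## Quantification rules

* %H = H/(H+L) per peptide; both areas zero ⇒ missing, never 0/0.
* Technical replicates merged by arithmetic mean; missing values ignored.
* Background filter: a peptide is kept iff its mean %H in every labeled
  condition of interest is ≥ 3× its mean no-label %H.  The mean (not
  per-replicate) comparison is a choice; peptides with no no-label record
  are kept with a warning rather than silently dropped.  The filter is
  intended for long labelings where true signal clears the background by
  construction; after a 1 h pulse a stable protein's signal is only
  ~2.8× background, so the kinetics chain does not apply it.
* Protein roll-up: median over peptides, per condition × replicate.
* Fold changes: per peptide, ratio of replicate means (treated/control);
  per protein, median of peptide ratios.  Zero control fractions make a
  peptide unusable (skipped and counted, not imputed).  Fold changes are
  computed on linear-scale fractions; log2 is a display/test scale.
* Polysome fraction: trapezoidal areas above a baseline,
  A_poly/(A_mono + A_poly).  qPCR relative levels: 2^(−ΔΔCt) with an
  internal reference and a no-label control.

## Kinetic clustering

Profiles are replicate-resolved (one column per condition × biological
replicate), so replicate scatter participates in the distances as it does
in a clustered heatmap.  Clustering is agglomerative with Euclidean
distance; complete linkage is the default (the common default of the
heatmap tooling this emulates), with other linkages exposed.

Distances are taken on log2 fractions by default (`log_scale=True`).
Heavy fractions carry multiplicative noise, so on the linear scale
cluster spread grows with amplitude: fast exchangers form clouds two
orders of magnitude wider than the tight stable groups, and any global
quality criterion then prefers coarse cuts that merge the small-amplitude
groups.  On the log scale the noise is homoscedastic and amplitude ratios
become distances, which is the appropriate geometry for ratio data.  The
raw-scale option remains available.

The number of groups k is chosen by maximizing the mean silhouette width
over k = 2..10 — a stand-in criterion: the original analysis reports six
groups without stating how the cut was chosen.  A fixed-k override
exists.  The "rapidly incorporating" set is the union of clusters whose
mean pulse-only (no-chase) heavy fraction strictly exceeds the grand mean
over all proteins; with no numeric cut published, the grand-mean rule is
our explicit choice.

A note on chase direction: a chase-induced *decrease* (the signature of
fast exchangers being replaced by unlabeled nascent protein) requires the
mature pool to track the decaying free pool, i.e. k_ex of the order of
k_f or larger.  At the moderate default amplitudes the planted exchangers
still gain label during a 3 h chase; the decrease is demonstrated in
tests with fast free-pool turnover (short T_f, high k_ex).

## Exchanger calling (ROUT)

LMB/control fold changes are first normalized by the median fold change
of the protein's own subunit (within compartment, median including the
protein itself), removing the different bulk effect of export block on
the two subunits.  Outliers are then called with the ROUT procedure
specialized to a constant model — the degenerate case of its published
robust-regression form:

1. residuals = log(normalized FC) − median(log normalized FC);
2. RSDR = 68.27th percentile of |residuals| × n/(n − 1);
3. residuals tested largest-first with two-tailed t tests (df = n − 1) at
   α_i = Q·(n − i + 1)/(100·n); the first failure stops the scan.

Q defaults to 0.2 (percent).  Exchangers are the HIGH-side outliers only
(least reduced by biogenesis inhibition); low-side outliers are reported
but not labeled.  Tests verify agreement with an independent brute-force
implementation of the same recipe for n ≤ 8 and a null false-positive
rate within the Q bound on 10,000 Monte-Carlo values.  Testing on log
fold changes reflects their multiplicative nature.

## Stress differential test

Treated heavy fractions are divided by the arithmetic mean of all
per-peptide treated/control ratios (geometric-mean option exposed), which
makes the all-peptide mean fold change exactly 1.  Per protein, on log2
fractions: y = μ + β·treatment + u_peptide + ε with a random peptide
intercept.  For the balanced complete design the REML solution reduces
exactly to two-way (peptide + treatment) ANOVA — peptide intercepts
cancel in the treatment contrast — giving β as the difference of
condition means, Var(β) = σ_e²(1/n₁ + 1/n₀), and residual df N − P − 1;
this closed form is used whenever the design is balanced and is
cross-checked against `statsmodels` MixedLM in tests.  Unbalanced
proteins fall back to MixedLM (REML) when they have ≥ 3 peptides, else to
fixed peptide intercepts.  Proteins observed in only one condition are
marked untestable.

Significance: Benjamini–Hochberg across testable proteins, FDR < 0.01,
*and* |β| ≥ half the interquartile range of all per-protein effects (the
minimal-difference gate; "interquantile" read as interquartile).  This is
a deliberately simplified stand-in for the dedicated peptide-level
mixed-model packages, which add ridge shrinkage, robust observation
weights and empirical-Bayes variance moderation; exact numerical
agreement with them is a non-goal.  In full stress simulations the
delayed-assembly groups also show genuine (secondary) down-regulation,
because their effective labeling window overlaps the stress window
disproportionately — the enhanced subset is distinguished by effect sign
and size, not by being the only non-null proteins.

## Surface accessibility

SASA uses the Shrake–Rupley construction with a deterministic
golden-spiral (Fibonacci lattice) point set — results are reproducible
bit-for-bit — with probe radius 1.4 Å, 960 points per atom, and a bundled
Bondi-style van der Waals radii table (overridable).  A chain's
accessible fraction is its SASA computed inside the full complex divided
by its SASA in isolation; this two-pass definition is equivalent to
"total surface minus all interface areas, over total surface" up to
interface bookkeeping.  Absolute areas differ from interface-analysis
web services; the preserved contract is the *fraction* and the
stable-vs-exchanger comparison (two-tailed Mann–Whitney; exact for small
tie-free samples).  Tests pin the isolated-sphere closed form (< 0.2%),
rotation invariance (< 0.5%), occlusion monotonicity, a brute-force
grid-integration oracle (2%) and an independent library implementation.
Analysis of a real ribosome structure requires downloading its PDB entry
and is deliberately outside the test surface; toy structures are
generated in the tests.

## Occupancy normalization

Polysome-profile abundances are divided by the median abundance of the
protein's own subunit within each fraction; small-subunit proteins never
receive a value in the large-subunit fraction and vice versa (structural
absence, not missingness).  Clustering reuses the kinetics machinery on
the columns shared by all proteins (no imputation).

## Problem sizes and determinism

Default study designs: 70 proteins; 3 biological × 2 technical
replicates for the pulse/pulse-chase arm, 4 biological for the 2-day
LMB arm, 3 for the stress arm; noise CV 0.10; background 0.002.  The
acceptance script runs these designs as-is.  Monte-Carlo test suites use
10,000 null values (ROUT) and ~1,000 proteins (mixed-model null), sizes
at which the checked rates are stable; everything is seeded and the whole
pipeline is deterministic given its configuration.

## Known limitations

* The exchange/biogenesis model is linear and memoryless; cooperative or
  site-limited exchange is not represented.
* The background filter interpretation (mean across replicates) and the
  grand-mean rapid-group rule are explicit choices where the original
  description is silent.
* The silhouette criterion for k is a documented stand-in; nothing
  guarantees it matches how the published six-group cut was chosen.
* The ROUT constant-model specialization fixes df = n − 1 and the
  n/(n − 1) RSDR correction; other small-sample corrections exist.
* Real-data reanalysis (deposited proteomics accessions) is supported by
  the same interfaces but is not part of the test surface.
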