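# Methods

## Model

Each chromosome's ordered marker sites carry a two-state hidden chain:
**P** (phenotype-linked) or **N** (neutral). Observations are the
superior-parent read counts n_A out of total coverage n at each site.

**Emissions.** n_A | state ~ BetaBin(n, α, β) with state-specific shapes.
The beta-binomial's overdispersion absorbs the extra variance of pooled
counts relative to a binomial (pool composition noise, library and
alignment artefacts). Neutral shapes (α_N, β_N) are estimated from the
data (below). Linked-state shapes are user-set with β_P = 1 and α_P the
stringency knob: the implied Beta(α_P, 1) allele-frequency density is
∝ p^(α_P−1), so larger α_P demands stronger skew toward the superior
allele before a site looks linked. Defaults: α_P = 10 (permissive), with
15 and 30 as stricter presets. Log-pmfs are evaluated through the
log-gamma function (scipy) and remain finite at coverage 100+ and shape
parameters up to the 10⁶ concentration cap.

**Transitions.** Over an inter-marker gap of l bp the chain stays in its
state with probability e^(−r·l) (N state) or e^(−r·l·s) (P state), and
switches with the complement. r (default 3.5×10⁻⁶ per bp, an average
yeast meiotic recombination scale) controls how fast state persistence
decays with distance; s (default 1.0) allows asymmetric persistence and
is exposed only as a knob. True inter-marker distances are used — no
binning. The *stay* orientation is deliberate: persistence must *decrease*
with distance for LD to regularise the decoding, and markers a few hundred
bp apart then share their state with probability ≈ 0.999. A consequence
worth noting: the r → ∞ limit of this parameterisation is deterministic
state *alternation*, not independence; exact site-independence occurs at
stay = 1/2 (r·l = ln 2), where the transition rows are uniform. The test
suite pins both limits (r → 0 gives a chromosome-wide consensus posterior;
the memoryless rate reproduces single-site Bayes posteriors exactly).

**Initial distribution.** (π_N, π_P) = (0.5, 0.5) by default and
configurable; with hundreds of markers per chromosome the smoothing
posteriors are dominated by emissions and transitions, so this choice is
inconsequential in practice.

**Decoding.** Scaled forward–backward (per-site normalisation constants,
emissions max-shifted per site) gives exact smoothing posteriors; with two
states the normalised linkage probability P(P_i|D)/(P(P_i|D)+P(N_i|D)) is
the P posterior itself. Chromosomes are decoded independently; the chain
is *not* broken at large gaps (e.g. centromeres) — the exponential decay
already makes distant markers nearly independent, and a hard break would
add an arbitrary threshold.

**Region calling.** Markers with posterior strictly greater than the
cutoff (default 0.95) are grouped into maximal consecutive runs; any
sub-threshold marker breaks a run (no gap tolerance). A region spans the
first to last marker of its run, inclusive.

## Neutral-parameter estimation

Most of a genome is neutral, so (α_N, β_N) are fitted from the observed
allele fractions p_i = n_A/n by the method of moments: with μ̂ = mean(p_i),
v̂ = sample variance(p_i) and n̄ = mean coverage, the intraclass
correlation is

    ρ̂ = (v̂·n̄ / (μ̂(1−μ̂)) − 1) / (n̄ − 1),

clamped to [10⁻⁶, 1−10⁻⁶]; then α_N + β_N = 1/ρ̂ − 1 (capped at 10⁶) and
α_N = μ̂·(α_N+β_N). Mean coverage rather than per-site n_i keeps the
estimator closed-form; within the usual 20–100 coverage filter window the
difference is negligible. Underdispersed data (ρ̂ ≤ 0, e.g. every p_i
exactly 0.5) hit the concentration cap and behave as near-binomial rather
than erroring, keeping the pipeline total. Estimation fails only when the
pooled mean fraction is exactly 0 or 1 (no information about balance).

Fitting is two-step: fit on all markers, decode once, drop markers whose
posterior exceeds the cutoff, re-fit on the remainder, decode again. The
first fit is biased by any true QTL (its markers inflate both μ̂ and v̂);
the exclusion step removes most of that contamination. If the first pass
marks essentially everything linked, the step-1 estimates are kept with a
warning.

## Marker filters

Applied in the fixed order quality → coverage → spacing, all idempotent:
genotype quality ≥ 40 (only when a quality column exists), total coverage
within [20, 100] inclusive, and removal of *both* members of any marker
pair closer than 30 bp (distances measured on the original input, which
makes the rule order-independent). These are the standard upstream-hygiene
settings for real pooled data; simulated data is analysed unfiltered (its
fixed coverage of 200 would otherwise be rejected wholesale), which is why
the Model default applies no filters and the CLI `run` command defaults to
the real-data set. Repeat-region and copy-number masking require a genome
annotation and are expected to have been applied upstream.

## Synthetic data generator

One dataset = one artificial chromosome (default 750 kbp) with n_markers
(default 2500) distinct marker positions uniform over the chromosome, one
chosen uniformly as causal. A segregant starts from either parent with
probability 1/2 and recombines at crossover breakpoints drawn as a Poisson
process with intensity 0.37 cM/kb / 10⁵ = 3.7×10⁻⁶ per bp (the
small-distance Haldane limit; the explicit-breakpoint construction is
validated in the tests against the odd-crossover discordance formula
(1 − e^(−2ρl))/2). Pool selection: a candidate carrying the superior
allele at the causal site is accepted with probability PSC, a non-carrier
with 1−PSC, until n (default 30) segregants are pooled; carriers arise
with prior 1/2, so the expected pooled carrier fraction equals PSC —
PSC = 0.95 is a low-noise screen, 0.5 a fully neutral pool. Sequencing:
per marker, coverage c (default 200, fixed; Poisson(c) optional) reads
each sample a pooled segregant uniformly with replacement and report its
allele flipped with probability ε = 0.01. Implementation detail: with
pool superior fraction f at a marker the read-level process collapses
exactly to one Binomial(c, f(1−ε) + (1−f)ε) draw, which is what is
sampled.

What the generator does **not** emulate: diploid/inbred designs, multiple
or interacting QTLs, read-level artefacts (mapping bias, indels, base
quality structure), variable marker informativeness, and chromosome-scale
features such as centromeric recombination suppression. Passing tests
therefore show the estimator is correct *under the model's own data
assumptions*; performance on real data additionally depends on upstream
alignment and calling quality, which the filters only partially address.

## Evaluation

Predictions for a dataset are scored as: recovered iff some called region
strictly contains the causal position (an adjacent but non-containing
region counts as a false positive — conservative and unambiguous);
causal-region size = end − start + 1 of that region; false positives =
all remaining regions, including fragments of a true LD block split by a
sub-threshold marker. Benchmarks run 100 replicates per setting, each
replicate seeded deterministically from (master seed, replicate index),
and report means with Monte-Carlo standard errors.

A behaviour documented by the benchmark and worth knowing: at small pool
size (n = 30) a fully neutral pool (PSC = 0.5) still yields a called
region in roughly one replicate in ten, with ~0.14 false regions per
dataset on average. This is not a decoding artefact — in those replicates
pool-composition drift (pooled carrier counts follow a ±1 random walk
across the ~80 crossover breakpoints of the pool) genuinely sustains a
0.70–0.83 allele frequency over a multi-kbp LD block, which is
information-theoretically indistinguishable from a weak QTL in a single
pool. At n = 131 the same null is clean (no called regions in 100/100
replicates). Small-pool designs should therefore treat isolated calls
with caution or use a control pool.

## Individual-segregant validation

For fine-mapping, markers re-scored in individually genotyped segregants
(k of m carrying the superior variant) are tested against k ~
Binomial(m, 1/2) with a two-sided exact binomial p-value computed by
doubling the smaller tail and capping at 1 (at p₀ = 1/2 this coincides
with the minimum-likelihood two-sided test by symmetry). Multiple testing
uses Benjamini–Yekutieli (valid under arbitrary dependence — neighbouring
markers are strongly linked), with linked = adjusted p < 0.05.

## Numerical and design choices

- Forward–backward in scaled linear space with per-site max-shifted
  emissions; exhaustive-path enumeration agrees to 10⁻¹⁰ on random
  instances up to 12 sites.
- Coverage bounds of the filter are inclusive at both ends.
- Posterior cutoff comparisons are strict (> cutoff).
- TSV, not VCF, is the canonical input: orienting counts toward the
  superior parent is an upstream decision this package cannot make.
- BED output is 0-based half-open with score = round(1000 × max
  posterior); input coordinates are 1-based.
- Problem sizes in the test suite: study-scale checks use 100 replicates
  at 2500 or 10000 markers; component-level Monte-Carlo identities use
  3000–10000 draws, sized for tight (3–4 σ) bands.
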