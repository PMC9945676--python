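# Methods

## Model overview

`dmrseg` detects differentially methylated regions in two stages: an HMM
segments the CpG axis into runs of constant methylation state between two
groups, and a Bayesian GLM with a bisulfite observation model scores each
region for differential methylation with respect to one covariate in an
arbitrary design, reporting Savage–Dickey Bayes factors.

### Segmentation

Observations are per-CpG differences of group-mean methylation levels,
`y_t = mean(μ, group 1) − mean(μ, group 2)`, `μ = N_BS,C / N_BS`. Group means
are unweighted over samples with non-zero coverage; a CpG is dropped from the
track when an entire group is uncovered (with the default inner join across
samples this cannot happen). Methylation levels can optionally be mapped to
M-values, `M = log2(μ/(1−μ))` with `μ` clipped to `[ε, 1−ε]`,
`ε = max(1/(N_BS+2), 1e−3)`, which moves the observations onto the real line
where the Gaussian emissions are more natural.

Hidden states carry Gaussian emissions `N(ψ, σ)`. Defaults:

| scale | states | (ψ, σ) |
|---|---|---|
| beta | 3 | equal (0, 0.08), hypo (−0.3, 0.06), hyper (0.3, 0.06) |
| beta | 5 | equal (0, 0.08), hypo₁/₂ (−0.25/−0.5, 0.06), hyper₁/₂ (0.25/0.5, 0.06) |
| M | 3 | equal (0, 0.5), hypo (−1.7, 0.5), hyper (1.7, 0.5) |

The initial transition matrix puts 0.9 on the diagonal with the remainder
split evenly, and the initial distribution is uniform; this encodes
persistence of methylation state along the chromosome and is refined by
Baum–Welch. By default only `(A, π)` are re-estimated (emissions stay fixed
at their prescribed values); `learn_emissions` re-estimates the Gaussians
too, starting from a seeded k-means of the pooled observations, with fitted
states relabelled equal/hypo/hyper by the sign and magnitude of their means.
Transitions carry no genomic-distance term — only CpG order matters — and
each chromosome is an independent sequence.

Decoding uses log-space Viterbi with the emission density floored at 1e−300
(so an extreme observation cannot annihilate every path) and ties broken
toward the lower state index, making output deterministic. Maximal
same-state runs become regions; per-sample counts are summed over member
CpGs. Candidate selection keeps either all regions or only the hypo/hyper
families, with an optional minimum CpG count (26 reproduces the ">25 CpGs"
filter commonly applied to real data).

Forward–backward uses per-step rescaling rather than log-sum-exp, which is
numerically equivalent for these state counts and substantially faster.

### Region model and inference

Per region, with design `D (N × N_p)` and interest index `k`:

    b ~ Normal(0, σ_b² I)        σ_b² = 15
    σ_E² ~ Gamma(α_E, β_E)       shape–rate, α_E = β_E = 5 (prior mean 1)
    Y ~ Normal(D b, σ_E² I)
    θ = sigmoid(Y)
    N_BS,C_i ~ Binomial(N_BS_i, p("C"|5mC)_i θ_i + p("C"|C)_i (1 − θ_i))

The conditional "C" probabilities encode bisulfite conversion (`BS_eff`),
incorrect conversion (`BS*_eff`) and sequencing error (`seq_err`); with ideal
chemistry (`BS_eff = 1, BS*_eff = 0, seq_err = 0`, the default when no
control data are supplied) the likelihood reduces to `Bin(N_BS, θ)`.
`BS_eff` can be estimated as the conversion fraction on an unmethylated
spike-in (lambda phage), `BS*_eff` as the conversion fraction on a fully
methylated oligo, and `seq_err` from Phred scores via `10^(−Q/10)`. The
Gamma prior for `σ_E²` is taken in the shape–rate parameterization.

Inference runs on the unconstrained vector `(b, log σ_E², Y)` with analytic
gradients:

* **HMC** — leapfrog integration with a jittered number of steps (uniform on
  1..16, guarding against periodic orbits), dual-averaging step-size
  adaptation targeting 0.8 acceptance, and a diagonal mass matrix estimated
  from the second warmup phase, shrunk toward the unit metric. Defaults: 4
  chains, 1000 warmup, 1000 sampling iterations. Transitions with an energy
  error above 1000 are counted as divergences in the diagnostics. All chains
  (and, in batch mode, all regions) advance in lock-step as one vectorized
  computation.
* **ADVI** — mean-field Gaussian over the same unconstrained space,
  reparameterization-trick ELBO gradients (4 Monte-Carlo samples per step),
  Adam at learning rate 0.1, up to 10,000 steps with early stopping when the
  windowed ELBO changes by less than 1e−4 relative over 100-step windows;
  1000 approximate posterior draws are then sampled from the fit.

The Bayes factor for `b_k = 0` is the Savage–Dickey density ratio: the prior
ordinate is the closed-form `Normal(0, σ_b²)` density at zero; the posterior
ordinate is, by default, a moment-matched normal approximation to the draws
of `b_k` (a Gaussian KDE is available as an alternative — the normal
approximation is smoother in the far tail, where the KDE ordinate at zero
degenerates once the posterior has moved away). `BF > 1` favours
differential methylation, and the BF is the region score used for ranking.

Regions are modelled independently (no pooling of `σ_E²` or `b` across
regions). Because all regions in a run share one design matrix, fits are
vectorized across regions in chunks; a batched run draws from one seeded RNG
stream, so per-region draws depend on batch membership, while the
single-region path (`fit_region_model`) is exactly reproducible per region.
Only summaries (BF, posterior mean and 95% interval of `b_k`) are retained
for large batches to bound memory.

## Synthetic data

The simulator defines the study conditions the test-suite measures.

**Confounded protocol.** The CpG axis is partitioned into regions with
lengths `L ~ ceil(Gamma(shape=4, rate=0.2))` (mean ≈ 20 CpGs). Each region
draws `b ~ N(0, 5)` per covariate; null regions have the interest
coefficient forced to 0, DMR regions rejection-sample it from the same
normal truncated to `|b| > 3`. Region noise is
`σ_E² ~ Gamma(shape=0.5, scale=1)`; `Y ~ N(Db, σ_E²)` and `θ = sigmoid(Y)`
are shared by all CpGs of the region. The default design has 6 samples and
four covariates — intercept, binary case/control (of interest), an arbitrary
binary and an arbitrary continuous covariate (0.3/0.5/0.7) — so the nuisance
covariates partially align with case/control and act as genuine confounders.
Read depth is `Poisson(30)` truncated at ≥ 1 per CpG and sample (depth is a
free choice documented here; 30× is a typical WGBS design), counts are
binomial at ideal experimental parameters, and coordinates are a synthetic
50-bp stride on one chromosome (the model is distance-blind, so only CpG
order matters). Full-scale defaults are 215,000 CpGs with 1,700 DMRs;
benchmark runs use 20,000 CpGs / 170 DMRs.

**Spike-in protocol.** Two groups of 6 samples. Region baselines come from a
bimodal `Beta(0.5, 0.5)` (mimicking the low/high methylation of CpG-island
data); each sample draws a replicate level from a Beta centred on the
baseline (concentration 50), giving within-region correlation and
between-replicate variability. In DMRs the case group's success probability
is shifted by a difference drawn from {0.1, 0.2, 0.3, 0.4} with random sign;
baselines too close to the boundary for the chosen shift are re-drawn. This
generator is a synthetic stand-in for benchmarks built from real CpG-island
data: it reproduces fixed effect sizes and within-region correlation but not
real coverage profiles, genomic spacing, or island/shore structure — so
passing tests demonstrate correct behaviour of the algorithms under the
stated generative assumptions, not performance on any particular real
dataset. Because replicate variability is part of the design, realized
group differences match the nominal shift in expectation over DMRs, with
per-region spread beyond pure binomial noise.

## Evaluation conventions

Scoring is per cytosine: each region's BF is propagated to its member CpGs
and CpGs not covered by any returned region score zero. AUROC uses mid-rank
tie handling and AP processes tied scores as a block; both matter here
because region-constant scores and the zero mass produce heavy ties. Under
these conventions a constant ranking has AP exactly equal to the
positive-class fraction, which is the quoted chance baseline. Both metrics
are invariant under strictly monotone transforms of the BF.

The desk-scale confounded benchmark (20,000 CpGs, 170 DMRs) has a positive
fraction of ≈ 0.17. AP depends strongly on class balance, so AP values from
this benchmark are only comparable against the same balance — at
genome scale the same method yields much lower AP simply because the
positive fraction is ~0.0014.

## Numerical and design choices

* Viterbi tie-break: lower state index wins; exact ties have measure zero
  for continuous observations but the rule makes decoding deterministic.
* Baum–Welch stops when the total log-likelihood improves by less than
  `tol = 1e−4` or after `max_iter = 50` iterations; rows of `A` for states
  never visited retain their previous values.
* Counts with `N_BS = 0` give a missing `μ` (excluded from group means)
  rather than 0/0.
* Binomial success probabilities are clipped to `[1e−12, 1 − 1e−12]` inside
  the likelihood; `log σ_E²` is clipped at ±700 before exponentiation.
* Savage–Dickey requires ≥ 100 draws; the posterior ordinate is floored at
  1e−300 so the BF stays finite.
* Input coordinates are 1-based (bismark convention); all BED output is
  0-based half-open. Strand is ignored. The default join across samples is
  the intersection; a union mode marks missing coverage as `N_BS = 0`.

## Limitations

* Transitions ignore genomic distance, so widely separated CpGs are treated
  as adjacent; on sparse data this can merge unrelated regions.
* One methylation modification only (no 5hmC), no spatial random effects
  within regions, and two-group observation tracks only (the Bayesian stage,
  by contrast, handles arbitrary designs).
* ADVI's mean-field family underestimates posterior spread; Bayes-factor
  rankings agree closely with HMC, but interval widths from ADVI should not
  be used for calibrated inference.
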