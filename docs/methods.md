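# Methods

## Model

Analysis is restricted to the `P` protein isoforms compatible with at
least one detected peptide; isoforms without any detected peptide
cannot be identified and are removed upfront, so the detected-peptide
counts satisfy `M_p ≥ 1`. The per-isoform abundances
`X = (X_1, …, X_P)` are modeled as a multinomial split of the total
abundance `n = Σ_p x_p` with probabilities `π` on the simplex, and `π`
gets a conjugate `Dirichlet(δ)` prior. `X` is never observed — the data
are peptide abundances `Y_i` with compatibility sets `ψ_i` — so the fit
uses Bayesian data augmentation: latent states and parameters are
alternately drawn from their full conditionals (Gibbs sampling).

One sweep consists of:

1. **Mis-detection layer (PEP mode).** `ε_i ~ Bernoulli(PEP_i)`
   independently per peptide; `ε_i = 1` means the identification is
   treated as erroneous this sweep and contributes no abundance. The
   indicators are resampled every sweep. In FDR mode this layer is
   skipped (`ε ≡ 0`) and unreliable peptides are removed up front
   instead.
2. **Allocation.** Each retained peptide's abundance `Y_i (1 − ε_i)`
   is split across `ψ_i` by a multinomial draw with probabilities
   proportional to `π_p / M_p` on `ψ_i` and zero elsewhere. The
   `1/M_p` factor normalizes for the number of peptides contributing
   to each isoform, so that an isoform detected through many peptides
   is not over-counted. Summing allocations over peptides yields `x`,
   and `Σ_p x_p = Σ_i Y_i (1 − ε_i)` holds exactly at every sweep.
3. **Conjugate update.** `π | x, δ ~ Dirichlet(x + δ)`.

Abundances must be integers: PSM counts are used as-is; intensities
are first divided by the sample total, multiplied by 1e5 and rounded
to the nearest integer (half-to-even, the IEEE default — the rule
matters only for exact .5 ties and is fixed for reproducibility). The
total rounding error is bounded by N/2 counts out of 1e5.

## Error-handling modes

* **FDR mode** (default): peptides with FDR strictly below the
  threshold (default 0.01, "below" read literally as `<`) are kept and
  treated as correct. Fast, one latent layer.
* **PEP mode**: a weak FDR pre-filter is applied first (default 0.10,
  boundary kept, since peptides *above* 10% FDR carry error
  probabilities too close to 1 to be informative), then the
  mis-detection layer weights each remaining peptide by its PEP. More
  peptides are analyzed and detection uncertainty propagates into the
  posterior, at roughly the cost of one extra Bernoulli vector per
  sweep. A missing PEP column with PEP mode requested is a hard error;
  there is no silent fallback to FDR mode.

`M_p` is computed once on the filtered peptide set (after the strict
filter in FDR mode, after the weak pre-filter in PEP mode) and held
fixed across sweeps; it is a property of which peptides are analyzed,
not of which happen to be sampled as correct in a given sweep.

## Prior

Without transcript data, `δ = (1, …, 1)` (weakly informative). With a
transcript-abundance table (e.g. TPM), entries are restricted to the
analyzed isoforms, isoforms with no entry or zero TPM receive a
configurable pseudo-TPM floor (default 1) so every `δ_p` stays strictly
positive, and the result is renormalized to `π^T`; then
`δ = prior_mass · π^T`. The total prior mass defaults to `P`, giving
the informative prior the same weight as the flat one relative to the
data; it is exposed as a knob (`prior_mass` / `--prior-mass`) because
the appropriate strength depends on how much the user trusts the
mRNA–protein correlation in their system.

## Sampler implementation and numerics

* **Initialization:** `π⁰ = δ/Σδ`, `ε⁰ = 0`. All updates are
  conjugate draws, so the chain forgets its start quickly; the default
  2000 sweeps with 1000 burn-in (both user-adjustable) follow the
  same convention as the reference settings for this class of model.
  No thinning: every post-burn-in draw is kept.
* **Vectorized allocation:** unique peptides are allocated
  deterministically (their whole retained abundance goes to the single
  compatible isoform). Shared peptides are grouped by `|ψ_i|` and each
  group is allocated with a conditional-binomial decomposition of the
  multinomial — component `j` given the remaining total is binomial
  with probability `w_j / (w_j + … + w_k)` — which replaces a
  per-peptide Python loop with a handful of array operations per
  group.
* **Blocks:** the connected components of the bipartite
  peptide–isoform graph are computed (union–find) and reported in the
  run manifest. Peptides never couple isoforms across blocks, so the
  single vectorized pass is distributionally identical to per-block
  processing; the global `π` is still drawn jointly each sweep, which
  keeps the prior coupling exact without any derivation about
  factorizing the Dirichlet over blocks. Thread-level per-block
  concurrency is not implemented: at the problem sizes this package
  targets, the vectorized single-process sweep is faster than the
  coordination overhead would allow.
* **Degenerate weights:** with `δ > 0` the Dirichlet draw is positive
  almost surely, so all-zero allocation weights can only arise from
  floating-point underflow; that case falls back to a uniform split
  over `ψ_i` and is logged.
* **Determinism:** one `numpy` PCG64 generator seeded from the config
  drives the whole chain; identical seed + config + inputs give
  bit-identical chains and byte-identical output files.

## Posterior summaries

* `Pr(X_p > 0)`: fraction of kept draws with `x_p > 0`.
* Point estimates: posterior means of `X_p` and `π_p`.
* **HPD intervals** at level 0.95 (configurable) via the empirical
  shortest-window estimator: the narrowest window of `⌈level·K⌉`
  sorted draws, ties broken toward the lowest endpoint. On strongly
  discrete chains this is the natural finite-sample analogue of the
  highest-density region.
* **Gene aggregates** are computed on the per-sweep sums of the member
  isoforms' `x` draws, not on per-isoform summaries, so gene CIs
  reflect the joint posterior (anti-correlation between isoforms of a
  gene narrows them). Gene-level relative abundances are not reported:
  `π` is defined across the whole sample and summing it per gene has
  no per-gene simplex interpretation.
* With transcript data: `log2((π̄_p + κ)/(π_p^T + κ))` with
  κ = 1.5e−6 stabilizing zeros, using the posterior mean `π̄_p` (a
  point-estimate fold change), and `Pr(π_p > π_p^T)` as the per-draw
  exceedance frequency.

## Synthetic data generator

`make_random_truth` emulates the structure of deeply fractionated
human cell-line datasets: isoforms partitioned into genes (~3 isoforms
per gene), a bipartite compatibility graph in which a configurable
fraction of peptides is shared (default 0.8, matching the ~80% shared
peptides seen after FDR filtering in such data), with shared peptides
preferentially linking isoforms of the same gene; integer abundances
drawn log-normally (base-10 mean 0.8, sd 0.5, giving present-isoform
means of order 10 counts) with a default 30% of isoforms absent; and
transcript abundances generated with a target correlation (default
0.65) to `log10(truth + 1)`, the level reported for mRNA–protein
isoform abundance agreement. Defaults were fixed once from those
published structural figures. The first `P` peptides cover each
isoform once so every isoform is analyzable.

`simulate_peptides` splits each isoform's true abundance across its
compatible peptides with an **equal-probability** multinomial draw and
sums contributions per peptide — total abundance is conserved exactly.
Real peptides carry FDR = PEP = 0 (noise-free). Optionally a fraction
of decoy peptides is appended: erroneous identifications with
abundance resampled from the real peptides' positive abundances, PEP
from Beta(40, 2) (mean ≈ 0.95) and FDR uniform on (0.02, 0.09) — so a
strict 0.01 FDR filter removes them, a weak 0.10 pre-filter keeps
them, and the PEP layer is what must discount them. The decoy
mechanism is a documented stand-in for an unspecified real-data error
process.

What passing tests on this generator do **not** show: robustness to
peptide detectability differences, missing peptides, digestion
chemistry, search-engine score miscalibration, or an incomplete
protein database. Note also that the generator allocates abundance to
peptides uniformly, while the model allocates by `π_p/M_p` — the
model is deliberately fit under this mild misspecification, as it
would be on real data.

## Evaluation metrics

Against a known truth: presence AUC from `Pr(X_p > 0)` via the
tie-corrected Mann–Whitney estimator (ties at exactly 0 and 1 are
common, so the tie-aware form is required); Pearson correlation of
estimated vs true abundance on the `log10(x + 1)` scale; CI coverage
with closed endpoints (truth on the boundary counts as covered);
class-wise mean estimated abundance for truly present vs absent
isoforms; and mean bias.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale chosen to
keep Monte Carlo error small relative to the asserted margins: the
calibration check pools 20 datasets × 200 isoforms (4000 intervals);
the brute-force oracle comparison uses 1e5 kept draws with
batch-means standard errors (post-burn-in Gibbs draws are
autocorrelated, so naive iid standard errors would understate the
Monte Carlo error); mode-consistency comparisons use 1e4 kept draws.

## Known limitations

* Single-sample model: no biological replicates, no differential
  testing across conditions.
* Presence probabilities are posterior quantities per isoform; no
  multiplicity control across isoforms is applied to presence calls.
* PEP mode trusts the search engine's PEP calibration.
* Intensities are rounded to a 1e5-count scale; for extremely skewed
  intensity distributions the discreteness floor (1 count = 1e-5 of
  the sample) limits resolution of very low-abundance peptides.
* Convergence diagnostics beyond the shipped checks (constant-chain
  detection, calibration tests) are left to the user via
  `--save-chains`.
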