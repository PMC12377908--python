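# isoinfer

Bayesian inference of **protein isoform presence and abundance** from
bottom-up mass-spectrometry peptide data, with optional integration of
transcript abundances from RNA-seq.

## The problem

Bottom-up MS proteomics measures peptides, not proteins. Two sources of
technical noise make isoform-level inference hard:

* **Shared peptides** — because isoforms of a gene are highly similar in
  sequence, most detected peptides are compatible with several protein
  isoforms, and their abundance has to be divided among them.
* **Erroneous detections** — peptide identifications carry error
  estimates (an FDR / q-value and, per peptide, a posterior error
  probability, PEP) and some identifications are wrong.

Because of this, protein-level results are usually abstracted to genes
or protein groups. `isoinfer` instead performs inference for each
individual isoform, for users (proteomics / proteogenomics analysts)
who need isoform resolution, e.g. to study alternative splicing.

## The model

Let `Y_1..Y_N` be the abundances (PSM counts, or intensities rescaled
and rounded to integers) of the detected peptides, and `ψ_i` the set of
isoforms peptide `i` is compatible with. The latent per-isoform
abundances `X = (X_1..X_P)` split the total abundance `n` as

```
X | π ~ Multinomial(n, π),        π | δ ~ Dirichlet(δ)
```

`X` is recovered from the peptide data by data augmentation. Each Gibbs
sweep:

1. *(PEP mode only)* draws mis-detection indicators
   `ε_i ~ Bernoulli(PEP_i)`; a mis-detected peptide contributes nothing
   this sweep. In FDR mode, peptides are instead pre-filtered at a
   strict FDR cutoff (default 0.01) and `ε ≡ 0`.
2. allocates each retained peptide's abundance `Y_i(1−ε_i)` across
   `ψ_i` with a multinomial draw with probabilities
   `π̃_p ∝ (π_p / M_p) · 1(p ∈ ψ_i)`, where `M_p` is the number of
   detected peptides of isoform `p` (dividing by `M_p` normalizes for
   how many peptides feed each isoform); summing allocations gives `x`.
3. draws `π` from the conjugate posterior `Dirichlet(x + δ)`.

The prior is `δ = (1,…,1)` by default; when transcript abundances are
supplied, `δ` is set proportional to the transcript relative abundances
`π^T` (informative prior), encoding that a shared peptide more likely
originates from the isoform with the more abundant mRNA.

From the posterior chains the tool reports, per isoform: the presence
probability `Pr(X_p > 0)`, posterior-mean abundances with 0.95
highest-posterior-density (HPD) credible intervals, gene-level
aggregates, and — with transcript data — the stabilized fold change
`log2((π_p+κ)/(π_p^T+κ))` (κ = 1.5e−6) and `Pr(π_p > π_p^T)`.

## Worked example

```python
import numpy as np
from isoinfer import (make_random_truth, simulate_peptides,
                      ProteinIsoformModel, evaluate_run)

rng = np.random.default_rng(42)
truth = make_random_truth(n_isoforms=50, rng=rng)   # known ground truth
dataset = simulate_peptides(truth, rng=rng)         # peptide-level data
model = ProteinIsoformModel(dataset, seed=42)       # mRNA attached -> informative prior
res = model.fit()                                   # 2000 sweeps, 1000 burn-in
print(res.summary(max_rows=6))
```

```
Protein isoform inference (Dirichlet-multinomial Gibbs sampler)
================================================================
mode: fdr    prior: mRNA-informative
peptides: 250 in, 250 after filtering
isoforms analyzed: 50 in 1 independent blocks
iterations: 2000 (1000 burn-in), seed 42
credible level: 0.95 (HPD)

isoform_id  prob_present  abundance_mean  abundance_ci_lo  abundance_ci_hi  rel_abundance_mean  log2_fc  prob_protein_higher
   iso0001         0.018           0.024                0                0           0.0001079   -2.589                0.036
   iso0002             1           5.174                1               13              0.0111    2.318                0.861
   iso0003             1           22.86               15               30             0.05002    1.506                0.999
   iso0004         0.195           0.807                0                6            0.001774    1.138                0.208
   iso0005             1           17.26                7               27             0.03811   0.9364                0.896
   iso0006         0.911           5.627                0               10             0.01253   0.7181                0.706
... 44 more isoforms
```

`prob_present` is the posterior probability that the isoform is present
(`iso0001` is almost surely absent, `iso0003` surely present);
`abundance_mean` with the CI columns estimates its PSM-count-scale
abundance; `log2_fc` and `prob_protein_higher` compare the protein
relative abundance with its transcript counterpart (`iso0003`'s protein
share is almost certainly above its mRNA share).

Scoring the fit against the simulation truth:

```python
rep = evaluate_run(res.isoform_table, truth)
```

prints `AUC: 0.919 | log10-corr: 0.903 | 0.95-CI coverage: 0.94 |
mean abundance present/absent: 12.45 / 0.29` — presence calls separate
present from absent isoforms well, estimated abundances track the truth
on the log10 scale, and the credible intervals are close to nominal.

The same workflow is available from the shell:

```bash
isoinfer simulate --n-isoforms 200 --seed 1 --out sim/
isoinfer run --peptides sim/peptides.tsv --mrna sim/transcripts.tsv \
             --genes sim/genes.tsv --seed 1 --out fit/
isoinfer evaluate --results fit/isoforms.tsv --truth sim/truth.tsv --out eval/
```

`run` accepts any TSV with peptide id, abundance, FDR, optional PEP and
a `;`-separated isoform list (column names remappable via
`--config`/flags), so exports from MetaMorpheus-, Percolator- or
MaxQuant-style pipelines can be used after conversion to this contract.
Outputs are an isoform-level TSV, a gene-level TSV and a JSON run
manifest; a given seed reproduces them byte for byte.

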