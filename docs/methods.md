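# Methods

## Model

For each gene, pseudobulk counts `y_k` in cell type `k` are modeled with a
two-group Poisson–Gamma compound: all samples within one condition group
share a Poisson mean `λ`, and `λ ~ Gamma(α, rate β)`. Integrating `λ` gives
the group marginal in closed form (log-gamma arithmetic throughout, so the
likelihood is finite for counts up to at least 1e6). Under the EE state all
`m+n` samples form one group; under the DE state the two condition groups
get independent `λ`s. One `θ = (α, β)` is shared across all K cell types
and both states of a gene — there is no pooling across genes, and no
shrinkage. This is deliberate: `θ` is a per-gene nuisance describing
between-sample variability, and the state posterior is driven by the
likelihood *ratio* between pooled and split groupings, which is far less
sensitive to `θ` error than `θ` itself. A consequence worth knowing: with
K = 6 cell types a gene's data contain at most ~2K latent-rate draws, so
per-gene `θ` estimates are noisy and upward-biased in the shape. They are
consistent as information grows (verified in the test suite on a K=600
instance); treat the per-gene values as internal quantities, not as
dispersion estimates.

The latent DE/EE vector `x` follows a pairwise-interaction MRF on the
cell-type network: `log p(x) = γ·n1 − β_mrf·n01 + const`. Only the
difference of the DE and EE singleton potentials is identifiable, so the EE
potential is fixed at zero and `γ` alone is stored. The full conditional of
node k is logistic with field `F = γ + β_mrf·Σ_{k'∈N_k}(2x_{k'}−1)`. The
`+` coupling sign is the one consistent with the joint (checked exhaustively
by enumeration in the tests) and makes `β_mrf ≥ 0` a smoothing penalty on
discordant neighbors; `mrf.local_field(..., sign="anti")` exposes the
opposite-sign variant for comparison only.

## Inference

Per gene, ICM alternates: (i) L-BFGS-B maximum likelihood for `θ` in
(log α, log β) with box `[1e−6, 1e6]`, moment-matching start
(`β₀ = μ/(v−μ)` if `v > μ` else 1, `α₀ = μβ₀`), objective tolerance ~1e−12,
analytic gradients; the fit never returns a point below the start
(explicit ascent guard). (ii) Pseudolikelihood (coding-method) fit of
`Φ = (γ, β_mrf)` over the box `[−20, 20] × [0, 20]`; the objective is
concave, so the box-constrained optimum is global. Constant state vectors
(all EE / all DE) pin `γ` to a boundary and are flagged degenerate — the
box doubles as regularization, since a single K-vector carries little
information about `Φ`. (iii) One ICM sweep in fixed ascending cell-type
order, setting `x_k = argmax log f(y_k|x_k; θ) + log p(x_k|rest; Φ)`, ties
broken toward EE (conservative under the null). The loop stops when a full
iteration leaves the states unchanged, capped at 20 outer iterations
(every benchmark gene converges well before the cap). Each coordinate
update cannot decrease the joint objective; the tests audit this on every
run. All-zero genes are degenerate: forced all-EE with sentinel
`θ = (1, 1)` and excluded from calling and from benchmark denominators.

Initialization accepts (a) any external DE table (per cell type, BH
adjustment across genes — "local" correction — then adjusted p < 0.05 and
|logFC| above threshold), (b) the built-in initializer: an exact two-sided
binomial test of the condition-1 count share against m/(m+n), conditioning
on each (gene, cell type) total, thresholded the same way, or (c) seeded
random Bernoulli(0.5) states for robustness checks.

## Calling

logFC is `log2((mean₂+ε)/(mean₁+ε))` of CPM-normalized pseudobulk (each
(cell type, sample) column scaled to 1e6; ε = 1 by default). CPM was chosen
so per-sample library factors cancel and values are comparable with
standard count-model outputs; both the pseudocount and the scale are
configurable. A final call requires state 1 and |logFC| above the
threshold; no p-value enters the call, because the model's output is a
state, not a test statistic. Real-data mode adds a minimum-expression
filter: mean CPM of the (gene, cell type) must exceed the 40th percentile
(configurable) of all pooled gene × cell-type mean-CPM values.

## Simulator

The generator emulates a multi-sample, multi-cell-type experiment.
Network: exactly `round(connectivity·K(K−1)/2)` pairs chosen uniformly
(fixed edge count rather than independent coin flips, so every replicate
has the same connectivity). Truth: per gene, 5 Gibbs sweeps from a
Bernoulli(0.5) start at `Φ_true = (−10, 11)` — a deliberately short,
non-stationary chain whose strong smoothing leaves mostly-EE genes with
network-coherent DE clusters. Counts: per-cell NB mean
`exp(gene effect + cell-type effect) × sample factor`, with gene effects
`N(−1.5, 1)`, cell-type effects `N(0, 0.5)`, sample biological factors
`LogNormal(0, 0.15)`, library factors `LogNormal(0, 0.2)` and per-cell NB
dispersions `LogNormal(0, 0.5)` — values picked once as a realistic
stand-in for a reference-data fit (median per-cell mean ~0.2, sample CVs
~15–25%, dispersions centred at 1) and exposed in `NBReference`. DE
(gene, cell type) pairs draw |log2 FC| ~ Gamma(shape 4, rate 4/τ) (mean τ),
an independent up/down sign, and a uniformly chosen condition whose mean is
multiplied by `2^{±δ}`. Fast mode samples pseudobulk directly using the
NB summation identity (sum of `n_c` iid NB(μ, 1/φ) is NB(n_c·μ, n_c/φ));
cells mode emits the full cell-level matrix with per-cell library factors,
and its aggregated pseudobulk is distributionally equivalent to fast mode.

What the simulator does **not** emulate: zero inflation beyond NB,
cell-type composition shifts between conditions, batch effects, gene–gene
correlation, or unequal cell numbers per sample. Passing benchmarks
therefore demonstrate correct inference under the generative model's
assumptions, not robustness to those artifacts.

## Benchmark

Three scenario grids vary cells per type (100–1000), samples per condition
(3–12) and mean logFC τ (1.2–3.8); grid spacing is uniform (the design
fixes only the endpoints) and configurable. Full scale is 1000 genes × 50
replicates; reduced mode (300 genes, 5 replicates, 3 grid points) is the
default for tests and the acceptance script — chosen as the smallest design
that keeps replicate-level FDR/sensitivity estimates stable at the
(gene × cell type) resolution of 1800 units per replicate. Arms: the
binomial initializer alone (BH p < 0.05 and |logFC| > τ/2), the MRF model
from that initializer, and the MRF model from random states (all arms share
each replicate's data; calls for the model arms use the |logFC| > τ/2
threshold only). Metrics are confusion counts at (gene, cell type)
resolution with degenerate genes excluded symmetrically; FDR uses a guarded
denominator (`FP/max(1, TP+FP)`), so an empty call set has FDR 0.

## Numerical and degenerate-input choices

- Likelihoods and MRF conditionals in log space end to end; no factorials.
- Empty (cell type, sample) pseudobulk groups: zero columns plus a logged
  warning, so incomplete designs still run.
- Counts must be integral; normalized matrices are rejected at the door.
- Pseudobulk sample order is condition-1 block first, lexicographic within
  condition; all tensors and tables follow that order.
- Seeds: every stochastic entry point takes a seed or a Generator; the
  benchmark spawns per-replicate substreams from the master seed so arms
  share data and tables reproduce byte-identically.

## Known limitations

- No library-size offsets in the likelihood: the Poisson–Gamma model as
  formulated assumes a common mean per condition group, so systematic depth
  differences between samples load onto the Gamma dispersion instead. CPM
  is applied in the logFC, not in the model. A pre-scaling flag is the
  escape hatch if depth imbalance is severe.
- Per-gene `Φ` from a single K-vector is weakly identified; bounds act as
  the prior.
- Binary states only: no up/down distinction, no gene–gene network, no
  edge weights.
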