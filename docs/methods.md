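# Methods

## The zonation screen

The single-cell input is a genes × cells UMI matrix plus a cells × L
matrix of layer-membership probabilities over L ordered lobule layers
(layer 1 most pericentral, layer L most periportal); the probabilities are
taken as given, not inferred. The screen:

1. **Expression filter.** A gene is "expressed" in a cell when its count
   is ≥ 1; genes expressed in fewer than `min_cells` (default 15) cells
   are dropped. The count-≥-1 reading is the simplest definition and the
   only one that needs no extra threshold.
2. **Normalisation.** Median-of-ratios size factors: the reference profile
   is the per-gene geometric mean over cells, computed on genes with
   nonzero counts in every cell; each cell's factor is the median of its
   count ratios to the reference, rescaled so factors have geometric
   mean 1. On very sparse matrices no gene may be ubiquitous; the code
   then falls back to total-count factors with a warning. Because the
   downstream trend test is rank-based within genes, only cross-cell
   scaling matters, so this deterministic estimator is sufficient and a
   pooling/deconvolution scheme would change nothing the test can see.
3. **Layer assignment.** Each cell goes to its maximum-probability layer;
   exact ties break to the lower (more pericentral) index, a deterministic
   rule chosen for reproducibility.
4. **Trend test.** Per gene, the Jonckheere–Terpstra statistic across the
   ordered occupied layers: U = Σ over ordered layer pairs a < b of
   #{x_a < x_b} + ½·#{x_a = x_b}. Exact mode computes the permutation null
   as the convolution of Mann–Whitney null distributions
   U(n_1+…+n_{i-1}, n_i) — valid for tie-free data; with ties or above the
   size cap (default total n = 20) the tie-corrected normal approximation
   is used (mean (N² − Σn_i²)/4 and the standard three-term tie-corrected
   variance). Real layered data (hundreds of cells per layer, many tied
   zero counts) always lands in the asymptotic branch; the exact branch
   exists for small samples and for oracle testing. p-values are
   two-sided (twice the smaller exact tail, capped at 1, or the two-sided
   normal tail): the screen classifies both increasing and decreasing
   genes, so a directional test would be incoherent. No continuity
   correction is applied; at the screen's operating sizes its effect is
   negligible, and the exact branch covers the small-sample regime.
5. **Calling.** BH-FDR over all genes surviving the filter; at
   q ≤ `fdr_threshold` (default 0.001), z > 0 → periportal, z < 0 →
   pericentral.

**Consensus sets.** Gene symbols are first harmonised through a
one-column-to-one-column alias table. A gene enters the consensus set of
a direction when ≥ `min_studies` (default 2) studies report it with that
direction. Genes qualifying in both directions across studies are
excluded from both sets and logged; cross-study discordance is evidence
against a clean zonation label.

## Differential expression

Bulk counts are TMM-normalised: the reference sample is the one whose
upper quartile of depth-scaled counts is closest to the mean upper
quartile; per sample, M- and A-values against the reference (genes
positive in both) are doubly trimmed (30% on M, 5% on A, rank-based) and
the scale factor is the 2^(weighted mean of M) with inverse
asymptotic-variance weights (1/y − 1/N terms), rescaled to geometric
mean 1. This implementation agrees with the standard implementation to
seven significant digits on random count matrices. Expression is
log2-CPM with a 0.5 pseudocount **on the CPM scale**
(log2(count/effective-library × 1e6 + 0.5)), which makes the transform
exactly invariant to pure depth rescaling of a sample; note the TMM
factors themselves are only near-invariant, since their precision
weights depend on absolute depth.

The design is a one-way layout over (treatment, month) groups; the fit is
ordinary least squares on group means with residual variance pooled over
real groups (df = samples − groups). The time course has no month-6 oil
group; its mean is imputed as the arithmetic mean of the month-2 and
month-12 oil group means, on the log2-CPM scale (imputation on the log
scale keeps it a plain average of the quantities actually contrasted).
The imputed group enters only the contrast mean — never the residual
pool — and the month-6 contrast's variance multiplier accounts for the
halved weights on the two donor groups
(√(1/n_c + ¼/n_o2 + ¼/n_o12)); this is the conservative treatment of an
imputed mean with no replicate scatter of its own.

Moderation: with per-gene s² on d df, the prior (d₀, s₀²) solves the
moment equations of e = log s² − ψ(d/2) + log(d/2) —
Var[e] = ψ′(d/2) + ψ′(d₀/2) and E[e] = log s₀² + log(d₀/2) − ψ(d₀/2) —
with the trigamma inverse found by bracketed root-finding. When the
empirical Var[e] does not exceed its pure-sampling value, d₀ = ∞ (full
shrinkage); exactly identical variances short-circuit to s₀² = that
value. The moderated t is logFC/(u·s̃) with
s̃² = (d₀s₀² + d·s²)/(d₀ + d) on d₀ + d df (standard normal at d₀ = ∞;
d₀ = 0 recovers the ordinary t). Voom-style precision weights are not
implemented; moderation is applied to log2-CPM directly. This leaves a
mild mean–variance trend unmodelled and costs a little calibration at
genes with extreme expression — the empirical FDR stays within its
nominal-times-two band on the synthetic designs tested, and the
enrichment readout is rank-based and insensitive to it.

DE thresholds: |logFC| ≥ 1.5 and FDR ≤ 0.05, boundaries inclusive; the
relaxed overlap analysis uses |logFC| ≥ 0.8, FDR ≤ 0.2 and unions the
per-month intersections with a zonation set across months 2–12.

## Enrichment

**GSEA.** Genes ranked by moderated t, descending, exact ties broken by
gene id. Walking the ranking, set members increment the running sum by
|t|^w (w = 1 by default, the classic weighted form; exposed because the
convention varies) normalised over member weights; non-members decrement
uniformly. ES is the running-sum value of maximal |deviation|; on the
degenerate all-zero-statistic signature the weights fall back to
unweighted. The null is gene-set permutation: random same-size sets drawn
from the signature (sample permutation is impossible on a single
contrast). The p-value is one-tailed on the observed ES sign,
(1 + b)/(1 + m) with b the same-sign null ES at least as extreme and m
the same-sign null count — this denominator makes the null p uniform,
which the test suite verifies by KS test. NES = ES / mean(|null ES| of
matching sign). No adaptive tail approximation is used, so p is floored
at 1/(1 + m); at the default 100,000 permutations the floor is ~2e-5.
The leading edge is the set members at ranks up to (positive ES) or from
(negative ES) the running-sum peak. Set members absent from the
signature are dropped with a logged count. The two zonation sets per
signature are reported without cross-set adjustment.

**ORA.** One-sided (enrichment) Fisher exact test of the 2×2 table
(k, n−k; K−k, N−n−K+k) against a fixed background universe, default
N = 20,000 (a typical mouse transcriptome size). The odds ratio gets a
0.5 continuity correction only when a cell is zero, and the result is
flagged.

**Footprint pathway scores.** raw = Σ w_g·t_g over the model genes
present in the signature; z standardises raw against a null that permutes
the gene-to-statistic assignment (statistics drawn without replacement).
Under an i.i.d. normal signature z is standard normal, which the suite
checks by simulation.

**Regulon activity.** Statistics are rank-transformed to normal quantiles
Φ⁻¹(rank/(N+1)); a TF's NES is the mode-signed sum of its targets'
quantiles over √(targets present). This is a deliberate rank-based
simplification of the full interaction-confidence-weighted,
multi-tailed enrichment machinery: no likelihood weights, no two-tail
blending, no pleiotropy correction. It preserves the property the
pipeline needs — a signed, size-normalised activity score that is exactly
antisymmetric under signature negation.

## The synthetic generators

The generators define the study conditions the tests and the acceptance
script run under; they are first-class, tested code.

* **Counts** are negative binomial with var = μ + φμ² via the
  gamma–Poisson mixture, one global φ (default 0.1, i.e. ~32% biological
  CV — typical for between-mouse bulk variability and a reasonable
  mid-range for UMI overdispersion); φ = 0 gives Poisson. Per-cell /
  per-sample depth factors are log-normal (σ = 0.3 by default) to
  exercise normalisation.
* **Single cell** (defaults: 1415 cells, 9 layers — the size of the
  layered hepatocyte reference dataset): true layers are uniform over
  layers; membership rows are Dirichlet with α = 0.3 everywhere plus a
  concentration (default 15) on the true layer, so rows sum to 1 and the
  arg-max recovers the truth with high probability. The source study
  publishes such probabilities but no generative recipe, so the sharpness
  is an exposed placeholder, as is the UMI-depth scale (gene baselines
  log-normal around 0.5 counts/cell). Zonated profiles are geometric —
  a constant log2 step per layer summing to `profile_amplitude` (default
  2) across the axis — which guarantees the strict monotonicity the
  trend screen targets; 5% of genes are planted per direction.
* **Bulk**: groups untreated-m0, oil-m2, oil-m12, ccl4-m2/6/12 with 6
  replicates each (36 samples); oil and untreated means equal the gene
  baseline (no solvent effect is planted, making the month-6 imputation
  unbiased by construction — a planted solvent drift would bias the
  imputed mean and is deliberately out of scope). Planted ccl4-vs-oil
  effects default to pericentral −1.5/−2/−3 log2 at months 2/6/12 and
  periportal +2/+1.5/0: deepening pericentral loss and transient
  periportal gain, the fibrosis pattern the pipeline is built to detect.
* **Study sets**: each study reports each truly zonated gene with
  probability `sensitivity` in its true direction and each null gene with
  probability `fpr` in a random direction — a minimal model of
  independent studies with imperfect, partly discordant calls.

What the generators do **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation, mean-dependent dispersion, library
composition bias, or solvent/aging drift. Passing tests therefore show
that the algorithms are correct and well-calibrated under the stated
stochastic model, not that real data meet that model.

## Numerical choices and degenerate inputs

* Probability rows must sum to 1 within 1e-6 (inputs) / 1e-9 (generator
  outputs); violations raise with the offending cell named.
* Zero-total cells/samples are an error naming the column; all-zero
  filter results warn rather than raise.
* The exact JT null is computed in float64 probability space; convolution
  round-off is ~1e-15, and the suite verifies 1e-12 agreement with exact
  enumeration.
* Trigamma inversion uses bracket expansion plus Brent's method at 1e-12
  tolerance.
* All stochastic operations take explicit integer seeds and flow through
  a single `numpy.random.Generator`; identical (config, seed) runs are
  byte-identical, which the pipeline test verifies by hashing every
  artifact.
* Pipeline intermediates are plain TSV/GMT so any stage can be swapped
  against external tools.

## Problem sizes

The test suite and the acceptance script run at deliberately modest
sizes chosen to exercise every code path at full statistical fidelity:
trend-screen recovery at the reference scale (1415 cells × 1000 genes),
the end-to-end fibrosis run at 1500 genes and 10,000 GSEA permutations,
null-calibration sweeps at 2000 draws × 500 permutations. Production
runs use the same code with larger `n_perm` (default 100,000).

## Known limitations

* The moderated-t model is unweighted log2-CPM; strongly heteroscedastic
  count data would benefit from precision weights the pipeline does not
  implement.
* The regulon score is the simplified rank-based form described above.
* The exact JT branch requires tie-free data; tied data always use the
  asymptotic approximation, whose two-sided p can deviate from the exact
  value by a few percent deep in the null at small n (it agrees within
  0.02 when a moderate trend is present).
* Consensus construction takes per-study sets as given; re-deriving layer
  probabilities from landmark genes, and any sex-stratified merging of
  source lists, are upstream choices left to the caller (a union is the
  natural default for merging "common" and sex-specific lists).
* The ±1e-6-level depth invariance of log2-CPM holds at fixed scale
  factors; the TMM factors themselves shift by ~1% under 4× depth change
  because their precision weights see absolute counts.
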