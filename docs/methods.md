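# Methods

## Scope and model

`splitrootseq` analyses genes × samples fragment-count matrices from a
split-root nutrient-resupply design. The statistical core is three layers:
a negative-binomial (NB) model for counts, a two-group Wald test with the
DEG rule |fold change| ≥ 2 ∧ p < 0.05 ∧ FDR < 0.01, and deterministic set
algebra over the resulting DEG sets that assigns each deficiency-responsive
gene a recovery label. Everything downstream of a count matrix is in scope;
read processing, alignment and transcript assembly are not — the count
matrix is the interface.

Counts are modelled as NB(μ, σ²) with σ² = μ + φμ², where φ ≥ 0 is the
dispersion; φ = 0 degenerates to Poisson. The same parameterisation is used
by the simulator and the test, so simulation-based checks exercise exactly
the model the test assumes — a deliberate choice that makes calibration
claims sharp but means passing tests certify internal consistency, not
robustness to model misspecification (see Limitations).

## Synthetic data generator

The generator emulates the nine-group design (shoots CK_Sh, S0_Sh, SR_Sh,
SP_Sh; roots CK_R, S0_R, SR_R, SPSR_R, SPS0_R; default 3 replicates,
default 37,344 genes — the transcript count detected in the rice experiment
this design mirrors). Each gene receives:

- a baseline mean, log-uniform on `base_mean_log_range`
  (default 10^0.5–10^3.5 — spans low to high expressors without heavy
  tails);
- a planted class: `background`, or direction (up/down) × response class
  (local / systemic / both / none / unrecovered). Class counts are
  `round(n_genes × proportion)` with the rounding remainder absorbed by the
  background class. Default proportions plant 12% responders with
  both/none/unrecovered outnumbering local, and systemic rarest — the
  qualitative ordering split-root studies report. No published effect-size
  or dispersion estimates exist for this design, so the defaults
  (Δ = |log2FC| = 3, φ = 0.1, library-size CV = 0.1) are the package's own
  choices of a strong deficiency response, moderately noisy bulk RNA-seq
  and well-matched libraries; they are stated here once and used as the
  standard study conditions throughout the tests.
- one tissue (root with probability 1 − `shoot_fraction`, default
  `shoot_fraction` = 0.2, roughly the shoot share of responsive genes in
  such experiments). A planted gene expresses its pattern only in its own
  tissue's groups.

Group means are baseline × pattern factor × per-sample library factor
(log-normal with the given CV, renormalised to geometric mean 1). For an up
gene with effect Δ the deficient factor is 2^Δ and recovery returns a group
to 1: S0 is always 2^Δ, SR always 1 (except `unrecovered`, which stays at
2^Δ everywhere), and the split halves encode the class (local: SPSR 1,
SPS0 2^Δ; systemic: the mirror; both: both 1; none: both 2^Δ). Down genes
use 2^−Δ. In shoots there is a single heterogeneous-resupply group, SP_Sh;
a shoot gene recovers there iff its class is `systemic` or `both`, on the
reasoning that shoot recovery under partial resupply requires the
shoot-relayed signal, while `local` and `none` classes map to
homogeneous-only recovery. `expected_shoot_label` exposes this mapping.

What the generator does **not** emulate: tissue-common responders (each
gene responds in one tissue), batch effects beyond library size, gene–gene
correlation, length-dependent counting bias, or dispersion that varies with
expression. Pipeline recovery rates measured on it are therefore
best-case figures for data matching the NB model, not predictions for real
libraries.

## FPKM and replicate QC

FPKM[g,s] = counts[g,s] / ((length_bp[g]/10³) × (total[s]/10⁶)) with
total[s] the column sum of the supplied matrix — the only mapped-fragment
total available once alignment is out of scope; with an external mapped
count the values would shift by a constant per-sample factor. Replicate QC
reports pairwise Pearson correlation of log₁₀(FPKM + 1) within each group
(pseudocount 1 stabilises the variance of low expressors); constant vectors
yield a missing value rather than an error. Full PCA is intentionally
omitted: the correlation summary covers the replicate-agreement question
the pipeline needs answered.

## Differential expression

Per contrast (groups A vs baseline B, named "A/B"):

1. **Size factors** — median-of-ratios over genes observed in every sample
   of the contrast, rescaled to geometric mean 1; if no gene is observed
   everywhere, column-sum ratios are used (logged).
2. **Dispersion** — per gene, the moment estimate
   φ_mom = (s² − m̄)/m̄² from the pooled within-group variance s²
   (n_A + n_B − 2 df) and the pooled mean m̄ of normalised counts. The
   working dispersion is φ̂ = max(0, w·φ̄ + (1−w)·φ_mom) with φ̄ the plain
   across-gene mean of the (unclamped) φ_mom and shrinkage weight
   **w = 1 by default**, i.e. a common dispersion.

   Why full pooling: at n = 3 the per-gene estimate carries ~4 df. Feeding
   it into a normal-reference Wald statistic at any non-trivial weight
   inflates the type-I error well above nominal, while switching to a
   t-reference with the residual df overcorrects into conservatism.
   Equally important, φ̄ must be the *plain* mean: clamping negative moment
   estimates at zero or trimming the right-skewed distribution before
   averaging biases the common dispersion down and understates every
   standard error. With the unclamped mean the test sits at its nominal
   level — the acceptance script recomputes the empirical type-I error
   (fraction of null p-values below 0.05 on a 5,000-gene all-background
   simulation) on every run, and the test suite asserts it lies in
   [0.04, 0.06]. The weight is exposed for designs with enough replicates
   to make per-gene dispersion informative, with the caveat that
   calibration was only verified at w = 1. Under gene-varying dispersion
   the common-φ test is anticonservative for high-dispersion genes — the
   main robustness cost of this choice.
3. **Wald test** — log2fc = log2((m̄_A + ½)/(m̄_B + ½)) (pseudocount ½
   avoids division by zero and tempers low-count fold changes);
   SE² = (1/ln 2)² [v_A/(n_A μ_A²) + v_B/(n_B μ_B²)] with v = μ + φ̂μ²
   evaluated at μ = m̄ + ½ (delta-method variance of the log of a mean of
   NB draws); z = log2fc/SE against the standard normal. Genes with both
   means zero are untestable: log2fc = 0, p = 1.
4. **Multiple testing** — Benjamini–Hochberg step-up (statsmodels'
   `fdr_bh`). Genes with zero counts across every sample of the contrast
   are excluded from the BH denominator — they were never detected in that
   comparison — and carry FDR 1.
5. **Calling** — up: log2fc ≥ 1 ∧ p < 0.05 ∧ FDR < 0.01; down mirrored.
   The FDR cut-off is configurable (0.05 is a common alternative
   convention); p and FDR comparisons are strict, the fold-change bound
   inclusive.

## Recovery classification

"Recovered" means a *significant opposite-direction call* in the resupply
contrast — a strict set intersection, not a numeric move toward baseline.
This is the defining convention of the split-root set algebra and makes
class sizes sensitive to the DEG thresholds; a gene that drifts back 1.9×
without reaching significance counts as unrecovered. The whole-root
resupply contrast (SR/S0) is the gate: genes significant in a split-half
contrast but not in SR/S0 are labelled `unrecovered`. Within the gated set
R the four root classes A–D (up branch; E–H down) are the four cells of the
2×2 table (recovered in SPSR?) × (recovered in SPS0?), so {A,B,C,D}
partitions R by construction and swapping the SPSR/SPS0 inputs swaps
local ↔ systemic exactly — both are asserted in the test suite. Root and
shoot universes are independent; tissue-common deficiency DEGs are reported
separately as plain intersections. Percentages are rendered with half-up
decimal rounding at a caller-chosen precision while internal values stay
unrounded.

## Enrichment

One-sided hypergeometric over-representation: for a term annotating K of N
background genes and hitting k of an n-gene set, p = P(X ≥ k) via the
survival function. The annotation file defines the universe — term members
outside the declared background are dropped with a warning, and no GO-DAG
ancestor propagation is performed (terms are tested exactly as annotated).
BH runs within each category (BP/MF/CC/pathway) separately, mirroring the
convention of testing GO and pathway collections as separate families;
FDR ≤ 0.05 flags enrichment. Ties in top-N selection break
lexicographically by term id so reports are deterministic. The direction
score (up − down)/total annotates each term with the net direction of its
DEGs. Term–gene edge lists are emitted for network rendering elsewhere;
depletion, two-sided tests and topology-aware algorithms are out of scope.

## Pipeline, determinism and problem sizes

One TOML config (a `[simulate]` table or `[inputs]` paths, plus thresholds
and output settings) drives the run; every stage writes plain TSV/JSON and
the report contains only integers plus fractions recomputable from them.
All randomness flows from the design seed through `numpy` Generators, so a
config + seed pair reproduces byte-identical reports; the count stream is
seeded as `[seed, 1]` so truth planning and count drawing are independent
streams. Input validation distinguishes errors (missing gene lengths,
non-integer or negative counts, <2 replicates, sample-sheet mismatches)
from warnings (annotation genes absent from the counts, which are dropped).

The test suite and acceptance script use deliberately scaled problem sizes
— 250–10,000 genes rather than the full ~37,000 — chosen so the statistical
checks (type-I error on 5,000 null genes, class recovery on 10,000 planted
genes, 20-design partition sweeps) have tight Monte-Carlo error while the
whole suite runs in seconds. Rates at these sizes are representative;
nothing in the implementation scales worse than linearly in genes.

## Numerical choices and degenerate inputs

- Pseudocounts: ½ on group means (fold change and SE), 1 under the QC log
  transform.
- φ estimates clamped at 0 only at the final step; raw per-gene values are
  reported clamped, the common mean is computed unclamped (see above).
- Correlation of a constant replicate vector is reported as NaN, and the
  QC summary ignores NaNs.
- All-zero genes: excluded from the BH universe per contrast; untestable
  in the dispersion step (they take φ̄) and null in the Wald step.
- Empty DEG sets propagate cleanly: classifier outputs empty label tables,
  enrichment of an empty set is skipped with a zero-count report entry.
- Hypergeometric instances are validated (k ≤ min(K, n), K, n ≤ N) before
  calling the survival function.

## Known limitations

- The DE test is a two-group comparison only — no covariates, no GLM, no
  independent filtering; it is isolated behind the per-contrast results
  table so a different engine can be substituted.
- Common dispersion by default (rationale above): per-gene dispersion
  variation in real data would make the test anticonservative for the
  noisiest genes.
- The simulator's idealisations (single-tissue responders, no batch
  structure, constant φ) mean measured recovery rates are upper bounds for
  real data.
- FPKM totals come from the count matrix itself, not an external
  mapped-read total.
- The classifier inherits threshold sensitivity from the DEG rule: class
  membership is a statement about significance calls, not effect sizes.
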