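# Methods

This note records the models implemented in `turnoverkit`, their assumptions,
the numerical choices behind them, what the synthetic cohort generator does
and does not emulate, and the known limitations.

## Isotopologue envelope model

We work in heavy-leucine-count space: a peptide with `L` leucines has `L + 1`
isotopologue channels `m = 0..L`, each channel separated by 3.0188325 Da (the
²H₃-leucine mass shift). The observed envelope is modeled as the two-component
mixture

    P(m | f, p) = (1 − f)·[m = 0] + f·Binom(m; L, p),

with `f` the fraction of the peptide pool synthesized after the diet switch
and `p` the precursor-pool enrichment. The assumptions are: (i) leucine
incorporation events are independent across the `L` positions with a common
per-position probability `p`; (ii) pre-existing protein carries no label;
(iii) the natural ¹³C fine structure has been collapsed upstream during
envelope integration, so channels are purely heavy-leucine counts. Assumption
(iii) trades fidelity to raw spectra for a clean identifiable two-parameter
model; the package deliberately starts downstream of spectral processing.
Because the turnover-score and mixture formulas are our own reconstruction of
a deconvolution approach that is described only qualitatively in the
turnover-proteomics literature, numeric parity with any specific external
tool (e.g. Topograph) is not claimed.

## Fitting, identifiability and numerics

Envelopes are normalized to unit sum; negative areas are rejected at parse
time, all-zero envelopes are errors. The model is linear in `f` at fixed `p`,
so `f` is profiled in closed form, `f*(p) = clip(⟨a − e₀, b(p) − e₀⟩ /
‖b(p) − e₀‖², 0, 1)`, and the remaining 1-D problem in `p` is solved on a
401-point grid followed by bounded Brent refinement (`xatol` 1e-12). The
degenerate grid point `p = 0` (where the design vector vanishes) is handled
explicitly. With a single leucine (`L = 1`) the pair (f, p) is not jointly
identifiable — only the product matters — so single-leucine peptides are
deconvolved at a fixed enrichment. Near `p → 0` the objective is flat along
the ridge `f·p ≈ const` for any `L`; the optimum is still unique but
discretized comparisons (grid oracles) can wander a cell or two along the
ridge, which is why oracle-equivalence tests propagate the grid resolution
through the local ridge slope `df/dp ≈ f/p`.

Pool enrichment is estimated **per sample** (not per peptide, not globally):
the total residual sum of squares over all of a sample's multi-leucine
envelopes is minimized in `p` with every envelope's `f` profiled out. A
per-sample estimate matches how animals actually differ (each animal has its
own dietary history) while borrowing strength across peptides; per-peptide
estimates are far noisier and a global estimate would mask animal effects.
Single-leucine peptides are then deconvolved at their sample's estimate.

## Turnover score and quality filter

The turnover score is the cosine similarity between the observed envelope and
the best-fitting theoretical envelope. Cosine is scale-invariant (peak areas
are arbitrary units) and reaches 1 exactly at proportionality. Peptides with
score < 0.98 are removed by default. The cutoff can be re-derived from data:
each peptide is labeled true-positive if its own free-(f, p) enrichment
estimate lies within 2 SD of the mean enrichment over all peptides, a ROC is
swept over observed scores, and the threshold maximizing Youden's J is
returned (ties broken toward the more stringent cutoff). The 2-SD labeling
assumes well-behaved envelopes dominate the dataset; it degenerates (by
design, with an error) when all labels coincide.

## Turnover kinetics

Percent newly synthesized follows first-order kinetics,
`y(t) = 100 + β₁·e^(αt)` with `α < 0`, `β₁ ≤ 0`; complete labeling
corresponds to `β₁ = −100`. Fits use Levenberg–Marquardt with starts
`β₁ = −100`, `α = −ln2/median(day)`; non-convergence (or a fit violating the
sign constraints) is flagged rather than raised, and flagged fits are
excluded from medians, normalization and comparisons. Half-life is
`t½ = ln(2)/|α|` — the dimensionally consistent reading of "half-life from
the slope" under first-order kinetics.

Group comparisons linearize the model: `z = ln(100 − y)` is linear in `t`
with slope `α`, so slope equality is tested by ANCOVA,
`z ~ peptide_block + day + group + day×group`, with the day×group interaction
as the test of interest. Peptide identity enters as a fixed blocking factor
because peptides of one protein differ systematically in ionization and
digestion efficiency. Observations at `y ≥ 100` (possible under noise) are
clipped to 99.9 before the log transform and counted in the result so users
can audit; a group consisting entirely of clipped values is an error.
The null-calibration simulations draw measurement noise multiplicatively on
the unlabeled fraction `100 − y` (log-normal, CV 5%), i.e. additively on the
linearized response — the error structure under which the F-test is exact.
Under that model the type-I error at nominal 0.05 is 0.045–0.05 over 2000
replicates and the null p-value distribution is uniform to Kolmogorov
distance < 0.05 (both recomputed by the test suite).

Multiple testing uses Benjamini–Hochberg q-values; the selection threshold
for downstream steps is configurable between raw `p < 0.05` and `q < 0.05` —
the two conventions both appear in practice for heatmap/selection steps and
the package does not silently prefer one (pipeline default: p < 0.05).

## Abundance contrasts and partial correlation

Protein abundance is the sum of unique-peptide MS1 areas per sample (the
standard label-free roll-up); a peptide missing in a sample is absent from
the sum, not zero-imputed. Contrasts are `log2(mean(group A)/mean(group B))`
on the linear scale — log2 symmetrizes up/down regulation. Proteins with a
zero or missing group mean are dropped from that contrast and counted.

Two contrasts sharing a term (e.g. OWT/YWT and YmCAT/YWT share YWT) are
correlated even under independence — spurious correlation of ratios. We
report first-order partial correlations controlling the shared group's log
mean abundance, `r_xy·z = (r_xy − r_xz·r_yz)/√((1 − r_xz²)(1 − r_yz²))`,
with p-values from `t = r√((n−3)/(1−r²))` on `n − 3` df. Rank-based
(Spearman-flavored) is the default, making the result invariant to monotone
transforms of the inputs. The simulation in the test suite shows shared-
denominator ratios of independent log-normals with raw Spearman ≈ 0.5 and
partial correlation indistinguishable from 0 at n = 2000.

Per-pathway analysis computes Spearman correlations of two per-protein
statistics over each pathway's members (≥ 3 shared proteins required), plus
pooled statistics over the union of the top pathways; proteins appearing in
several top pathways enter the pooled set once by default (a flag enables
per-membership weighting). Pathway enrichment is the one-sided hypergeometric
upper tail within the user-supplied universe, BH-corrected across pathways —
a generic Fisher enrichment against GMT-style gene sets; no proprietary
pathway database is bundled. Heatmap orderings use agglomerative clustering
on Euclidean distances (complete linkage by default for protein maps, Ward
for pathway maps), with row-mean imputation of missing cells for the distance
computation only and optional row-mean centering.

## Aging-trajectory index

Over proteins selected as significantly changed with wild-type aging, with
`a_i = log2(OWT_i/YWT_i)` and `d_i = log2(G_i/YWT_i)`,

    index(G) = 100 · mean(sign(a_i)·d_i) / mean(|a_i|).

Computing the projection in log space is the only choice under which "same
direction as aging" and "opposite direction" are symmetric around zero; the
wild-type aging magnitude is additionally reported on the linear scale as
mean(max(r, 1/r)) because fold-change magnitudes are conventionally quoted
linearly. The index is exactly 0 for YWT and 100 for OWT on any selection
with a non-degenerate aging effect, and is linear in log-space interpolation
between the two (a group at `YWT + λ(OWT − YWT)` in log space scores 100λ).
Proteins with an undefined ratio in any compared group are dropped from all
groups to keep the sets comparable.

## Synthetic cohort generator

The generator defines the study conditions used by every simulation-based
test:

- design: groups YWT/OWT/YmCAT/OmCAT × days 3/7/12/17 × 3 animals = 48
  samples, cross-sectional (each animal one time point);
- group median half-lives default to the heart values 6.43/5.37/4.86/7.71
  days; per-protein half-lives are log-normal around the group median with
  log-SD 0.45, chosen to give the right-skewed half-life spread seen in
  turnover datasets;
- pool enrichment defaults to a constant plateau of 0.5 per sample —
  the dietary label replaces leucine completely but is diluted roughly
  half-and-half by recycled unlabeled leucine; a saturating rise
  `p(t) = plateau·(1 − e^(−rt))` is available (rate 0 = constant);
- peptides: 2–4 per protein, 1–6 leucines, log-normal ionization factors;
- noise: multiplicative log-normal per envelope channel, CV 5% by default;
- missingness: completely at random, 5% by default;
- abundance matrix: log-normal baselines; 30% of proteins form the aging
  subset with signed log2 shifts in OWT scaled so the mean absolute linear
  fold change is 5.66; the young and old transgenic groups receive λ_young
  and λ_old times the same shift (defaults 1 and 0 — the pattern in which
  the young transgenic proteome looks aged and the old one young);
  per-sample log2 noise SD 0.25.

What it does **not** emulate: chromatographic peak shape and integration
error, retention-time drift, natural-isotope envelopes, chimeric spectra,
intensity-dependent missingness, correlated peptide noise within a protein,
shared peptides between proteins, and biological covariance structure across
proteins. Passing tests therefore demonstrate that the estimators recover
truth under the stated generative model at realistic noise — not that every
real-data artifact is handled.

## Problem sizes and determinism

Simulation-based checks use: 200–500 proteins for half-life recovery and
median-ordering runs (the ordering check averages recovered medians over 5
seeds), 2000 replicates for ANCOVA calibration, n = 2000 for the
spurious-correlation demonstration, and exhaustive enumeration to universe
size 50 for the enrichment oracle. All randomness flows through
`numpy.random.default_rng` seeds; identical (config, seed) pairs produce
byte-identical cohorts.

## Known limitations

- Two-pool or delayed label-uptake kinetics, mixed-effects and Bayesian
  models are out of scope; one first-order pool per protein per group.
- Peptide→protein assignment is exact substring matching with a two-tier
  uniqueness rule (curated tier first, then secondary); shared peptides are
  discarded, not grouped. I/L equivalence is off by default (a flag enables
  it).
- The ANCOVA blocking factor is a fixed effect; with very many peptides per
  protein a random-effects formulation would be more efficient.
- Abundance quantification is relative only; no absolute (iBAQ-style)
  estimates.
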