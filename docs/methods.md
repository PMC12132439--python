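# Methods

## Problem and model

Deep mutational scanning (DMS) experiments measure a functional score for
thousands of single amino-acid substitutions in a protein, but real variant
effect maps are incomplete: assay dropout and coverage limits leave many
cells of the positions × substitutions matrix unmeasured. `dmsfill` treats
map completion as supervised regression. Each variant is described by a
feature vector combining evolutionary, biochemical, sequence-contextual and
position-aware information, and a gradient-boosted regression-tree ensemble
(LightGBM) is trained on observed variants to predict the normalized score
of unobserved ones.

### Score normalization

Raw assay scores are rescaled against two per-protein anchors — the
study-determined wild-type score `s_wt` and the nonsense (loss-of-function)
baseline `s_nons`:

    s_norm = (s_raw − s_wt) / (s_wt − s_nons) + 1

so wild-type-like variants sit near 1 and fully damaging variants near 0.
The transform is affine and invertible and does not clip: hyperstable
variants or scoring artifacts legitimately land above 1 or below 0 and are
preserved. The nonsense baseline is aggregated over a protein's nonsense
variants with a configurable statistic (`mean`, the default, or `median`);
study-supplied baselines on the domain entry always take precedence over
re-estimation. There is no fallback for a missing wild-type anchor — it is
an error, because every downstream quantity is expressed relative to it.

### Positional tolerance priors

The mean normalized score of the observed variants at a (protein, position)
is a strong data-driven prior for site-specific mutational tolerance
(`mean_dms`). A shrinkage variant (`jse_dms`) pulls each position mean
toward the protein-wide mean with a count-weighted James–Stein-style form

    prior(P, pos) = (n · m_pos + λ · m_P) / (n + λ),    λ ≥ 0, default 1

which reduces to the plain mean at λ = 0 and converges to it as the
per-position observation count n grows. At prediction time a position with
no training-visible observation falls back to the protein-wide mean of the
prior's source scope, then to the global training mean; lookups record
whether a fallback was used.

**Leakage policy.** Priors are always computed from training-visible
observations only. For strategies that split within a protein (random,
position-held-out, variant-held-out, SNV, masking) this means train-side
records only. For whole-protein holdouts the held-out protein has no
training-side records at all; there the prior is computed from the held-out
protein's own observed variants and every report is flagged
`within_protein_prior`. This is the imputation regime — you have measured
part of a protein's map and want the rest — and is deliberately distinct
from zero-shot evaluation, which refuses prior-bearing feature sets
outright.

### Feature groups

- **Substitution matrices (`sm` / `top5sm`)** — one column per matrix,
  `M[wt, var]` with symmetrized lookup. The roster is the 24 protein
  matrices shipped with Biopython (BLOSUM/PAM/Gonnet/Benner/Dayhoff/…)
  plus the Grantham distance matrix shipped as package data, 25 in all;
  the five-matrix subset is {blosum62, blosum80, blosum90, grantham,
  gonnet1992}.
- **Physicochemical properties (`pc`)** — molecular weight, isoelectric
  point, backbone pKa values, Kyte–Doolittle hydropathy and residue volume
  for the wild-type and variant residue, each with the absolute difference
  `|p_wt − p_var|`; boolean descriptors (side-chain hydrogen-bonding
  capability, buried/exposed tendency) as 0/1 with the same triple; and
  one-hot encodings of categorical descriptors (chemical group, charge
  class, polarity) for both residues. Values are a documented CSV shipped
  with the package.
- **SNV indicator (`snv`)** — 1 if any codon of the wild-type residue can
  reach any codon of the variant residue by a single nucleotide change
  under the standard genetic code, precomputed for all 380 ordered pairs.
- **Positional priors (`mean_dms` / `jse_dms`)** — as above.
- **Embeddings (`wt_esm` / `var_esm` / `diff_esm`)** — per-residue vectors
  at the mutated position from the wild-type and mutated sequence, plus
  their difference `Δe = e_var − e_wt`. Any provider honoring
  `embed(sequence) → L × D` stands behind the contract; archives store one
  wild-type matrix per protein and only the mutated-position row per
  variant. Rows are passed through unscaled.
- **Auxiliary score (`eve`)** — a per-variant external score column (e.g.
  an evolutionary-model pathogenicity score) carried on the dataset;
  missing values flow to LightGBM's native missing handling rather than
  being imputed.

Named presets: `full`, `full_minus_diff_esm`, `esm_plus_mean`, `mean_only`,
`no_esm`, and `zero_shot` (= `full_minus_diff_esm` without positional
priors). Column order is a pure function of the configuration.

### Training and tuning

LightGBM regression with up to 1,000 boosting rounds and early stopping
after 50 rounds without validation-RMSE improvement. When no explicit
validation set is given, a group-aware 10% slice of the training rows is
held out (whole proteins), falling back to a seeded random 10% slice for
single-protein training sets. Determinism contract: fixed seed,
`deterministic=true`, single-threaded row-wise construction — two runs
produce identical models; multi-threaded execution is permitted but outside
the bit-exactness guarantee.

Hyperparameter search minimizes mean grouped 5-fold RMSE over a standard
GBDT box: learning rate [1e−3, 0.3] (log), max depth [3, 12], leaves
[15, 255], row/feature subsampling [0.5, 1], L1/L2 [1e−8, 10] (log). The
sampler is seeded random search, declared in the trial log; the interface
admits any sequential model-based optimizer. Library defaults
(`DEFAULT_PARAMS`) are used when no search is requested, including by the
evaluation protocols and the acceptance script — the package's own choice
to keep end-to-end runs cheap and deterministic.

### Split strategies

All evaluation splits are built by one harness and re-checked by an
independent leakage verifier before any model sees them: whole-protein
holdout (general split and one-protein-out series), per-protein random
splits at a ratio (nearest-variant rounding, ties toward training),
position-granular ratio splits, one-position-out and one-variant-out
series, the SNV split (train on single-nucleotide-reachable substitutions,
test on the rest, with the SNV indicator feature removed since it would
separate the sides by construction), and a family-unique split that retains
at most one domain per family (most observed variants wins, ties broken
lexicographically) so train and test share no family.

### Metrics

RMSE, MAE, R² (1 − SS_res/SS_tot) and Pearson r, with set sizes. R² and r
are reported as missing with a warning flag when the observed values have
zero variance or predictions are constant. Per-variant error tables
(observed, predicted, absolute/squared/percent error) accompany every
protocol run.

## Synthetic corpus

The generator emulates a stability-assay domain corpus so the entire
pipeline is testable without any external data. Its defaults are the study
conditions used throughout the tests: 30 domains of length 60–100, eight
families with Zipf-skewed membership (exponent 1.5), per-position tolerance
τ ~ Beta(2, 2), observation fraction 0.7, Gaussian raw-score noise
σ = 0.05, wild-type anchor 1.0 and nonsense anchor 0.2 on the raw scale.

The true normalized effect of a substitution is

    g(P, pos, wt→var) = max(1 − τ(P, pos) · (1 − ρ(wt, var)), −0.2)

with ρ a BLOSUM62 rescaled to [0, 1]: tolerant positions (small τ) absorb
any substitution, intolerant ones are damaged in proportion to substitution
dissimilarity. The −0.2 floor emulates the slightly out-of-bound scores
real assays produce. Raw scores are the exact inverse of the normalization
transform applied to g plus noise, so at σ = 0 normalization recovers g to
machine precision — the generator and the normalizer are exact inverses by
construction, which the tests exploit as an oracle. Nonsense variants are
emitted at every position at the nonsense anchor plus noise. A
conservation-proxy auxiliary column ("eve") is emitted as a clipped noisy
affine image of 1 − g (σ = 0.1), anti-correlated with fitness, so presets
that include the auxiliary group are exercisable end to end.

Synthetic embeddings place affine images of τ, (1 − ρ) and τ·(1 − ρ) along
three fixed random directions, scaled by a signal fraction (default 0.8),
plus isotropic noise scaled by its complement; signal 0 is a pure-noise
negative control, signal 1 with σ = 0 makes the true effect linearly
decodable from the difference vector.

**What passing tests do and do not show.** The synthetic corpus realizes
the modeling assumptions the method relies on — informative positional
tolerance, informative substitution similarity, embeddings correlated with
effect — in a form learnable by trees. It does not mimic real assay error
structure, real embedding geometry, epistasis, or activity-type phenotypes;
green tests demonstrate the machinery is correct and the qualitative
orderings (embeddings + priors > priors alone > prior-free zero-shot;
nothing learned from pure noise) emerge under controlled conditions, not
that any particular accuracy will be reached on real data.

## Numerical choices and degenerate inputs

- Coordinates are 1-based, closed; offsets are signed integers added to
  domain positions, so the two offset modes compose to the identity.
- Duplicate variant keys are an error, never averaged.
- A wild-type residue disagreeing with the declared sequence is an error
  rather than a silent fix.
- `wt_score == nonsense_baseline` is rejected (zero denominator).
- Ratio splits use nearest rounding with ties toward training and always
  leave at least one variant on each side.
- Nonsense variants anchor baselines but are never feature rows.
- Grouped folds are assigned greedily, largest group first (ties shuffled
  by seed), onto the currently smallest fold.
- Metric test sets of size 1 report absolute error in place of undefined
  correlation statistics.

## Known limitations

- The real protein-language-model provider is an optional plugin; the
  package itself ships only the deterministic mock provider and the
  synthetic generator.
- Only single amino-acid substitutions are modeled; multi-substitution
  variants are out of scope.
- No structural features, no multi-assay harmonization, and no
  significance testing across split strategies.
- Problem sizes in the test suite and acceptance script (30-domain
  corpora, default LightGBM parameters rather than a search) are the
  package's choices for cheap, deterministic end-to-end runs; users fitting
  real corpora should run the tuner.
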