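# dmsfill

Imputation of missing deep-mutational-scanning (DMS) scores across protein
domains with gradient-boosted regression trees.

## The problem

DMS assays measure a functional score for thousands of single amino-acid
substitutions in a protein, producing a variant-effect map over positions ×
substitutions. Real maps are incomplete — coverage limits, sequencing depth
and assay dropout leave many cells unmeasured — which hampers variant
interpretation and downstream analyses. `dmsfill` is a library and CLI for
completing such maps: it is aimed at groups curating MaveDB-style score
tables who want the missing cells filled by a model whose training and
evaluation are explicitly controlled for data leakage.

## The method

Raw scores are first normalized against two per-protein anchors, the
wild-type score s_wt and the nonsense (loss-of-function) baseline s_nons:

    s_norm = (s_raw − s_wt) / (s_wt − s_nons) + 1

so 1 ≈ wild-type-like and 0 ≈ fully damaging, without clipping. Each variant
is then described by a feature vector combining

- amino-acid substitution matrix scores (24 Biopython matrices + Grantham),
- physicochemical properties of both residues and |p_wt − p_var|,
  with one-hot encodings of categorical descriptors,
- a single-nucleotide-variant (SNV) reachability indicator under the
  standard genetic code,
- the mean normalized score per (protein, position) — a data-driven
  positional tolerance prior, optionally James–Stein-shrunk toward the
  protein mean,
- per-residue embedding vectors at the mutated position (wild-type,
  variant, and difference Δe = e_var − e_wt) from any provider honoring the
  embedding contract, and
- optional auxiliary per-variant scores (e.g. an evolutionary model score).

A LightGBM regressor is trained on observed variants (≤1,000 boosting
rounds, early stopping after 50), with group-aware cross-validation —
whole proteins never straddle a split — and a seeded random search over
the usual GBDT hyperparameter box. Evaluation strategies cover whole-protein
holdouts, per-protein random/position/variant holdouts, the SNV split and a
family-unique split, each re-checked by an independent leakage verifier.
A seeded synthetic-corpus generator with known ground truth makes the whole
pipeline testable end to end without any downloads.

See `docs/methods.md` for the model details, the prior leakage policy, and
what the synthetic corpus does and does not emulate.

## Worked example

```python
import numpy as np
import dmsfill as df

# a synthetic stability-assay corpus with known ground truth
spec = df.SyntheticSpec(n_domains=30, length_range=(60, 100), noise_sd=0.05,
                        observed_fraction=0.7, seed=7)
dataset, truth = df.simulate(spec)

# normalize raw scores against wild-type and nonsense baselines
baselines = df.estimate_all_baselines(dataset)
normalized = df.normalize_scores(dataset, baselines)

# synthetic per-residue embeddings correlated with the true effects
archive = df.simulate_embeddings(normalized, truth, dim=16,
                                 signal_fraction=0.8, seed=7)

# train on 90% of proteins, test on held-out proteins
reports, errors = df.run_protocol(normalized, "leave_protein_out",
                                  "esm_plus_mean", seed=7,
                                  embeddings=archive)
r = reports[0]
print(f"held-out proteins: n_test={r.n_test}  RMSE={r.rmse:.3f}  "
      f"MAE={r.mae:.3f}  R2={r.r2:.3f}  r={r.pearson_r:.3f}")
```

prints

```
held-out proteins: n_test=3218  RMSE=0.072  MAE=0.057  R2=0.876  r=0.936
```

i.e. on proteins the model never saw, predictions of the normalized scores
(wild-type ≈ 1, loss-of-function ≈ 0) are within ~0.07 RMSE and explain
~88% of the variance; `errors` holds the per-variant observed/predicted/
error table behind those numbers. The same pipeline is available from the
shell:

```sh
dmsfill simulate --domains 30 --len 60:100 --seed 7 --embeddings --out sim/
dmsfill normalize --scores sim/scores.csv --fasta sim/sequences.fa --out norm.csv
dmsfill evaluate --scores norm.csv --fasta sim/sequences.fa \
    --strategy general --preset esm_plus_mean \
    --embeddings sim/embeddings.h5 --seed 7 --out report.json
```

and `dmsfill train` / `dmsfill impute` fill every unobserved cell of a real
score table, flagging imputed rows.

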