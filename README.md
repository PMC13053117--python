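# aposcore

Detectability-vs-toxicity analysis for butterflies: from citizen-science
detection-game logs and Daphnia bioassays to a phylogenetic Bayesian model
of how conspicuousness relates to chemical defence.

## The scientific problem

Aposematic animals pair a warning signal (conspicuous colour) with a
secondary defence (toxins). For butterflies, the dorsal and ventral wing
surfaces can carry different signals — the dorsal side is exposed in
flight, the ventral side at rest — so the relationship between
conspicuousness and toxicity may differ by wing side. `aposcore`
implements the full analysis pipeline for studies that operationalise
conspicuousness as *human detection time*: players of a web game click on
a butterfly image placed against a natural background, with rounds
right-censored at 10 s, while toxicity is proxied by the fraction of 10
*Daphnia* killed by a body extract in repeated binomial assays.

The pipeline is aimed at researchers in sensory/chemical ecology and
phylogenetic comparative methods who want these stages as tested,
reusable parts rather than one-off scripts:

- **`synthetic_data`** — a generator with known ground truth (pure-birth
  trees, log-normal censored detection times, phylogenetically correlated
  toxicity), so every stage is verifiable by parameter recovery.
- **`game_ingest`** — schema-validated reading of round logs, censoring,
  exclusion of players who found fewer than three butterflies, and a
  mixed-model estimate of replay learning.
- **`detectability`** — mean detection time per image × background; each
  image's *most cryptic background* score; the dorsal–ventral difference
  statistic; imputation of missing dorsal scores and z-scoring.
- **`toxicity_assays`** — per-species mean mortality, control baselines,
  and the >20% toxicity flag.
- **`phylo_cov`** — Newick parsing, pruning to study species via an
  explicit mapping table, and the Brownian-motion correlation matrix.
- **`bayes_glmm`** — the Bayesian binomial mixed model with a
  phylogenetically correlated species effect, with convergence
  diagnostics (split-R̂, bulk/tail ESS) and Table-style summaries.
- **`variance_report`** — Bayes R², marginal (fixed-effect) R² with the
  logit π²/3 residual variance, genus-level effect summaries, reports.

## The model

Per assay *i* on species *s(i)*:

```
deaths_i ~ Binomial(n_i, p_i)
logit(p_i) = x_i'β + u_{s(i)},        u ~ MVN(0, σ² C)
```

where `C[j,k] = depth(MRCA(j,k)) / tree depth` is the Brownian-motion
correlation implied by the phylogeny. Model 1 uses the z-scored dorsal
and ventral most-cryptic-background detection times as predictors;
Model 2 uses the z-scored dorsal–ventral difference statistic.
Coefficients have flat priors; σ has a half-Student-t(3, 0, 2.5) prior.
Sampling uses adaptive Metropolis-within-Gibbs on the non-centered
parametrization `u = σ L z` (L the Cholesky factor of C), plus
likelihood-invariant translation/scale moves that decorrelate β from the
species effects; see `docs/methods.md` for details and validation.

## Worked example

```python
import dataclasses
from aposcore import (synthetic_data as sd, game_ingest as gi,
                      detectability as det, bayes_glmm as bg,
                      variance_report as vr)

cfg = sd.SimConfig(n_species=20, n_backgrounds=10, rounds_per_game=10,
                   n_players=300, games_per_player=2, n_missing_dorsal=2,
                   n_dimorphic=1, seed=11)
truth = sd.simulate_ground_truth(cfg)
records = gi.apply_censoring(sd.simulate_game_log(cfg, truth))
records, qc = gi.filter_players(records, min_found=3)
table = det.mean_times(records)
predictors = det.species_predictors(table, truth.images)
assays = sd.simulate_assays(cfg, truth, detectability_scores=predictors, model=1)
data = bg.build_model_data(predictors, assays, truth.correlation, model=1)
draws = bg.sample_posterior(data, chains=4, iter=2000, warmup=1000, seed=1)
print(bg.summarize(draws).round(2).to_string(index=False))
```

prints (this run kept 5820/6000 rounds from 300 players, 9 excluded):

```
   parameter  Estimate  Est.Error   l95   u95  significant  Rhat  Bulk_ESS  Tail_ESS
   Intercept     -1.32       0.40 -2.15 -0.43         True  1.01    848.37    666.90
 dorsal_time     -0.25       0.09 -0.43 -0.08         True  1.01    313.00    581.14
ventral_time      0.03       0.11 -0.19  0.23        False  1.02    184.41    569.13
    sd_phylo      0.63       0.25  0.23  1.19         True  1.02    127.08    248.59
```

The negative, significant `dorsal_time` slope says faster-found (more
conspicuous) dorsal sides predict higher Daphnia mortality on the
log-odds scale — here correctly recovering the generator's truth
(β_dorsal = −0.21 per SD, β_ventral = −0.06). Continuing,

```python
r2 = vr.bayes_r2(draws, data)
marg, phylo = vr.marginal_r2(draws, data)
```

gives `Bayes R2 = 0.25 (95% CI 0.14-0.36)`, `marginal R2 = 0.020` and a
phylogenetic share of `0.11` of the latent-scale variance.

A command-line surface mirrors the stages:

```sh
aposcore simulate --config cfg.yaml --out data/ --seed 5
aposcore ingest   --log data/rounds.tsv --out clean/
aposcore scores   --clean-log clean/clean_rounds.tsv --mapping data/images.tsv --out scores/
aposcore assays   --in data/assays_model1.tsv --out tox/
aposcore phylo    --tree data/tree.nwk --mapping data/mapping.tsv --out phylo/
aposcore fit      --data rundir/ --model 1 --chains 4 --iter 2000 --seed 3 --out fit/
aposcore report   --run fit/
```

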