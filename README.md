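# naturegait

Trial-by-trial analysis of gait kinematics while people walk toward
photographic images of nature and urban scenes that were matched
beforehand for how much an independent sample liked them. Walking is
sensitive to cognitive load — people slow down and shorten their steps
when processing a demanding scene — so per-trial gait parameters act as
an implicit, continuous probe of how hard a scene is to process. The
package is written for movement scientists and environmental
psychologists who want to run (or stress-test) this analysis chain
end-to-end without access to the original laboratory recordings.

It covers four stages, each usable on its own:

1. **Gait kinematics** (`naturegait.gait`) — from 3D marker trajectories
   (hip + both feet, 100 Hz): zero-phase 5 Hz Butterworth low-pass
   filtering, truncation of the first 0.5 m and last 2 m of a 12 m
   capture space (leaving 9.5 m of steady walking), stance detection as
   stationary foot-marker periods (< 5 cm displacement per 0.1 s),
   landing/lifting times from Y-axis acceleration extrema, and per-trial
   mean/SD of step length and stride time plus walking velocity.
   Trials with missing markers, steps over 1.3 m, or consecutive
   same-foot steps are flagged as inconsistent walking.
2. **Fractal dimension** (`naturegait.fractal`) — Minkowski–Bouligand
   box counting on mean-binarized grayscale images: the image complexity
   statistic used as a candidate predictor of gait change.
3. **Cross-classified multilevel model** (`naturegait.model`) — trials
   are nested simultaneously in participants and images:

       z_v[t] = x[t]'β + u[participant(t)] + v[image(t)] + e[t],
       u ~ N(0, σ²_u),  v ~ N(0, σ²_v),  e ~ N(0, σ²_e),

   fitted by a conjugate Gibbs sampler (diffuse Normal priors on β,
   inverse-Gamma(0.001, 0.001) on variances; burn-in 500, chain 10,000
   by default), with DIC for model comparison, Wald X²₁ screening of
   fixed effects, and the two-stage predictor-selection procedure
   (main effects, then pairwise interactions of the survivors).
4. **Synthetic study generator** (`naturegait.synthetic`) — liking-matched
   image pairs, a trial table drawn from the cross-classified model at
   the study's design values (44 participants × 105 trials; variance
   components 0.904/0.002/0.157; liking effect 0.016 on standardized
   velocity), and full marker trajectories with alternating stance/swing
   foot motion and 1 mm capture noise — so every stage above can be
   round-trip tested against known ground truth.

The model-fitting, fractal and gait-extraction surfaces follow
scikit-learn conventions (`CrossClassifiedModel`, `GaitFeatureExtractor`,
`BoxCountingFractalDimension` expose `fit`/`transform`/`get_params`), and
a `naturegait` CLI wires the stages together.

## Worked example

Simulate a small study with a clear liking effect and no environment
effect, measure one trial's gait from its synthesized trajectory, and run
the staged model selection:

```python
from naturegait import (GeneratorConfig, McmcConfig, generate_image_metadata,
                        generate_trial_table, synthesize_trial_trajectory,
                        summarize_trial, prepare_design, staged_selection)
from naturegait.synthetic import images_to_frame

config = GeneratorConfig(seed=7, n_participants=12, n_pairs=25,
                         n_control=3, beta_liking=0.06)
images = generate_image_metadata(config)
table, truths = generate_trial_table(config, images)

gait = summarize_trial(synthesize_trial_trajectory(truths[0], config))
print(f"velocity {gait.mean_velocity:.3f} m/s "
      f"(true {truths[0].true_velocity:.3f})")

design = prepare_design(table, images_to_frame(images),
                        predictors=("ENV", "LIK", "TK", "FR"),
                        velocity_col="true_velocity")
result = staged_selection(design, ["ENV", "LIK", "TK", "FR"],
                          McmcConfig(burn_in=500, chain_length=4000, seed=7))
print(result.comparison.to_string(index=False))
print(f"best model: {result.best_label} "
      f"(fixed effects: {', '.join(result.best_fixed_effects)})")
```

which prints

```
velocity 1.218 m/s (true 1.217)
model        dic                        fixed    random
    1 874.027718                              PT, IM, T
    2 869.830518             ENV, LIK, TK, FR PT, IM, T
   2a 868.553440                          LIK PT, IM, T
    3 871.407597 LIK, LIK*ENV, LIK*TK, LIK*FR PT, IM, T
   3a 868.553440                          LIK PT, IM, T
best model: 2a (fixed effects: LIK)
```

Reading the output: the gait chain recovered the trial's generating
velocity to 1 mm/s from the noisy synthetic trajectory. In the selection
table, model 1 is the random-intercepts-only null; model 2 enters all
four candidate predictors (environment dummy ENV, liking z-score LIK,
task dummy TK, fractal-dimension z-score FR); 2a keeps only the
Wald-significant survivors; model 3 adds the survivors' pairwise
interactions and 3a prunes them again. The liking-only model wins on
DIC (lower is better), its liking coefficient is 0.074 ± 0.024 standard
deviations of velocity per standard deviation of liking score (Wald
X²₁ = 9.77, p = .002), and the environment dummy is discarded — the
selection recovers the structure the data were generated with: liking,
not environment type, predicts walking speed.

The same run is available from the shell:

```bash
naturegait run --simulate --seed 7 --out-dir out/
naturegait simulate --out-dir sim/ --seed 1 --write-trajectories 10
naturegait gait --input-dir sim/trajectories --out gait.csv
naturegait fractal --images stimuli/ --out fd.csv
naturegait model --table gait.csv --images sim/images.csv \
    --candidates ENV,LIK,TK,FR --burn-in 500 --chain 10000 --seed 1
```

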