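# dfcstates

Dynamic functional connectivity ("chronnectome") brain-state analysis for
independent-component time courses, with a synthetic cohort generator so the
whole pipeline is testable without any imaging data.

The pipeline, per subject and then per cohort:

1. **Preprocessing** (`dfcstates.prep`) — discard initial volumes, optional
   nuisance regression (motion parameters + derivatives + polynomial trends),
   median/MAD despiking, zero-phase fifth-order Butterworth band-pass
   (0.01–0.15 Hz); framewise-displacement computation from rigid-body motion.
2. **Windowed features** (`dfcstates.features`) — sliding-window Pearson
   correlations (22 TR windows, step 1 TR), boxcar-averaged windows (ASWC,
   25 TR) with aligned first-order derivatives, per-subject per-block
   z-scoring, cohort concatenation, and full-length static connectivity.
   With the default acquisition (225 volumes, TR 2 s, 53 components) this
   yields 222 → 200 → 175 windows of 1378 + 1378 = 2756 features.
3. **Brain states** (`dfcstates.states`) — exemplar windows at local maxima of
   across-feature variance; Davies-Bouldin and Ray-Turi validity curves over
   k = 2–10; k-means under correlation distance (33 replicates, 4000 max
   iterations); states renumbered by descending occupancy.
4. **State dynamics** (`dfcstates.dynamics`) — fraction of time, mean dwell
   time, visits, transition counts per subject; group-pooled
   transition-probability matrices and their attractors (cycles of the
   maximal-probability successor map).
5. **Group inference** (`dfcstates.inference`) — two-tailed permutation tests
   (100,000 permutations), Benjamini-Hochberg FDR within the FT and MDT
   families, Hedges' g (patients − controls), Spearman correlations with
   clinical scores (CGI-S / BDI / BAI) in the patient group.
6. **Synthetic cohorts** (`dfcstates.synthetic`) — Markov-switching
   multivariate-normal component signals with block-structured (seven
   functional subdomains: AUD 2, CER 4, CON 17, DMN 7, SCN 5, SMN 9, VIS 9)
   state covariances, per-subject seeded streams, motion traces, and optional
   group effects on state-1 occupancy.

## CLI

```bash
# end-to-end on a synthetic cohort (simulate -> preprocess -> features ->
# fit-states -> dynamics -> compare)
dfcstates all --workdir out --seed 1

# individual stages; a YAML config can override any parameter
dfcstates simulate   --workdir out --config config.yaml
dfcstates preprocess --workdir out
dfcstates features   --workdir out
dfcstates estimate-k --workdir out          # validity curve + chosen k
dfcstates fit-states --workdir out --k 5    # supplementary k override
dfcstates dynamics   --workdir out
dfcstates compare    --workdir out
```

Every stage writes delimited-text artifacts plus JSON sidecars, echoes the
resolved configuration, logs itself in `pipeline_log.json`, and refuses to
run before its predecessor (override with `--force`).

## Library use

```python
from dfcstates import prep, features, states, dynamics, inference
from dfcstates.synthetic import SyntheticCohortConfig, simulate_cohort

subjects, truth = simulate_cohort(SyntheticCohortConfig(seed=1))
sets = []
for tc in subjects:
    clean = prep.preprocess(tc)
    swc = features.sliding_window_correlations(clean)
    sets.append(features.zscore_feature_blocks(features.aswc_and_derivatives(swc)))

cohort = features.concatenate_cohort(sets)
curve = states.estimate_k(states.select_exemplars(sets))
model, seqs = states.fit_states(cohort, curve.chosen_k)
metrics = [dynamics.state_metrics(s, model.k) for s in seqs]
report = inference.run_group_analysis(
    [m for m, tc in zip(metrics, subjects) if tc.group == "patient"],
    [m for m, tc in zip(metrics, subjects) if tc.group == "control"],
    k=model.k,
)
```
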