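# contextsim

Simulation and analysis of **delay-dependent context reactivation in medial
temporal lobe (MTL) voxel patterns** during recognition memory.

The scientific question: when people recognize an item one day after
studying it (vs. minutes after), do hippocampal and parahippocampal regions
still reactivate the *context* in which the item was studied? The package
implements, on fully synthetic data with known ground truth, the complete
analysis used to answer this with fMRI pattern similarity:

1. **Experiment simulator.** A two-day design: 252 object nouns in three
   84-item lists (immediate, delayed, lure); studied items are embedded in
   sentences placing them in one of eight rooms (four rooms per study day,
   21 items per room); after encoding, each day's rooms are grouped into two
   "houses". Item recognition is tested in three scanner runs (2 s word
   events, jittered fixation with mean 4 s and range 2–10 s, TR = 1.22 s)
   using a 6-point remember/know scale, followed by an associative
   (intact/recombined sentence) test with 28 intact and 56 recombined
   sentences per day. Behavior comes from a dual-process generative model;
   BOLD comes from HRF-convolved trial sticks with AR(1) noise, drift, and
   motion artifacts, in which recollection trials carry a room-specific
   pattern component.
2. **Behavioral scoring.** Dual-process estimates
   `R = (R_old − R_new)/(1 − R_new)` and
   `F = F_old/(1 − R_old) − F_new/(1 − F_new)`, item and associative
   `d′ = z(hit) − z(fa)`, and associative accuracy conditioned on item
   memory status.
3. **GLM estimation.** A nine-condition event model (recollection /
   familiarity / forgotten × delay, correct rejections, false alarms,
   no-response) for univariate contrasts, and least-squares-separate (LSS)
   single-trial models yielding a 252-trial beta series per subject.
   ART-style artifact flagging (> 0.3 mm movement or > 1.3 % global signal
   change) supplies spike regressors.
4. **ROI patterns.** Temporal-SNR voxel filtering (drop voxels > 1 SD below
   the ROI mean), pattern extraction, and global-signal trial outliers.
5. **Context similarity.** Pearson correlations between recollection-trial
   patterns, restricted to pairs from the same list and memory status, at
   least two trials apart, within run; different-room pairs from rooms
   grouped into one house are excluded. Fisher-z similarities are averaged
   within run, then across runs; the statistic is *same-room minus
   different-room* similarity. A stratified room-label randomization test
   provides its null distribution.
6. **Group inference.** 2×2 within-subject ANOVAs via difference scores
   (exact for two-level factors), trial-count matching across delays,
   directional t-tests, conjunction thresholding (joint p = 0.001 → per-map
   p = 0.032), and the brain–behavior regression of context similarity on
   associative d′ controlling for recollection trial counts.

## Worked example

The dual-process estimators applied to group-mean response rates
(`R_old` = 0.46/0.25 for the immediate/delayed lists, `R_new` = 0.04):

```python
>>> import contextsim as cs
>>> cs.estimate_recollection(0.46, 0.04)
0.43750000000000006          # rounds to 0.44
>>> cs.estimate_recollection(0.25, 0.04)
0.21875                      # rounds to 0.22
```

A six-subject cohort simulated and analyzed end to end (full BOLD + LSS
route, left-MTL ROIs):

```python
>>> cfg = cs.PipelineConfig(seed=7, n_subjects=6, neural=cs.small_mtl_params())
>>> results, group = cs.simulate_cohort(cfg)
>>> group["activation_anova"]["left_post_hf"]["memory_x_delay"]
{'F': 42.91, 'p': 0.0012}
>>> group["context_similarity_tests"]["left_ant_hf_immediate"]
{'t': 3.68, 'p': 0.0071, 'n': 6, 'mean': 0.063}
```

The posterior hippocampus shows the memory × delay interaction (its
recollection effect was simulated to drop from 0.5 to 0.1 after the delay),
while anterior-hippocampal patterns show positive context similarity during
immediate recollection (same-room pairs more similar than different-room
pairs by ~0.06 Fisher-z units) — the two signatures the pipeline is built
to detect.

The same pipeline is available from the shell:

```bash
contextsim simulate --seed 3 --out sim/
contextsim score-behavior --events sim/recognition_events.tsv --out scores.csv
contextsim full-pipeline --seed 0 --n-subjects 6 --out run/
```

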