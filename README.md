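# actinovelty

Movement-pattern divergence analysis for multi-sensor actigraphy.

## The problem

Children wear four tri-axial accelerometers (one on each wrist and ankle,
10 Hz, g units) for a day. The question is not *how much* a child moves but
*how* — whether their movement patterns differ from those of a typically
developing reference population, as happens for example in ADHD. The
approach implemented here:

1. **Preprocessing.** Raw sensor-frame acceleration is orientation-dependent,
   so each stream is projected onto its own gravity estimate
   g′(i) = (1/(N+1)) Σ_{j=i−N/2}^{i+N/2} a_t(j), giving the geo-referenced
   vertical movement acceleration a_v(i) = (a_t(i) − g′(i)) · ĝ′(i).
   The four streams are aligned on a deliberate simultaneous shake burst
   recorded while the sensors are held together (entry threshold th₁, exit
   condition mean |a_v| ≤ th₂ over a forward window).
2. **Forecasting.** A 2-layer LSTM (50, then 20 memory units; standard
   forget/input/output gate equations with shared weights across time) plus
   a fully connected head maps the last 6 s of the four aligned channels
   (60 × 4) to the next 2 s (20 × 4), trained by mean-square-error
   minimisation on windows from a *training* control group only.
3. **Novelty scoring.** Recordings are divided into non-overlapping 8 s
   windows. A window whose observed 2 s continuation correlates with the
   forecast below th = 0.5 (Pearson, over the flattened 80-value vectors)
   is a **non-similar fragment** — a movement pattern the control-trained
   model did not learn.
4. **Group comparison.** Per-participant non-similar counts are compared
   between each case group and a held-out control group with a one-sided
   pooled-variance t-test, overall and stratified by movement intensity
   (the sample SD of all 320 pooled values in the window, binned at
   0.2 g steps). Group separability is summarised by the pairwise AUC and
   a Youden-optimal operating point; a threshold sweep re-derives counts
   at other values of th from the stored correlations.

Because no recordings are distributed with the study design, the package
ships a seeded synthetic-cohort generator (`actinovelty.synthetic`) that
emulates the structure the analysis relies on — shake bursts, drifting
sensor orientations, ≤2 Hz band-limited movement motifs at mixed
intensities — and plants a controllable fraction δ of group-specific
divergent motifs inside a chosen intensity band, giving ground truth
against which the whole pipeline is validated.

## Worked example

```python
from actinovelty import MovementNoveltyModel, TrainConfig
from actinovelty.synthetic import CohortSpec, generate_cohort

spec = CohortSpec(seed=42)   # 9 per group, 600 s at 10 Hz, delta=0.8 in [0.4, 1.0) g
cohort = generate_cohort(spec)
model = MovementNoveltyModel.from_cohort(cohort)
res = model.fit(TrainConfig(seed=42))
print(res.summary())
```

```
Movement-pattern divergence analysis
====================================================================
similarity threshold th = 0.5; control group: control_test; 7 comparisons (uncorrected)

group              n    total  mean/participant        SD
--------------------------------------------------------------------
control_test       9      389              43.2       6.5
atypical           9      519              57.7       3.9

one-sided t-tests, case > control (all intensities):
  atypical         t =  5.730  df =   16  p = 0.0000

per intensity bin (combined SD, g units):
bin                 atypical
[0, 0.2)              0.6914
[0.2, 0.4)            0.0881
[0.4, 0.6)            0.0019
[0.6, 0.8)            0.0003
[0.8, 1)              0.0049
[1, inf)              0.9048
```

The atypical group accumulates more non-similar fragments (57.7 vs 43.2
per participant), and the per-bin p-values localise the effect to exactly
the 0.4–1.0 g band where the divergent motifs were planted; bins outside
the band stay at chance. Separability in the band:

```python
auc, op = res.roc_auc("atypical", band=(0.4, 1.0))
# divergence-band AUC = 0.988; operating point: 9/9 atypical vs 1/9
# controls above count threshold 23
```

The same analysis is scriptable from a shell via the `actinovelty` CLI
(`simulate`, `preprocess`, `segment`, `train`, `score`, `compare`,
`sweep`, or `run` for the whole chain), driven by a flat `key = value`
config file; every stage reads the previous stage's CSV outputs and all
parameters are echoed into a run log.

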