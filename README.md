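# gaitdyn

Nonlinear dynamics of walking from wearable tri-axial accelerometry:

- **Synthetic gait generator** (`gaitdyn.synthgait`) — lumbar and foot
  acceleration signals driven by stride-interval series of prescribed
  correlation structure (constant, random, persistent fGn via exact
  Davies–Harte synthesis, or anti-persistent error-corrected "metronome"
  timing), with ground truth for every downstream stage.
- **Preprocessing** (`gaitdyn.preprocess`) — tilt realignment so gravity lies
  on the vertical axis, vector norm, FFT cadence estimation, steady-segment
  selection, and crop + polyphase resampling to exactly 18,750 samples
  (250 steps × 75 samples/step).
- **Stride detection** (`gaitdyn.strides`) — stride intervals from the foot
  sensor via norm → integration → detrend → peak detection.
- **DFA** (`gaitdyn.dfa`) — DFA-1 scaling exponent α with evenly log-spaced
  box sizes from 16 to N/2.
- **Attractor reconstruction** (`gaitdyn.attractor`) — embedding delay from
  the first minimum of average mutual information, dimension from global
  false nearest neighbors, exact delay embedding.
- **Divergence exponents** (`gaitdyn.divergence`) — nearest-neighbor
  logarithmic divergence curves (Theiler window 75 samples, 1800-sample
  horizon), short-term exponent (LDS, fit 0–0.5 stride) and long-term
  exponent (ACI, fit 5–12 strides), per axis and for the vector norm, plus a
  fit-range tuning sweep.
- **Reliability statistics** (`gaitdyn.reliability_stats`) — paired Hedges' g
  with percentile-bootstrap CIs, Pearson correlation tables, ICC(3,k)/(A,k)
  absolute-agreement reliability with SEM / smallest detectable difference.
- **Pipeline + CLI** (`gaitdyn.pipeline`, `gaitdyn.cli`) — per-lap analysis
  and cohort tables (condition contrasts, test–retest reliability,
  correlations).

## CLI

```sh
# synthesize one lap (lumbar.csv, foot.csv, truth.json)
gaitdyn simulate --out-dir sim/ --n-strides 150 --structure persistent --seed 7

# analyze one lap (stride detection + DFA from the foot file,
# divergence exponents from the lumbar file)
gaitdyn analyze --lumbar sim/lumbar.csv --foot sim/foot.csv --out-dir out/P0 \
    --participant P0 --condition normal --lap out

# aggregate many analyzed laps into cohort tables
gaitdyn cohort --results out/ --out-dir tables/

# fit-range tuning sweep over saved divergence curves
gaitdyn sweep --results out/ --out-dir tables/ --ranges "1:4,3:8,5:12"
```

Input CSVs have columns `t,ap,v,ml` (seconds, units of g; axes ordered
anteroposterior, vertical, mediolateral, with +1 g static offset on the
vertical axis).

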