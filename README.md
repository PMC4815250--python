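# mrcpbmi

Asynchronous EEG-based motor-intent detection from movement-related cortical
potentials (MRCPs), packaged as a tested library + CLI:

- **`synthetic_data`** — seeded generator for EEG/EMG/kinematics sessions:
  slow negative cortical potentials with per-trial latency jitter on a
  configurable channel subset, 1/f background noise with a shared low-rank
  component, band-limited EMG bursts, minimum-jerk elbow trajectories, and the
  trial/fixation/catch-trial block structure.
- **`io_formats`** — a portable session container (JSON sidecar + raw float64
  arrays) and a minimal BrainVision `.vhdr/.vmrk/.eeg` reader/writer.
- **`preprocess`** — causal delta-band chain (4th-order Butterworth 0.1 Hz
  high-pass → Large-Laplacian re-reference → 1 Hz low-pass → decimation to
  20 Hz), with a state-carrying streaming variant that bit-matches
  whole-session filtering; paired Go/No-go epoching `[-2.5 s, 1 s]`,
  amplitude-based artifact rejection with paired removal, and EMG band-pass +
  trailing 300 ms RMS envelopes.
- **`features`** — spatial-average trace, fixed/adaptive feature windows
  (adaptive edge at the per-trial negative peak; trials peaking before
  −1.5 s screened from training), and the four features: slope, negative
  peak, area, Mahalanobis distance to the Go cluster.
- **`calibration`** — C-SVC (RBF) with probability outputs, stratified
  10-fold *pseudo-online* cross-validation (50 ms sliding test windows,
  three-consecutive-Go rule), (C, γ) grid search, window-length optimization
  over 0.5–1.0 s by ROC area, label-permutation significance test, and a
  JSON-serializable calibrated model.
- **`online_sim`** — closed-loop replay: causal streaming predictions every
  50 ms, τ_c/N_c consecutive-probability intent rule, EMG gating within a 1 s
  timer, per-trial outcome logs including catch trials.
- **`metrics`** — block TPR/FPR, intents per minute and its CoV, detection
  latency versus kinematic movement onset, rank-sum day comparisons and
  block-trend regression.

## CLI

```sh
mrcpbmi simulate  --config cfg.yaml --seed 3 --out sess/        # synthetic session
mrcpbmi calibrate --session sess/ --mode adaptive \
                  --channels Cz,C1,C2,CPz --out model.json      # train + optimize
mrcpbmi replay    --session sess/ --model model.json --out outcomes.csv
mrcpbmi evaluate  --outcomes outcomes.csv --out report.json
```

`simulate --config` accepts YAML with `session_plan`, `mrcp`, `emg`, `kin`
and `noise_level_uv` keys mirroring the dataclasses in
`mrcpbmi.synthetic_data`; `replay --config` mirrors
`mrcpbmi.online_sim.OnlineConfig`.

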