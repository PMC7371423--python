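# fiberlearn

Trial-based analysis of fiber-photometry calcium signals recorded while
head-fixed mice learn a go/no-go auditory discrimination, together with a
synthetic session generator so that every analysis stage is verifiable
against known ground truth without animal recordings.

The pipeline covers:

- **behavior** — outcome classification (hit / miss / CR / FA), d′ per
  50-trial bin, sigmoid fits `S(t) = a / (1 + e^{-(t-b)/c})`, and the
  learning threshold (the trial where the fitted curve crosses d′ = 1);
- **photometry** — per-trial ΔF/F baseline normalization, 2-D learning maps
  (trial time × learning), novice/expert phase averages (first/last 500
  trials), windowed evoked responses, choice traces (hit − miss), and
  frequency-response areas from passive tuning sessions;
- **discrimination** — time-resolved rank-based ROC/AUC between trial-type
  pairs (hit-vs-FA "stim", hit-vs-miss "choice", plus the CR-vs-miss /
  FA-vs-CR alternatives), a label-shuffle null band (mean ± 3 SD over 100
  shuffles), discrimination latencies, and second-derivative onset
  estimation for choice and lick-rate traces;
- **learning** — late-window response curves across learning, their
  normalized sigmoid fits and 0.5-crossing trial thresholds, per-timepoint
  correlation with the behavioral learning curve, and cross-mouse
  threshold concordance;
- **movement** — ROI motion energy (one minus frame-to-frame correlation),
  baseline-mean + 3 SD binarization, movement-probability maps, movement
  onsets (0.2 s before the first crossing), and movement-free truncation of
  photometry trials;
- **stats** — two-tailed Wilcoxon–Mann–Whitney and signed-rank tests
  (exact for small samples), per-mouse choice tests with minimum trial
  counts, and Bonferroni correction;
- **synthetic** — deterministic, seeded generation of trial tables,
  GCaMP-like fluorescence (sensory transient + learning-scheduled choice
  ramp + movement coupling, convolved with a difference-of-exponentials
  kernel), body-camera frame stacks with ground-truth movement intervals,
  and passive tuning sessions.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, closed-form checks, and seeded calibration/recovery
experiments at 50–100 repetitions); the whole suite runs in a few minutes
on one CPU.

## Command line

All stages are exposed under one entry point (`fiberlearn --help`):

```bash
# generate a synthetic bundle (trials.csv, session.h5, ground_truth.json)
fiberlearn simulate --config cfg.yaml --out session_dir --seed 1

# d' learning curve, sigmoid fit and learning threshold
fiberlearn behavior --table session_dir/trials.csv --bin 50 --criterion 1.0 --out curves.csv

# phase averages and windowed responses
fiberlearn photometry --session session_dir/session.h5 --table session_dir/trials.csv \
    --phase expert --window 0.6:1.0 --out phot.csv

# time-resolved AUC with shuffle-null band and latency
fiberlearn auc --session session_dir/session.h5 --table session_dir/trials.csv \
    --pair choice --phase expert --shuffles 100 --seed 7 --out auc.csv

# response curve, trial threshold, response/learning correlation
fiberlearn learning --session session_dir/session.h5 --table session_dir/trials.csv \
    --window 0.6:1.0 --out learning.json

# motion energy, binary movement vectors, onsets and truncation
fiberlearn movement --frames frames.h5 --roi forelimbs,neck,jaw \
    --session session_dir/session.h5 --table session_dir/trials.csv --out movement.h5

# one-shot JSON summary
fiberlearn report --session session_dir/session.h5 --table session_dir/trials.csv \
    --seed 3 --out report.json
```

## File formats

- Trial tables: CSV with columns
  `mouse_id,trial_index,day,stimulus_freq_hz,stimulus_class,outcome,lick_times_s`
  (lick times semicolon-joined, seconds relative to stimulus onset).
- Photometry sessions: HDF5 with `/traces` (trials × frames), `/time_s`,
  and attributes `sampling_rate`, `normalized`, `mouse_id`,
  `baseline_window`.
- Frame stacks: HDF5 with `/frames` (uint8), `/frame_time_s`,
  `/frame_trial_index`, `/roi/<name>` masks, attribute `frame_rate`.

Time convention: seconds relative to stimulus onset; the visual start cue
is at −2.0 s, the stimulus occupies (0, 1] s, and the lick response window
is (1, 4] s.

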