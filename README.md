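# oscipp

Oscillometric **pulse-pressure (PP) estimation** from smartphone-style
hand-raise sensor sessions, plus the measurement-validity rules and a
systolic-hypertension screening analysis on synthetic populations.

The idea implemented here: a user presses a thumb on a phone (contact
pressure near mean BP) and raises both hands through a full arm length.
The accelerometer z-channel times the blood-density hydrostatic pressure
(ρ·g·h, ~±45 mmHg for a typical arm) sweeps the thumb artery's transmural
pressure through zero, so the pulse-volume oscillation amplitude measured
by the front camera (PPG) traces an inverted-U oscillogram against ρgh.
The oscillogram is shifted by the unknown contact pressure, so absolute
systolic/diastolic BP are unidentifiable — but its **width** between the
maximum- and minimum-slope points of a fitted five-parameter curve gives
PP (the classic derivative algorithm).

## Layout

| module | contents |
|---|---|
| `oscipp.signal_sim` | physics-based session simulator + synthetic population generator (ground truth known, fully seeded) |
| `oscipp.oscillometry` | beat detection → ρgh conversion → discrete oscillogram → 5-point smoothing → five-parameter fit → derivative-width PP and HR |
| `oscipp.validity` | the three valid-measurement criteria (<5% contact-area change, both oscillogram limbs <50% of max, linear ρgh) and the target-contact-area heuristic with its halving rule |
| `oscipp.screening` | population filtering, 70/30 split, 10-ReLU-hidden/softmax MLP (L-BFGS, cross-entropy), ROC/AUC, PP measurement-noise robustness experiment, Bland–Altman agreement statistics |
| `oscipp.session_io`, `oscipp.config`, `oscipp.cli` | session CSV+JSON-sidecar formats, YAML run configuration, command-line surface |

## CLI

```bash
# simulate a session (PP = 40 mmHg), estimate it, check validity
oscipp simulate --pp 40 --seed 1 -o s.csv
oscipp estimate s.csv                 # JSON result on stdout
oscipp estimate s.csv --strict        # nonzero exit if invalid
oscipp validate s.csv                 # per-criterion table

# screening workflow on a synthetic population
oscipp simulate-population --n 20000 --seed 5 -o pop.csv
oscipp screen-train pop.csv --features all_features --seed 5 -o model.json
oscipp screen-eval model.json pop.csv --seed 5 --roc-csv roc.csv
oscipp noise-exp model.json pop.csv --seed 5   # PP-noise robustness
```

Exit codes: `0` success, `1` pipeline/validity failure (`--strict`,
`validate`), `2` usage error. Configuration defaults live in
`src/oscipp/data/defaults.yaml`; pass `--config my.yaml` to override.

Session files are long-format CSV (`t_s, channel, value`; channels `ppg`,
`accel_z_g`, `touch_x`) with a JSON sidecar (`arm_length_m`, rates, seed,
flags, optional ground truth). Population tables are plain CSV with
`age, sex, race, bmi, smoking, sbp, dbp, hr` (replicate columns
`sbp_1..n`/`dbp_1..n` are averaged by `filter_population`).

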