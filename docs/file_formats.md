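# File formats

All artifacts are UTF-8 delimited text or YAML; nothing binary.

## Trajectory pair (`trajectory_pair_*.csv`)

One file per trial. Columns:

| column | type | meaning |
| --- | --- | --- |
| `frame` | int | frame index from 0 (60 frames/s) |
| `hue_a_deg` | float | stream A hue in [0, 360) |
| `hue_b_deg` | float | stream B hue in [0, 360) |

Floats are written with `%.17g`, so reading a written file reproduces the
angles bit-exactly (`float_precision="round_trip"` on read). Reversal frames
are recovered on read as the sign changes of the wrapped per-frame step.

## Trial table (`trials.csv`)

One row per trial.

| column | meaning |
| --- | --- |
| `subject` | integer subject index |
| `trial_id` | trial index within subject |
| `experiment` | `exp1` \| `exp2` \| `exp3` |
| `soa` | probe time in seconds after hue onset (exp3 only; empty otherwise) |
| `cue_present` | whether the luminance cue appeared (exp3) |
| `cued_stream` | `a` \| `b` \| `none` |
| `probed_stream` | `a` \| `b` \| `both` |
| `target_a`, `target_b` | probe-time target hues, degrees in [0, 360) |
| `response_1`, `response_2` | reported hues; `response_2` empty outside dual-report trials |
| `favored_stream` | generative ground truth of the synthetic observer (never consumed by analyses) |

Readers validate that hues lie in [0, 360) and that any `error*` column lies
in [−180, 180], reporting the first offending row.

## Error table (output of `huetrack pair`)

`subject, trial_id, response_slot (1|2|single), assigned_target (a|b),
error` — signed response − target differences in (−180, 180].

## Fit report (`fit_*.yaml`)

Components (`mu_deg`, `kappa`, `weight`), `loglik_nats`, `n_samples`,
`converged`, `n_iter`, `sd_precise_deg`, `sd_imprecise_deg`, `ratio`,
`seed`. An optional companion CSV holds per-sample responsibilities.

## Run config (YAML)

Fields of `huetrack.RunConfig`: `seed`, `experiment`, `out_dir`,
`n_subjects`, `n_trajectory_pairs`, `observer` (ObserverModel overrides),
`stimulus` (trajectory-generator overrides), `mu_bound`, `n_restarts`,
`n_sim`, `n_perm`, `pad_to`, `pairing_strategy`.
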