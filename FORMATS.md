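# File formats

## Trial table (CSV)

Long format, one row per trial, UTF-8, LF newlines, floats written at
fixed precision (`%.6f`). Written by `seqhabit.io.write_trials`,
validated on read by `seqhabit.io.read_trials`.

Required columns, in order:

| column      | type  | domain                                   |
|-------------|-------|------------------------------------------|
| subject     | int   | any id; rows grouped per subject          |
| trial       | int   | consecutive 1..n within each subject      |
| s1_choice   | str   | `L1`, `R1`                                |
| transition  | str   | `common`, `rare`                          |
| s2_state    | str   | `green`, `yellow`, `red` (red: expt 2)    |
| s2_choice   | str   | `L2`, `R2`                                |
| reward      | float | 0/1 (binary task) or [−5, 5] (graded)     |

Optional columns:

| column        | type  | notes                                        |
|---------------|-------|----------------------------------------------|
| rt1, rt2      | float | stage latencies in milliseconds              |
| option_latent | str   | `""` or the executed sequence (`L1-L2`, ...);|
|               |       | simulation ground truth, never observable — |
|               |       | excluded from `observed` exports             |

When a task variant is supplied to `read_trials`, each row's
`transition` label is checked against its `(s1_choice, s2_state)` pair
and inconsistencies are reported with the row index.

## Evidence matrix (CSV)

Written by `seqhabit fit`: one row per subject (index column
`subject`), one column per model name, entries are log marginal
likelihoods (Laplace approximation).

## Analysis results (JSON)

Written by `seqhabit analyze`: one object per requested analysis.
Regression blocks contain `terms` (per-term `b`, `se`, `z`, `p`),
`n_obs`, `n_subjects`, `n_used`, `backend`, and `flags`.

## Manifests (JSON)

Every CLI command writes `<out>.manifest.json` (or `manifest.json` in
an output directory) containing the package version, the seed, the
full configuration, and its SHA-256 — sufficient to reproduce the
output exactly.
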