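# dfclearn

Directed functional connectivity of learning dynamics: a tested, fully
reproducible pipeline for simulating and analyzing block-design brain-network
time series from an associative-learning task, with two groups (healthy
controls, HC, and schizophrenia patients, SCZ).

The pipeline addresses a question from task-fMRI connectomics: during the
Early (linear) and Late (asymptotic) phases of associative learning, and
separately for memory Encoding and Retrieval, which *directed* interactions
between network nodes differ between groups?  Because subject-level data of
this kind are rarely deposited, the package ships a first-class synthetic
cohort generator with known ground truth, so every estimator and inference
step is testable end to end.

## What it computes

- **Block design**: an Encoding / Rest / Retrieval / Rest paradigm of 27 s
  epochs over 8 cycles at TR = 3 s (288 volumes); cycles 1–4 are the Early
  phase, 5–8 the Late phase.
- **Simulation**: per-epoch stable VAR(1) network dynamics
  `Z_t = c + B Z_{t−1} + E_t` with condition- and phase-specific coupling
  `B` per group (spectral radius < 1 enforced), restarting from the
  stationary distribution at each epoch boundary; recall behavior follows a
  Gompertz learning curve with binomial trial noise (9 items per retrieval
  block).
- **Directed connectivity (dFC)**: lag-1 MVAR coefficients `b_ij` (influence
  of node *j* on node *i*) estimated by OLS with per-coefficient standard
  errors and t statistics; lagged pairs never cross epoch boundaries.
  Default estimation is pairwise (one 2-node model per node pair), a full
  multivariate mode is available.  The default 6-node network (dlPFC, dACC,
  HPC, SP, FG, ITG) yields 30 directed edges per subject and condition×phase
  cell.
- **Behavior**: per-subject Gompertz fits
  `fraction correct = a·exp(−exp(b − c·t))` (a = asymptote / learning
  capacity; inflection at t = b/c) by bounded multi-start nonlinear least
  squares, plus a mixed group × block ANOVA with partial η² and Cohen's d
  group contrasts.
- **Inference**: edge-wise Welch t comparisons (HC ≠ SCZ) with
  Benjamini–Hochberg FDR across the 30 edges of each condition×phase cell
  (q < 0.05), relative-difference and direction labels, and Pearson
  covariate regressions (antipsychotic dosage PDD/DDD within patients; age
  and FSIQ across all subjects).

## Worked example

```bash
dfclearn run --out results/demo --seed 0
```

or equivalently in Python:

```python
import dfclearn as d
result = d.run_pipeline(write_outputs=False)
print(result.anova)
print(result.parameter_contrasts)
```

With the default configuration (24 HC vs 31 SCZ subjects, default
ground-truth coupling) this prints a behavioral ANOVA

```
      effect        F  df1  df2    mse      p  partial_eta_sq
       group  58.2026    1   53 0.0808 0.0000          0.5234
        time 121.3324    7  371 0.0215 0.0000          0.6960
group x time   1.1399    7  371 0.0215 0.3372          0.0211
```

— a strong main effect of time (learning) and of group (patients recall
less), no interaction — and group contrasts on the fitted curve parameters

```
      parameter  mean_HC  mean_SCZ      t     p  cohens_d
              a    0.896     0.782  2.931 0.005     0.758
inflection_time    1.155     2.349 -4.466 0.000    -1.167
```

showing the patients' lower learning capacity (asymptote a) and later
transition from the linear to the asymptotic regime (inflection b/c, in
blocks).  The four edge-statistic tables (Encoding/Retrieval × Early/Late,
30 rows each) flag exactly the directed edges whose generative coupling
differs between groups, e.g. for Early Encoding the reduced-in-SCZ
frontal–hippocampal–fusiform pathways `dlPFC->HPC`, `dlPFC->FG`, `HPC->FG`,
`dACC->dlPFC`, `HPC->dlPFC`, `FG->ITG`.

All outputs are plain tab-delimited text with JSON sidecars; the resolved
TOML configuration and a structured run log are written next to them, and a
rerun with the same seed is byte-identical.

CLI subcommands: `simulate`, `extract` (ROI sphere extraction from 4D
NIfTI), `fit-behavior`, `fit-mvar`, `compare`, `run`.

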