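# cealbp

A Markov cohort cost-utility model for chronic low back pain, comparing
pharmacopuncture (PPT) with physiotherapy (PT) over a 3-year horizon of
3-month cycles across three pain-severity states (mild / moderate / severe,
defined on NRS cut-offs <4 / 4–6 / ≥7).

The package provides:

- **`cealbp.model_core`** — the three-state cohort engine: validated
  transition models (with the 2-cycle mild row handled by `tunnel`,
  `matrix_root`, or `direct` per-cycle conventions), cohort traces, and
  annual discounting.
- **`cealbp.cea`** — discounted cost/QALY accrual under three perspectives
  (healthcare, restricted societal, full societal), ICER with dominance
  classification, net monetary benefit, and a convention-calibration
  harness that scores all 12 convention combinations against published
  base-case totals.
- **`cealbp.dsa`** — one-way deterministic sensitivity analysis over 29
  parameter ranges with proportional probability-row renormalization,
  ranked by NMB spread (tornado order).
- **`cealbp.psa`** — probabilistic sensitivity analysis (Beta utilities and
  scenario weights, Gamma costs, Dirichlet transition rows; 1,000
  iterations by default) with CE-plane exports, acceptability curves and
  probability-cost-effective summaries.
- **`cealbp.synthetic_trial`** — a patient-level trial simulator with known
  ground truth plus estimators that recover transition rows/Dirichlet
  alphas, pooled state utilities (method-of-moments Beta fits), and
  trapezoidal AUC QALYs.
- **`cealbp.config` / `cealbp.cli`** — YAML configuration loading with
  exhaustive validation, and a CLI covering every stage.

All model inputs ship in `src/cealbp/data/default_config.yaml` (documented
schema); no external data are required. Computation is in USD at the fixed
rate of 1,144.61 KRW/USD; the willingness-to-pay threshold is 30.5M KRW
(≈ 26,647 USD) per QALY.

## CLI

```bash
cealbp base-case --perspective all --out-dir out/       # Table-style summary + traces
cealbp dsa --perspective healthcare --out-dir out/      # tornado-ordered CSV
cealbp psa --iterations 1000 --seed 2026 --out-dir out/ # CE plane, CEAC, summaries
cealbp simulate --n-per-arm 50 --seed 7 --out-dir out/  # synthetic trial + recovery
cealbp calibrate --out-dir out/                         # convention residual table
```

Every run writes CSV/JSON artifacts carrying the config hash, seed, and the
convention tuple (`mild_handling_mode`, `cycle_correction`,
`discount_timing`) needed to regenerate it. A custom configuration can be
passed with `--config path/to/config.yaml`.

The calibrated default conventions are `direct` mild-row handling,
`half_cycle` (trapezoidal) accrual and `cycle_start` discounting, which
reproduce the published base-case totals to within 0.1%.

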