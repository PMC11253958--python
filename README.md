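# iogfr

Iohexol plasma-clearance GFR measurement with simplified-protocol
evaluation and method-agreement statistics.

The package computes measured GFR from concentration–time data under a
family of sampling protocols — the 10-hour/16-sample two-compartment
reference, one-compartment (slope-intercept) 4/5/6/7/8-hour protocols with
Bröchner-Mortensen correction, and a 4-sample reduced two-compartment
approximation — and quantifies how well a simplified protocol agrees with a
reference protocol on repeated-measures cohorts (Lin's CCC, total deviation
index, coverage probability, P10/P15, Bland-Altman limits, mountain curves,
random-intercept regression, patient-clustered bootstrap CIs). A synthetic
cohort generator with known two-compartment ground truth makes the whole
pipeline testable without patient data.

## Layout

| module | contents |
| --- | --- |
| `iogfr.pk_clearance` | domain types, sampling schedules, bi-/mono-exponential fits, Bröchner-Mortensen correction, DuBois BSA, `measure_gfr` pipeline |
| `iogfr.egfr_equations` | CKD-EPI (2009) and IDMS-traceable MDRD estimating equations |
| `iogfr.agreement_stats` | CCC, TDI, CP, P10/P15, Bland-Altman, mountain curve, mixed model, clustered bootstrap, `agreement_report` |
| `iogfr.synthetic_cohort` | cohort simulator with ground truth, Phase-A/B presets, assay-CV calibration |
| `iogfr.io`, `iogfr.cli`, `iogfr.plots` | CSV/XLSX round-tripping, `gfr` command line, diagnostic plots |

## Command line

```sh
# simulate a CKD cohort (writes concentrations.csv, covariates.csv, truths.csv)
gfr simulate --preset phase_b --seed 1 --out-dir out/sim

# per-study GFR table, one column per requested method
gfr fit --conc out/sim/concentrations.csv --cov out/sim/covariates.csv \
        --methods oc_8h_bm,oc_7h_bm,oc_6h_bm,oc_5h_bm,ckd_epi,mdrd \
        --out-dir out/fit

# agreement reports (JSON + CSV, optional plots) per method pair
gfr agreement --gfr-table out/fit/gfr_table.csv --ref oc_8h_bm \
              --test oc_7h_bm --test oc_6h_bm --test oc_5h_bm \
              --seed 1 --plots --out-dir out/agreement
```

Every command accepts `--config <file.toml|file.json>` to pre-fill options
(explicit flags win) and writes a `run_manifest.json` with the effective
configuration and library versions. Method labels: `ref_2c_10h`,
`oc_8h_bm` … `oc_4h_bm`, `popPK_approx`, `ckd_epi`, `mdrd`.

`popPK_approx` is a penalized 4-point bi-exponential fit standing in for a
published population-PK web tool whose priors are not public; it is never a
reimplementation of that tool.

## Units

Time is minutes since end of injection; concentration mg/L (≡ µg/mL); dose
mg; clearance mL/min; normalized GFR mL/min/1.73 m² via the DuBois BSA.
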