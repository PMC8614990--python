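# ipm — integrated process model toolkit

`ipm` builds an in-silico version of a multi-step purification process by
concatenating per-unit-operation specific-clearance regression models: the
pool concentration leaving one unit operation (UO) is the load of the next,
so parameter effects anywhere in the chain propagate to the drug-substance
(DS) result. On top of the Monte-Carlo engine it automates two
quality-by-design deliverables:

* **FMEA severity rankings** — a one-at-a-time grid parameter sensitivity
  analysis (PSA) produces out-of-acceptance (%OOA) curves at drug substance;
  the ratio of the simulated OOA slope to the maximum allowable ("critical")
  slope is mapped through a rubric to a severity rank, classifying critical
  process parameters (CPPs).
* **Proven acceptable ranges (PARs)** — per parameter, the contiguous range
  around the set point on which every CQA's OOA stays at or below the
  critical level (default 5%), with the most restrictive CQA setting each
  limit.

Model cells per UO×CQA may be: a multifactorial DoE model (clearance vs.
process parameters), a unifactorial load model (clearance vs. specific load
concentration), both (the DoE prediction corrected by the load model's
relative response), a fixed set-point clearance estimated from
manufacturing runs, or absent (pass-through). Clearance noise is sampled in
proportion to each model's RMSE; parameters are sampled normally with the
normal operating range spanning ±3 SD; OOA is evaluated with the sample SD
inflated to its upper one-sided χ² confidence limit.

Because real case-study data of this kind is proprietary, the package ships
a synthetic process generator (`ipm.synthetic`) producing chains with known
ground truth, simulated DoE datasets and set-point manufacturing runs, so
the entire fit → simulate → PSA → FMEA → PAR pipeline is testable.

## CLI

```bash
ipm synth    --seed 1 --out-dir run1          # synthetic chain + datasets
ipm fit      --chain run1/chain.yaml --doe-dir run1 \
             --mfg-runs-path run1/mfg_runs.csv --out-dir run1
ipm simulate --chain run1/fitted_chain.yaml --observed run1/mfg_runs.csv \
             --out-dir run1                   # plausibility check + trending
ipm report   --chain run1/fitted_chain.yaml --out-dir run1
             # PSA curves -> severity.csv -> par.csv + plots + manifest.json
```

`psa`, `fmea` and `par` run the individual stages (`fmea`/`par` consume a
`psa_curves.csv`). Defaults — 10 grid points, 1000 cycles per point, 5%
critical OOA, γ = 0.95, rubric bands 0.8/0.5/0.3 → 10/7/3/1 — live in
`RunConfig` and can be overridden via a YAML/JSON config (`--config`) or
flags. All randomness derives from the single master seed, so identical
configurations give byte-identical CSV outputs.

## Library sketch

```python
from ipm import (SyntheticSpec, make_chain, generate_doe_data,
                 generate_manufacturing_runs, fit_process_chain, run_ipm,
                 run_psa, assess_parameter, find_par)

chain, truth = make_chain(SyntheticSpec(rng_seed=1))
doe = generate_doe_data(chain, rng_seed=2)
mfg = generate_manufacturing_runs(chain, n=12, rng_seed=2)
fitted, diagnostics = fit_process_chain(chain, doe, mfg)
sim = run_ipm(fitted, n=1000, rng_seed=3)        # per-CQA %OOA at DS
curve = run_psa(fitted, "AT_p1", rng_seed=4)     # OOA across screening range
severity = assess_parameter(curve)               # FMEA ranking, is_cpp
par = find_par(curve)                            # proven acceptable range
```

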