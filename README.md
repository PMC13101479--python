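# loxkit

Quantitative analysis of **tunable low-rate Cre-lox recombination reporters**
in bacteria. A Cre-lox reporter population contains two heritable genotypes:
unrecombined (dark) cells carrying two lox sites and recombined (fluorescent)
cells carrying one. Under inducer exposure, cells convert irreversibly at a
low per-hour rate *k* that depends on the inducer concentration, so the
fluorescent fraction integrates exposure over time — the basis of
recombinase-based whole-cell biosensors (e.g. for arsenite) that record
transient, even anoxic, exposures for later aerobic readout.

`loxkit` implements the full analysis chain for such reporters, with a
synthetic-data layer so every stage is testable without instrument data:

- **synthetic_data** — closed-form switching curves, an exact stochastic
  jump-process generator whose mean-field limit is the logistic model,
  single-cell cytometry event synthesis (log-normal FL1-A/FSC-A per genotype,
  optional immature dim subpopulation), and plate-reader growth/fluorescence
  curves with blank wells.
- **cytometry** — control-derived gating ("lower boundary drawn to exclude
  the control strain", reproduced as a tail-quantile rule), fluorescent-cell
  fraction with binomial standard error `sqrt(p(1-p)/n)`, and median cell
  fluorescence with bootstrap error.
- **plate_reader** — blank averaging and the growth-normalized relative
  fluorescence `r_i(t) = (F_i(t)/F_i(0) - F̄_b(t)/F̄_b(0)) / (OD_i(t) - ŌD_b(t))`,
  its endpoint variant, and a sliding-window growth-rate estimate.
- **rate_inference** — per-replicate maximum-likelihood fits of the logistic
  model `f(t) = f_max / (1 + (f_max/f_0 - 1) e^{-kt})` (ensemble MCMC, flat
  priors, f_max bounded between the maximum measured fraction and 1) and its
  exponential small-fraction limit `f_0 e^{kt}`, selected by AICc; replicate
  ensembles summarized as mean curve, min–max envelope and k_min/k_mean/k_max.
- **biosensor_stats** — two-sided Welch's t-tests between successive inducer
  concentrations, Fisher combination across experiments, leakage summaries,
  serial-passage generation accounting `log2(ρ_i · D / ρ_{i-1})`, and
  stability-decline tracking.
- **pipeline** — a seeded simulate → gate → fit → report orchestrator with a
  hashed manifest, plus fixture generators for four study designs.

## Worked example

Numbered drivers under `analysis/` walk through the studies. For example:

```bash
python analysis/01_simulate_dose_response.py
python analysis/02_fit_recombination_rates.py
```

simulates 3 technical replicates at 4 inducer concentrations (7 time points
over 8 h, 20,000 gated cells per point) and prints the fitted dose-response:

```
 concentration   k_true    k_min   k_mean    k_max                              models
      0.000000 0.000000 0.000000 0.000000 0.000000 exponential,exponential,exponential
      0.000001 0.150000 0.124728 0.134131 0.139815 exponential,exponential,exponential
      0.000005 1.102941 1.081169 1.089507 1.095336          logistic,logistic,logistic
      0.000010 1.376147 1.387019 1.395673 ...               logistic,logistic,logistic
```

`k_mean` tracks the ground-truth rate at every concentration; AICc selects
the exponential model where the trajectory stays far below saturation (the
regime where f_max is unidentifiable) and the logistic model where
saturation is visible. At zero inducer only the exponential model is fitted
and the estimated rate is 0. `analysis/03_arsenite_detection.py` runs the
detection ladder (lowest detected concentration 15 nM on the synthetic
design, zero-inducer leakage ~0.12% median added recombined cells) and
`analysis/04_stability_passaging.py` tracks a −52% fluorescent-fraction
decline over 53.2 generations under a 2% per-generation selection
coefficient.

A `loxkit` command-line interface exposes the same stages
(`simulate`, `gate`, `normalize`, `fit`, `report`, `run`, `fixtures`).

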