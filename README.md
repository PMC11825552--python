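# txapk

Population pharmacokinetics of **tranexamic acid (TXA)** in adult cardiac
surgery with **cardiopulmonary bypass (CPB)** — a complete, tested
nonlinear mixed-effects analysis pipeline with a synthetic-cohort
generator, so the whole workflow runs end to end without access to the
original clinical data.

TXA is an antifibrinolytic given to limit bleeding in cardiac surgery.
CPB dilutes the blood, sequesters drug in the circuit, and alters renal
elimination, so TXA exposure under CPB differs markedly from the product-
information kinetics; because TXA is renally cleared and high doses are
associated with seizures, dosing wants to be individualized by body size
and renal function. The package is aimed at pharmacometricians and
methods-minded clinical pharmacologists who want a transparent, scriptable
implementation of this analysis: a two-compartment IV-bolus model with
covariates, FOCE estimation, likelihood-ratio covariate selection, and the
standard validation toolbox (CWRES diagnostics, visual predictive check,
nonparametric bootstrap).

## The model

Disposition is a two-compartment IV-bolus model, evaluated in closed form
and superposed over the double-bolus regimen (1000 mg at the start of
surgery and 1000 mg at CPB discontinuation). Typical values carry
power-law covariate effects; the final covariate model is

```
V1  (L)   = 12.77 x (BW / 61.4 kg)^0.911          V2  (L)   = 6.857
CL1 (L/h) = 3.263 x (CLcr / 61.0 mL/min)^0.752    CL2 (L/h) = 2.859
```

with creatinine clearance by Cockcroft-Gault and body surface area by
DuBois-DuBois. Between-subject variability is log-normal
(`P_i = TV(P) e^{eta_i}`, diagonal `omega^2`), the residual error combines
additive and proportional components
(`SD(c) = sqrt(sigma1^2 + (sigma2 c)^2)`), and the population fit
minimizes the FOCE-with-interaction objective (OFV = -2 x approximate log
marginal likelihood); nested models are compared at the -2 l.l.d. > 6.635
rule (chi-squared, 1 df, p < 0.01). See `docs/methods.md` for the full
account, including how the synthetic cohort reproduces the study design
(covariate medians/IQRs, CPB-timed second bolus, 0.5/1/2/5 h and 1/6/16 h
sampling, re-dosing drop rule landing at ~454 observations for 77
subjects).

## Worked example

```python
import txapk as tx

effects = (
    tx.CovariateEffect("v1", "bw", reference=61.4, exponent=0.911),
    tx.CovariateEffect("cl1", "clcr", reference=61.0, exponent=0.752),
)
theta = {"v1": 12.77, "v2": 6.857, "cl1": 3.263, "cl2": 2.859}

# typical patient at the cohort-median body weight with CLcr 60 mL/min
p = tx.apply_covariates(theta, effects, {"bw": 61.4, "clcr": 60.0})
print(f"CL1 = {p.cl1:.3f} L/h ({p.cl1*1000/60:.2f} mL/min), V1 = {p.v1:.2f} L")

# concentration profile under the double-bolus regimen (CPB ends at 2.833 h)
doses = [tx.DoseEvent(0.0, 1000.0), tx.DoseEvent(2.833, 1000.0)]
for t in (0.5, 2.0, 3.833, 18.833):
    print(f"C({t:>6.3f} h) = {tx.predict_conc(t, doses, p):6.2f} mg/L")

# simulate the full study design and recover the parameters by FOCE
ds = tx.simulate_dataset(seed=1)
fit = tx.fit_population(ds, tx.default_truth().model)
print(f"converged: {fit.converged}, OFV: {fit.ofv:.2f}")
```

prints

```
CL1 = 3.223 L/h (53.71 mL/min), V1 = 12.77 L
C( 0.500 h) =  62.44 mg/L
C( 2.000 h) =  36.27 mg/L
C( 3.833 h) =  74.07 mg/L
C(18.833 h) =   6.34 mg/L
converged: True, OFV: 2369.50
```

The first line is the model's typical clearance for a 61.4-kg patient with
mildly reduced renal function — visibly below the ~110 mL/min of
non-surgical product information, the clinical point of the analysis. The
profile shows the distribution-phase peak after each bolus (the second
bolus lands on residual drug, hence the higher 74 mg/L) and concentrations
still above commonly cited antifibrinolytic thresholds at +1 h, decaying
to ~6 mg/L by 16 h after re-dosing. The fitted typical values on this
synthetic cohort come back at `tv_v1 = 12.57 L` and `tv_cl1 = 3.04 L/h`
(%RSE ~5 and ~4), within a few percent of the generating values.

## Command line

Every stage is also exposed as a subcommand driven by a YAML config and a
single root seed (all outputs embed the config hash and seed and are
exactly regenerable):

```sh
txapk --seed 1 simulate --out cohort.csv
txapk --seed 1 fit --data cohort.csv --out fit.json
txapk --seed 1 covsearch --data cohort.csv --out ladder.csv
txapk --seed 1 vpc --data cohort.csv --out vpc.csv
txapk --seed 1 bootstrap --data cohort.csv --out boot.csv
txapk --seed 1 report --data cohort.csv --out gof.csv   # + four-panel figure
```

Datasets travel as NONMEM-style event-record CSV (ID/TIME/AMT/DV/EVID/MDV
plus covariate columns).

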