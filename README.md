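# nebpk — population pharmacokinetics of oral nebivolol

Nebivolol is a highly β1-selective third-generation beta-blocker whose
exposure varies strongly between people, largely because its hepatic
metabolism by CYP2D6 is polymorphic (oral bioavailability spans roughly
12% in extensive to 96% in poor metabolizers). `nebpk` implements, end to
end, a population-PK analysis of pooled literature concentration–time data
in young healthy adults, and uses the fitted model to ask a dosing
question: which regimen keeps the steady-state peak inside an efficacy
window of 1.0–2.0 ng/mL while letting the trough fall below a 0.5 ng/mL
safety threshold?

It is a library first (import `nebpk`), with narrative scripts under
`examples/` and a thin `nebpk` command-line front end for the pipeline
stages. It is written for pharmacometricians and for statisticians who
want a fully inspectable, pure-Python SAEM estimator rather than a vendor
black box.

## The model

Structural model: two-compartment disposition with first-order oral
absorption, absorption lag time and linear elimination. With apparent
(oral) parameters Tlag, ka, CL/F, V1/F, Q/F, V2/F, micro constants
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 and disposition exponents λ1, λ2
(roots of s² − (k10+k12+k21)s + k10·k21), the concentration after a dose D
at shifted time t′ = t − Tlag is the standard triexponential

C(t′) = (D·ka/V1) · [A1·e^(−λ1 t′) + A2·e^(−λ2 t′) + A3·e^(−ka t′)],

superposed over dose events for multiple dosing. Doses are in mg and
concentrations in ng/mL; apparent volumes and clearances are carried in
units of 10³ L and 10³ L/h so that amount/V1 evaluates directly in ng/mL
(see `docs/methods.md` for why this convention is the one consistent with
the reported estimates).

Statistical model: lognormal inter-individual variability per parameter,
multiplicative covariate effects (age as a power law on CL; CYP2D6
genotype class shifts on CL, V1 and Tlag), and proportional residual error
y = f·(1 + b·ε). Estimation is maximum likelihood by SAEM
(Metropolis-within-Gibbs E-step, exact Gaussian M-step, two-phase step
sizes with simulated annealing), with importance-sampling OFV, AIC/BIC,
empirical Bayes estimates, Louis-identity standard errors, forward/backward
covariate search on the EBEs, and IWRES/NPDE/VPC diagnostics.

Dosing-regimen evaluation: Monte-Carlo cohorts (default 1000 virtual
subjects, 15 days of treatment) are scored per regimen; because the
individual parameters behind the published attainment figures are not
available, the between-subject exposure distribution is a single lognormal
subject-level factor whose location and spread are calibrated so that
simulated attainment reproduces the published 5 mg (72.2%) and 10 mg
(22.6%) once-daily efficacy references; everything else is prediction.

## Worked example

`python examples/04_regimen_attainment.py` calibrates the exposure
distribution on the two reference doses and scores all eight regimens:

```
calibrated exposure distribution: location shift delta=-0.241 (log scale), spread sigma=0.291
anchors reproduced at n=100000: 72.4% and 22.6%

   regimen    n  efficacy_pct  safety_pct
   5 mg qd 1000          71.2        46.5
  10 mg qd 1000          24.6         0.6
  20 mg qd 1000           0.1         0.0
 2.5 mg qd 1000           4.1        98.8
2.5 mg BID 1000          40.2        28.9
2.5 mg q6h 1000          73.4         0.0
 6 mg q36h 1000          71.3        86.4
 6 mg q48h 1000          63.3        98.9
```

Reading the table: `efficacy_pct` is the share of the cohort whose day-15
dosing-interval peak lies in 1.0–2.0 ng/mL, `safety_pct` the share whose
day-15 trough is below 0.5 ng/mL. The once-daily doses trace the expected
unimodal pattern (5 mg best, 10 mg overshooting for a quarter of subjects,
2.5 and 20 mg essentially outside the window), and the 6 mg q36h proposal
holds efficacy at the 5 mg level while nearly doubling the fraction of
subjects whose troughs wash out below 0.5 ng/mL — the qualitative case for
spacing doses of a drug with a ~40 h terminal half-life.

`examples/03_saem_fit.py` shows the estimation side: a 30-subject study
simulated at the final estimates is re-fitted by SAEM,

```
parameter    truth  estimate    RSE%
tlag          0.30     0.313     4.5
ka            2.06     2.211     7.8
cl            0.22     0.189    10.5
v1            4.21     4.444     4.6
q             0.59     0.547     5.1
v2            7.12     9.319    11.7
b             0.13     0.135     6.6
```

i.e. every population parameter is recovered within a few standard errors.

## Command line

```sh
nebpk simulate-cohort --seed 7 --out run/      # synthetic 30-subject study
nebpk fit --data run/cohort.csv --out run/     # SAEM fit -> fit.json, ebes.csv
nebpk select-model --data run/cohort.csv --out run/
nebpk nca --data run/cohort.csv --out run/
nebpk regimens --plans presets --n 1000 --seed 7 --out run/
nebpk diagnose --data run/cohort.csv --out run/
```

Every run writes a JSON log with the seed, versions and timings.

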