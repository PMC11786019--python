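# hdmtx

Pharmacokinetics and transporter pharmacogenetics of high-dose methotrexate
(HD-MTX) consolidation in pediatric acute lymphoblastic leukemia.

In the consolidation phase studied here, children receive four courses of
5 g/m² methotrexate as a 24 h infusion (10% of the dose as a 0.5 h loading
segment), with plasma levels monitored at 24 h (end of infusion), 42 h, and —
when excretion is delayed — every 6 h thereafter. The scientific questions
the package addresses are the ones a TDM/pharmacogenetics group asks of such
data:

1. **How fast does each patient clear the drug?** Two or three timed plasma
   levels per course cannot identify a full kinetic model, so per-course
   clearance is estimated by **maximum-a-posteriori (MAP) fitting** of a
   two-compartment linear model with first-order elimination,

   dA_c/dt = R(t) − (k_e + k_cp)·A_c + k_pc·A_p,
   dA_p/dt = k_cp·A_c − k_pc·A_p,  C = A_c/V,  CL = k_e·V,

   under informative log-normal priors (V = 9.03 ± 4.70 L/m², k_e = 0.7 ±
   0.22 h⁻¹, k_cp = 0.08 ± 0.050 h⁻¹, k_pc = 0.11 ± 0.0038 h⁻¹).
2. **Who is over-exposed?** Protocol threshold flags (150 µM at 24 h, 1 µM at
   42 h, 0.5 µM at 48 h) and cohort quartiles of mean level / mean clearance
   (high exposure = level-Q4 or clearance-Q1).
3. **Do transporter variants matter?** Six candidate SNPs in *SLCO1B1*,
   *ABCB1*, *ABCC2*, *ABCC3* and *ABCC4* are coded under additive, dominant
   and recessive models and tested against severe hematological (HEM) and
   gastrointestinal (GI) toxicity (Fisher's exact test with the
   conditional-MLE odds ratio), PK endpoints (Gaussian linear and mixed
   models with likelihood-ratio tests), and relapse (Cox proportional
   hazards), with explicit multiplicity control.

Because the underlying patient-level data are not public, the package ships
a first-class **synthetic cohort generator** that reproduces the study's
data structure (sampling design, age- and genotype-dependent clearance,
genotype-dependent toxicity and relapse), so every stage is testable
end-to-end.

## Worked example

Fit one course from its three monitored levels (the cohort-median profile):

```python
from hdmtx import ConcentrationSample, fit_course, protocol_schedule

schedule = protocol_schedule(5000)           # 5 g/m2 over 24 h, 10% loading
samples = [ConcentrationSample(course=1, time_h=24.0, conc_um=41.1),
           ConcentrationSample(course=1, time_h=42.0, conc_um=0.54),
           ConcentrationSample(course=1, time_h=48.0, conc_um=0.39)]
res = fit_course(samples, schedule, dose_g_m2=5.0)
print(res)
print(res.summary().round(4))
```

```
<CoursePKResults CL=167.2 mL/min/m2 V=12.38 ke=0.811 kcp=0.064 kpc=0.110 converged=True>
                estimate  se_log
V                12.3758  0.2448
ke                0.8108  0.2269
kcp               0.0639  0.3190
kpc               0.1098  0.0344
CL (mL/min/m2)  167.2346     NaN
```

The estimated clearance (167 mL/min/m²) sits where a typical patient in this
protocol lands (cohort median ≈ 160 mL/min/m²); the log-scale standard
errors show what the sparse design identifies — clearance tightly, the
distribution constants mostly through the prior.

Test a genotype against severe toxicity from a 2×2 table (variant carriers
20/27 with severe HEM vs 20/53 among wild-type homozygotes):

```python
from hdmtx import ContingencyTable2x2, fisher_exact

res = fisher_exact(ContingencyTable2x2(20, 7, 20, 33,
                                       ("rs717620 CT+TT", "CC"), "severe HEM"))
print(f"OR = {res.estimate:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"p = {res.pvalue:.2e}")
```

```
OR = 4.62 (95% CI 1.54-15.39), p = 4.11e-03
```

The odds ratio is the conditional MLE given both margins (the estimate
conventionally reported with Fisher's exact test), with its exact
conditional confidence interval.

A full pipeline runs from the shell:

```bash
hdmtx simulate --n 200 --seed 7 --out run/sim
hdmtx fit      --conc run/sim/concentrations.csv --out run/fit
hdmtx exposure --conc run/sim/concentrations.csv \
               --summary run/fit/patient_summary.csv --out run/exp
hdmtx associate --patients run/sim/patients.csv \
                --exposure run/exp/exposure_classes.csv --out run/assoc
hdmtx report   --results run/assoc/association_results.csv --out report.txt
```

Every stage writes its resolved configuration next to its outputs, and the
whole chain is byte-for-byte reproducible for a fixed seed.

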