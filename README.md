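# hazstrat

Optimal fitting of multiplicative and additive hazards regression models
for right-censored survival data.

Clinical survival data can be modelled two ways: multiplicatively, where
covariates scale the baseline hazard — the Cox model
λ(t|x) = λ₀(t)·exp(x′β), yielding hazard ratios — or additively, where
they shift it — Aalen's model λ(t|x) = λ₀(t) + x′α(t) and Lin's
constant-coefficient special case λ(t|x) = λ₀(t) + x′γ, yielding hazard
differences. Each family rests on assumptions (proportional hazards and
log-linearity for Cox; linearity and, for Lin, constant effects for the
additive family) that must be checked and, when violated, repaired with
functional forms f(x) or time-varying coefficients β(t). `hazstrat` is a
toolkit for epidemiologists and biostatisticians that implements both
families, the full battery of diagnostics — Schoenfeld and martingale
residuals, jackknife pseudo-observations (cloglog- and scaled-log-
transformed), stratified martingale residual processes with wild-bootstrap
bounds and chi-square tests, and Arjas observed-vs-expected curves — and
two automated step-by-step fitting procedures (one per family) that
iterate diagnostics → model refinement and emit a complete JSON audit
trail. A synthetic-data module generates survival data with known
multiplicative or additive structure for validation.

## Worked example

Simulate a cohort whose binary exposure has a linearly decaying log-hazard
ratio β(t) = 0.8 − 0.4t, detect the violation, and repair it:

```python
import hazstrat as hs

scn = hs.SimScenario(
    n=2000, family="multiplicative", baseline=0.4,
    covariates={"z": ("bernoulli", 0.5)},
    effects={"z": hs.EffectSpec(((0.0, 0.8), (3.0, -0.4)))},  # 0.8 - 0.4 t
    censoring_time=3.0,
)
sample = hs.simulate_multiplicative(scn, seed=17)

plain = hs.fit_cox(sample, ["z"])
print(hs.ph_test(plain))

extended = hs.fit_cox(sample, ["z"],
                      time_varying={"z": hs.TimeVaryingSpec("linear")})
print(extended.summary()[["coef", "se", "p"]])
print("AIC plain %.2f -> extended %.2f" % (hs.aic(plain), hs.aic(extended)))
```

Output:

```
  correlation         p satisfied
z    -0.11901  0.000004     False
         coef        se             p
z    0.714171  0.087654  3.710285e-16
z:t -0.317672  0.068280  3.279169e-06
AIC plain 21049.66 -> extended 21029.44
```

The Schoenfeld-residual correlation test rejects proportionality
(p ≈ 4·10⁻⁶); the extended model with a linear time basis recovers the
generating coefficients (0.71 vs 0.8 and −0.32 vs −0.4, each within two
standard errors of the truth) and improves the AIC by 20.

The same analysis runs end-to-end from a shell:

```bash
hazstrat run --data data.csv --arm both --outdir report/
```

which writes `multiplicative_report.json` / `additive_report.json` (the
ordered audit trail: every diagnostic value, decision and model revision)
plus coefficient and cumulative-regression CSVs.

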