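# rbcage

Estimating how long red blood cells live is central to the differential
diagnosis of anemia — hemolytic disease destroys erythrocytes early — yet
the classical measurement, following ⁵¹Cr-labelled cells over weeks, is
laborious and the isotope is no longer available in some countries.
**rbcage** implements an alternative: the erythrocyte creatine concentration
(EC) of a single blood sample encodes the mean age of the circulating cells,
because young red cells import creatine through a transporter whose activity
decays over the cell's life.

The package is a library for clinical chemists and hematology researchers,
with a thin `rbcage` command-line tool on top. It provides:

* the log-linear calibration between mean erythrocyte age *M*<sub>RBC</sub>
  (days) and EC (μmol/g Hb), and its inverse estimator

  ln EC = *a*·*M*<sub>RBC</sub> + *b*  ⇔  *M*<sub>RBC</sub> = −22.84 ln EC + 65.83

  with the reference coefficients *a* = −0.04379/d, *b* = 2.882
  (*r* = −0.9475, *n* = 21, df = 19, *t* = 12.92, *p* = 7.4 × 10⁻¹¹),
  calibrated on EC 1.45–11.76 μmol/g Hb;
* unit conversion between mg/dL of red cells and μmol/g Hb
  (divisor MW × MCHC / 1000 = 4.328 at MCHC 33 g/dL), with per-subject MCHC
  overrides;
* ⁵¹Cr survival arithmetic: the ×2.61 (= 60/23) half-life → mean-age rule
  and a fixed-lifespan survival model with label elution that explains it;
* a mechanistic creatine-kinetics model
  (dC/dt = B e^(−λ₂t) − λ₁(C − C_p)) whose population average reproduces the
  near-log-linear EC–age relationship within the clinical range;
* a seeded synthetic-cohort generator (empirical and mechanistic modes)
  emulating the statistical structure of the 21-patient reference dataset.

## Worked example

```python
from rbcage import estimate_mrbc, published_model

est = estimate_mrbc(1.4, published_model())
print(round(est.m_rbc, 2), round(est.lifespan, 2), est.extrapolated)
```

prints

```
58.14 116.29 True
```

A standard EC of 1.4 μmol/g Hb maps to a mean cell age of 58.14 days
(close to the textbook 60 days; lifespan = 2 × mean age under the
uniform-age model). The `extrapolated` flag is raised because 1.4 sits just
below the calibrated EC range minimum of 1.45 μmol/g Hb. A severely
hemolytic EC of 11.76 μmol/g Hb instead gives 9.54 days — the circulating
population is dominated by young cells.

The same from the shell:

```bash
rbcage estimate --ec 1.4          # -> 58.14
rbcage convert --value 6.0592 --from-unit mg_dl_rbc   # -> 1.4 umol_gHb
rbcage simulate --n 21 --seed 7 --out cohort.csv
rbcage calibrate --in cohort.csv --out model.json
```

The `examples/` directory holds one short narrative script per capability
(estimation, unit conversion, ⁵¹Cr survival, the kinetic curve, cohort
simulation and refitting); each prints the numbers it computes and a line on
what they mean. `docs/methods.md` documents the models, defaults and known
limitations.

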