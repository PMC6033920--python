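# thermaltime

Growing degree days (GDD) are the standard developmental clock of crop
modelling: daily thermal time (DTT, °C·d) is accumulated from sowing, and a
phenological stage (emergence, jointing, heading, tasseling, milk, maturity)
is predicted to occur when the running total reaches a calibrated
requirement.  The classic ways of computing DTT assume development responds
*linearly* to temperature, which breaks down whenever afternoons climb past
the crop's optimum temperature — development then slows, but a linear clock
keeps ticking faster.

`thermaltime` implements four thermal-time methods behind one interface,
all parameterised by the cardinal temperatures T_b (base), T_opt (optimum)
and T_u (upper threshold):

| method | response | input |
|---|---|---|
| `method1` | linear in T_avg = (T_max+T_min)/2, capped at T_u − T_b | daily |
| `method2` | as method1 with T_max/T_min clamped into [T_b, T_u] first | daily |
| `method3` | bilinear hourly response with a sharp peak at T_opt | hourly |
| `bfm` | smooth beta-function hourly response | hourly |

The beta-function method (BFM) computes hourly thermal time as

```
HTT(T_h) = (T_h − T_b)/(T_opt − T_b) · [(T_u − T_h)/(T_u − T_opt)]^((T_u − T_opt)/(T_opt − T_b)) · (T_opt − T_b)
```

zero at T_b and T_u, maximal (T_opt − T_b) exactly at T_opt, and asymmetric
around the optimum the way measured developmental rates are.  Daily DTT for
the hourly methods is the mean of 24 HTT values; hourly temperatures come
from daily extremes through a pluggable disaggregation scheme (default: a
cosine diurnal wave peaking at 14:00), or can be supplied directly.

On top of the four clocks the package provides the full evaluation
protocol used to compare them:

* **Calibration** of per-stage GDD requirements from multi-year
  phenology records, with phase-dependent cardinal sets (winter wheat
  switches from 0/24/45 °C to 8/29/40 °C at heading).
* **CV in days** — SD of the annual stage GDD divided by mean daily GDD —
  the across-year consistency of each clock.
* **Willmott's refined index of agreement d_r** between observed and
  predicted stage dates.
* **Normalized logistic dry-matter fits** `y = 1/(1 + exp(a + b·GDD))`
  scored by RMSE.
* **Sensitivity analysis** perturbing one cardinal temperature at a time by
  {−4, −2, −1, +1, +2, +4} °C.
* A **synthetic-data module** (annual sinusoid + AR(1) noise weather,
  threshold-inverted stage dates, logistic biomass) so the whole pipeline is
  testable with known ground truth and no external archive.

Shipped crop parameter sets: corn 8/33/40 °C; spring wheat 0/24/42 °C;
winter wheat 0/24/45 °C (vegetative) and 8/29/40 °C (reproductive).

## Worked example

Simulate eight spring-wheat seasons in the shipped hot-desert climate
preset (stage dates generated under the beta response), then ask how
consistently each method's clock places the stages across years:

```sh
thermaltime simulate --preset arid-hot --crop spring-wheat --method bfm \
    --years 8 --seed 11 --out demo
thermaltime evaluate --weather demo/weather.csv --phenology demo/phenology.csv \
    --crop spring-wheat --out demo/eval
```

`demo/eval/cv.csv` pivoted to CV-in-days per stage and method:

```
method     method1  method2  method3   bfm
stage
emergence     0.78     0.81     0.68  0.47
jointing      1.99     2.03     0.63  0.42
heading       2.58     2.60     0.64  0.20
milk          2.96     2.99     0.75  0.37
maturity      3.45     3.46     0.59  0.35
```

Read it as: the thermal-time requirement for maturity under method 1 varies
across years by the equivalent of 3.5 calendar days, but only 0.35 days
under BFM.  In this climate most summer hours exceed the wheat optimum of
24 °C; the linear methods keep crediting those hours at full rate, so their
clock runs inconsistently from year to year, while the beta response, which
slows development above the optimum, stays steady.  In a mild climate (the
`temperate-mild` preset) all four methods agree within a day.

The same pipeline is available as a library:

```python
import thermaltime as tt

ct = tt.get_crop("corn").phases[0].cardinal   # 8/33/40 °C
tt.daily_dtt(30.0, 18.0, ct, "bfm")           # one day's thermal time
```

Other subcommands: `gdd` (per-method DTT/GDD series for a weather file),
`stages` (requirement calibration), `fit-dm` (logistic dry-matter fit, with
`--plot` overlay), `sensitivity` (cardinal-temperature grid), `simulate`
(synthetic fixtures + ground-truth sidecar).  Every run writes a
`manifest.json` with the configuration, seed and package version;
re-running with the same inputs reproduces the outputs byte for byte.

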