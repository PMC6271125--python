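# spmekin

Second-order kinetic modelling of flavor release measured by headspace
solid-phase microextraction (HS-SPME).

## The problem

HS-SPME/GC quantification of light, aroma-active esters is notoriously
irreproducible: the amount of analyte on the fiber depends on a competitive
adsorption/desorption balance, so raw peak areas vary strongly between
replicate extractions.  A practical way out is to fit each replicate's
*extraction-time profile* — GC peak area versus SPME exposure time — with a
kinetic model and report the model parameters instead of single-point areas:
the parameters are far more reproducible than the measurements themselves.

`spmekin` is for analytical chemists and modellers who have such
replicate extraction-time profiles (typically triplicates over minutes to
hours, showing a rise, an overshoot and a plateau) and want reproducible
kinetic characterization of them.

## The model

The amount of an analyte on the fiber is the net of two parallel
first-order processes, adsorption onto and release from the coating:

    C_ads(t) = k1 (1 − e^(−t/τ1))
    C_rel(t) = k2 (1 − e^(−t/τ2))
    C(t)     = C_ads(t) − C_rel(t)

with equilibrium constants `k1 > k2 > 0` (peak-area units) and time
constants `τ1 < τ2` (minutes; adsorption is the faster process).  Derived
quantities, in closed form:

    C∞    = k1 − k2
    t_max = τ1 τ2 / (τ2 − τ1) · ln(k1 τ2 / (k2 τ1))
    C_max = C(t_max)

Each replicate's profile is normalized by its final-time area (treated as
the equilibrium point) and fitted by bound-constrained weighted least
squares, where the observed peak sample carries a weight `W ≥ 1` and all
other samples weight 1 (*inner loop*).  A shared `W` is then optimized per
compound to minimize

    F = RSD(k1) + RSD(k2) + RSD(τ1) + RSD(τ2)

the summed relative standard deviations of the four parameters across the
triplicate fits (*outer loop*).  `W` trades fidelity at the characteristic
peak point against the remaining samples and is what makes the parameters
reproducible when replicates disagree about where or how high the peak is.
Hold-out validation withholds one late-time sample per replicate from the
fit and compares the model prediction against it.

## Worked example

Simulate a triplicate from the ethyl-octanoate preset (normalized
parameters k1 = 174.2, k2 = 173.2, τ1 = 58.30, τ2 = 59.08; 1% replicate
jitter, 3% multiplicative noise), hold out the 300-min point, and run the
two-loop fit:

```python
from spmekin import FitConfig, ReplicateKinetics, generate_replicates, preset_scenarios

scenario = preset_scenarios()["ethyl_octanoate_40C"]
replicates = generate_replicates(scenario, seed=1)
model = ReplicateKinetics(replicates, config=FitConfig(seed=1), validation_time=300.0)
results = model.fit(w_bounds=(1.0, 1000.0))
print(results.summary())
```

```
Second-order SPME release kinetics — two-loop fit
==========================================================
Compound:   ethyl octanoate
Condition:  beverage 40C
Replicates: 3   Converged: True
Weighting factor W: 7.38    F (sum of RSDs): 0.8675 %
Total RMSE (normalized scale): 0.07988
----------------------------------------------------------
 parameter           mean      RSD %
        k1         106.04          0
        k2        105.069      0.019
      tau1         58.588      0.364
      tau2        59.9212      0.485
----------------------------------------------------------
 replicate           k1      tau1      tau2      RMSE
         1       105.73     58.56     59.88    0.0123
         2       107.12     58.39     59.65   0.04391
         3       105.27     58.81     60.23   0.02366
Hold-out validation time: 300 min
```

Reading the output: the outer loop settled at `W = 7.38`, where the summed
parameter RSD is `F = 0.87%` — every parameter reproduces across the
triplicate to better than 0.5%, and the fitted time constants (≈58.6 and
≈59.9 min) recover the generating values within ~1.5%.  The total RMSE of
0.080 means each replicate's curve misfit is ≈0.03 on the normalized scale,
i.e. at the level of the injected measurement noise.  (The amplitudes k1,
k2 are reported under a fixed gauge — see `docs/methods.md` — only their
difference, the plateau, is determined by the data.)
`results.validate()` then predicts the withheld 300-min samples; for this
run the largest discrepancy is 3.3%.

The same pipeline is scriptable from the shell:

```
spmekin simulate --scenario ethyl_octanoate_40C --seed 1 --out profiles.csv
spmekin fit --input profiles.csv --output-dir fits/ --seed 1 --validation-time 300
```

which writes a per-compound summary table (`fits.csv`), per-replicate
parameters, a validation report and a JSON run manifest.

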