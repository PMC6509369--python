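# opsel

Spatially explicit analysis of the **opportunity for sexual selection** in
polygynous, band-living populations, built around mark–resight survey
records of the kind collected for island feral-horse systems (one dominant
stallion per band with a harem of mares, unattached bachelor males, 8–10
island-wide census occasions per breeding season).

For each harem-holding male the package computes Crow's index

    I = Var(f) / E[f]²   (f = qualified mares per male)

over the male's *buffer-overlap neighborhood* — all bands and bachelors
whose season sighting locations fall within a fixed radius (2.06 km by
default) of his band's locations — and partitions it into sequential
selection episodes: acquiring a harem (`I_harem`, which reduces to
(1 − p)/p for a local harem-holder fraction p) and acquiring mares given a
harem (`I_mares|harem`).  It then runs the two-stage mixed-model
inference: (1) local adult sex ratio (ASR) as the fixed effect with male
identity as a random intercept (maximum likelihood, Satterthwaite F
tests, marginal R²); (2) AICc competition of residual-based models —
null, year, and year × {distance from permanent freshwater, unpaired-male
density, total density} — plus a Gaussian spatial-correlation check and a
post hoc polynomial regression of the annual distance-from-water slopes
on climate.

Because field datasets of this kind are rarely redistributable, the
package ships a first-class synthetic island generator
(`opsel.synth`) that reproduces the survey's statistical structure
(52–79 bands/year over five years, harem sizes ≈ 2.1–2.7, mean 2.84
repeat sightings per individual, an east–west permanent-water gradient on
a 49 × 1.5 km island) and can *plant* known covariate effects, so the
whole inference chain is testable as a parameter-recovery experiment.

Audience: behavioral/evolutionary ecologists analysing mating inequality
from individual-based spatial survey data, and anyone needing a compact,
tested reference implementation of episode-partitioned selection
opportunity with neighborhood statistics.

## Worked example

```python
from opsel import pipeline

manifest = pipeline.run_pipeline(pipeline.RunConfig(seed=42,
                                                    spatial_check=False))
```

Running `python examples/03_two_stage_models.py` (which does the above and
prints the results) gives:

```
modelled 335 male-years of 108 males
stage 1 I: ASR slope -0.121, marginal R² 0.00, F = 0.8 (Satterthwaite df 333)
stage 1 I_harem: ASR slope +3.885, marginal R² 0.74, F = 944.7 (Satterthwaite df 308)
stage 1 I_mares_given_harem: ASR slope +0.158, marginal R² 0.01, F = 3.1 (Satterthwaite df 316)

stage 2, harem-acquisition episode (AICc competition):
                                    model  k   dAICc  weight  marginal_r2
       Unpaired adult male density x year 12   0.000     1.0        0.435
                     Total density x year 12  75.285     0.0        0.330
Distance from permanent freshwater x year 12 156.192     0.0        0.139
                                     Year  7 157.659     0.0        0.109
                                     Null  3 189.182     0.0        0.000
```

Reading this: 335 male-years (one per band-season over five years) enter
the models.  ASR explains most of the harem-acquisition episode (marginal
R² 0.74 — ASR and harem-holding are both expressions of male–male
competition) but little of the other episodes at this seed.  After ASR is accounted
for, the unpaired-male-density model carries essentially all the Akaike
weight for the harem episode — which is correct, because the generator
planted exactly that effect.  `examples/04_climate_posthoc.py` shows the
year-specific distance-from-water slopes switching sign between average
and extreme precipitation years, and the concave quadratic
climate fit that recovers an exactly-planted polynomial with R² = 1.

The `examples/` scripts cover each capability in order: simulation,
selection metrics, the two-stage models, the climate post hoc, and the
recovery experiment.  A thin CLI wraps the same pipeline:
`opsel all --seed 42 --out runs/demo` (subcommands `simulate`, `metrics`,
`fit`, `compete`, `posthoc`, `all`).

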