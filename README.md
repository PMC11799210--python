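# thermobias

Thermal-bias and occupancy-response analysis for fossil marine benthos.

## The problem

When regional seas warm, which species immigrate, which persist, and which
are lost? A species' **thermal bias** — the difference between its long-term
thermal preference and the ambient water temperature where it lives —
summarises how well matched a population is to its local climate. For marine
ectotherms (bivalves, brachiopods, gastropods), a species whose preference
sits below the local ambient is near its warm niche edge and is a candidate
for extirpation under further warming, while species with warmer-than-ambient
preferences are the expected immigrants.

`thermobias` implements this analysis end-to-end for fossil occurrence data
binned to ordered stratigraphic time bins (ammonite zones) with modelled
sea-surface-temperature fields as the climate input. It is written for
paleoecologists and macroecologists who want to link climate change across
bin boundaries to species- and assemblage-level occupancy change, with a
fully synthetic test world providing ground truth for every estimator.

## Core quantities and models

- **STI** (species temperature index): the median of ambient summer SST
  sampled at all of a species' occurrences across the study interval.
- **Thermal bias**: `bias = STI − T_region`, positive when a species prefers
  warmer water than locally available. **CTI** (community temperature index)
  is the median of member STIs; assemblage bias is `CTI − T_region`.
- **Occupancy responses** around each bin boundary *i → i+1*, per region,
  using two-timer rules (two consecutive regional presences required so
  single-bin sampling artifacts are suppressed), encoded as an ordered
  response: originating = 1, immigrating = 2, persisting = 3,
  extirpated = 4, extinct = 5. A three-timer variant is available.
- **Species-level model**: `response ~ thermal_bias (+ ΔT + clade +
  interactions)` as a linear mixed model with random intercepts nesting
  species within regions within time zones (REML; marginal and conditional
  R² by variance partition).
- **Meta-regression**: per-(region, boundary) slopes of bias on response
  level, regressed on the regional warming magnitude ΔT with 1/SE² weights.
- **Assemblage models**: percentages of assemblages extirpated/immigrating,
  Jaccard turnover, and bias change, each regressed on assemblage bias or
  ΔT with regions nested in time zones; predictions with CIs at a stated
  warming (default +3 °C).

Supporting stages: PBDB-style occurrence ingest with habitat categorisation
(carbonate/siliciclastic substrate, shallow/deep bathymetry) and exact
binomial environmental-affinity tests; gridded SST handling with bilinear
downscaling, coastal nearest-neighbour sampling and field comparison
(Spearman rho, RMSE); bioregionalisation by hierarchical clustering of
paleocoordinates validated against Jaccard clustering of species incidence.

## Worked example

Run the full chain on the default synthetic world (500 species, 5 regions,
6 bins spanning cold stasis → two warming pulses → transition → warm
stasis):

```python
import thermobias as tb

result = tb.run_pipeline(tb.RunConfig(preset="tracking", seed=1))
print(result.species_result.summary())
```

```
Species occupancy response ~ thermal bias (nested mixed LM, REML)
========================================================================
n_obs: 2173
R2 marginal: 0.196   R2 conditional: 0.212
random intercepts: zone+region
------------------------------------------------------------------------
term                                       coef      se       t        p
Intercept                                 2.956   0.037   79.06        0
thermal_bias                             -0.102   0.005  -19.47  6.3e-78
========================================================================
```

The thermal-bias coefficient of −0.102 per °C means that a species whose
preference sits 10 °C below ambient sits, on average, a full response level
further toward extirpation than a perfectly matched species. Assemblage
predictions at a modern-relevant +3 °C regional warming:

```python
for name in ("pct_immigrating", "pct_extirpated"):
    p = result.predictions[name]
    print(name, f"{p['prediction']:.1f}% [{p['ci_low']:.1f}, {p['ci_high']:.1f}]")
```

```
pct_immigrating 43.1% [24.9, 61.3]
pct_extirpated 20.1% [12.7, 27.6]
```

The same chain runs from the command line:

```bash
thermobias run-all --preset tracking --seed 1 --outdir out/
thermobias sensitivity --preset tracking --axis scheme=two_timer,three_timer
```

File-based runs take an occurrence CSV/TSV, one SST field (NetCDF or
gridded CSV) per time bin, and a FAD/LAD table; see
`tests/test_pipeline.py::test_file_based_run_roundtrip` for a complete
round trip.

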