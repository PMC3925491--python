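# rivaq

Tools for locating and quantifying water exchanges between a large river
and its lateral shallow aquifers, combining a hydraulic diagnosis with two
biological indicators along a river corridor.

Water managers need to know which river reaches recharge the alluvial
aquifer (losing reaches) and which are fed by groundwater upwelling
(gaining reaches) — without building a full gridded groundwater model.
`rivaq` implements a lightweight three-line-of-evidence approach:

1. **Hydraulic diagnosis.** Piezometric heads and river water-surface
   levels are triangulated into TIN surfaces.  Each triangle carries an
   elevation, a slope (the hydraulic gradient *i*) and an aspect (the
   downslope azimuth, i.e. the flow direction).  Along the bank polyline,
   the exchange flux per segment follows Darcy's law weighted by the angle
   *D* between groundwater and river flow:

   ```
   Qe = 86400 · K · i · A · sin(D)      [m³/day per m of bank]
   ```

   with *K* the aquifer permeability (m/s) and *A* the saturated exchange
   cross-section (groundwater head minus riverbed elevation, m).  Positive
   Qe means the aquifer feeds the river; negative means the river
   recharges the aquifer.  Segment fluxes aggregate per zone into
   `Qf = Σ Qe·L` (m³/day) and unit flows `Qu = Qf/(L/1000)` (m³/day/km).

2. **Stygobite fauna.** Obligate groundwater invertebrates reach the
   river's interstitial sediments mainly where groundwater upwells.  Per
   site or section, the package computes stygobite richness `S`, relative
   richness `S% = 100·S/total richness` and abundance, and classifies
   sections as upwelling / mixed / none against auditable cut-offs.

3. **Macrophytes.** Wetland plant communities integrate the trophic level
   and thermal stability of the water that feeds them.  Species ecological
   profiles are derived from site environmental series (temperature
   variability, phosphorus, ammonia) via equilibrated-class binning and
   Levene-gated class-difference tests; relevés (Braun-Blanquet codes) are
   then scored into four trophic classes and a groundwater-influence index
   (null / low / intermediate / high).

An **overlay** stage aligns the three maps on a common kilometric-point
partition, issues convergence/divergence verdicts per zone and computes
cross-metric correlations.

A fully synthetic scene generator (`rivaq.synthetic`) provides
seed-reproducible valleys with closed-form exchange fluxes and wetland
communities with planted ecological structure, so the whole pipeline is
testable without field data.

## Worked example

```python
from rivaq import tin, exchange, synthetic

valley = synthetic.generate_valley(synthetic.ValleyConfig(seed=1))
piezo = tin.build_tin(valley.piezo_points.to_numpy(), "piezometric")
river = tin.build_tin(valley.river_points.to_numpy(), "river_stage")
estimates, zones = exchange.run_exchange_diagnosis(piezo, river, valley.segments)
for z in zones:
    if z.L_pos:
        print(z.zone, "gaining", round(z.Qf_pos, 1), z.Qu_pos)
    if z.L_neg:
        print(z.zone, "losing", round(z.Qf_neg, 1), z.Qu_neg)
```

prints

```
zone     dir       Qf (m3/day)   L (m)  Qu (m3/day/km)
Z_gain   gaining        1702.3    1800             946
Z_lose   losing         -508.3    1800            -282
```

The default synthetic valley has one reach whose piezometric surface
slopes toward the river (the aquifer drains into it: Qf = +1702 m³/day
over 1.8 km of bank, i.e. Qu = 946 m³/day/km) and one reach with the
gradient reversed (the river recharges the aquifer at −282 m³/day/km).
The generator's closed-form expectation (`valley.expected`) gives the same
numbers to ~1e-11 %, which is the accuracy of the whole TIN → D → A → Qe →
Qf chain on piecewise-planar surfaces.

The same pipeline is available from a shell:

```sh
rivaq simulate --seed 1 --outdir inputs/
rivaq exchange inputs/piezo_points.csv inputs/river_points.csv \
      inputs/segments.csv --outdir out/
rivaq all --seed 1 --outdir run/     # simulate + all three indicators
```

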