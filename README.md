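# phenogate

Live-cell, high-content cell-viability profiling from multichannel
fluorescence images.

Metabolic proxy assays report a single number per well; imaging-based
viability readouts resolve *how* cells die. `phenogate` implements an open,
scriptable version of the three-dye live-cell protocol used in high-content
screening facilities: Hoechst 33342 marks every nucleus (and, with long
incubation, the cytoplasm faintly), annexin V–Alexa 488 binds exposed
phosphatidylserine at apoptosis onset, and Yo-Pro-3 enters only
permeabilized (late apoptotic / necrotic) nuclei. From these channels the
package

1. **segments** each field into four per-cell regions — nucleus, cell,
   cytoplasm and border-eroded nucleus — with watershed splitting of stuck
   nuclei and removal of border-touching cells;
2. **measures** per-cell intensity, morphology and spot/edge/ridge texture
   features in every region × channel;
3. **classifies** every cell as healthy, initial apoptotic, late apoptotic
   or necrotic by one of three interchangeable backends:
   * *gating* — a two-step decision tree on background ratios: nuclear
     Yo-Pro-3 > 2× background selects the late/necrotic branch, then
     whole-cell annexin V > 2× background splits each branch;
   * *linear* — a regularized linear discriminant trained on ≥ 40 annotated
     cells per class;
   * *supervised* — gradient-boosted trees over 16 nucleus + 6 cell-body
     features, able to learn phenotypes the dye ratios cannot express
     (e.g. fragmented, dye-negative nuclei);
4. **aggregates** cells per well, normalizes healthy counts to DMSO vehicle
   controls, and fits the four-parameter logistic

   r(c) = bottom + (top − bottom) / (1 + (c / IC₅₀)^h)

   on log concentration to report IC₅₀ per compound, plus replicate CV%.

A synthetic plate generator renders all four phenotypes (plus a fragmented
dye-negative one) with per-cell ground truth, so the whole pipeline is
testable without a microscope.

## Worked example

```python
import numpy as np
from phenogate import (
    SimulatedPlateSpec, KillModel, simulate_plate, run_pipeline,
)

spec = SimulatedPlateSpec(
    compounds={"cmpdA": KillModel(true_ic50_um=1.0, hill=1.0)},
    replicates=2, n_vehicle_wells=2, cells_per_well=120, fields_per_well=1,
    seed=7,
)
fields, truth, plate_map = simulate_plate(spec)
result = run_pipeline(fields, plate_map, method="gating")

m = result.manifest
print("detected", m.detected, "border_removed", m.border_removed,
      "classified", m.classified)
fit = result.fits[0]
print(f"{fit.compound_id}: IC50 = {fit.ic50_um:.3g} uM "
      f"(hill {fit.hill_slope:.2f}, top {fit.top:.0f}%, bottom {fit.bottom:.0f}%)")
```

prints

```
detected 1922 border_removed 141 classified 1781
cmpdA: IC50 = 1.29 uM (hill 1.36, top 85%, bottom 6%)
```

1922 nuclei were found across the 16 fields; 141 touched a field border
and were excluded, the rest were gated by dye ratios. The plate was
simulated with a true IC₅₀ of 1 µM; a small noisy plate (120 cells/well,
duplicate wells) recovers 1.29 µM — within the counting noise of so few
cells. Larger plates recover the IC₅₀ within ±20% (see below).

The same workflow runs from the shell:

```bash
phenogate run --out results/demo --seed 7 --method gating
phenogate simulate --out plate/ --seed 1          # TIFFs + plate map + truth
phenogate segment --images plate/images --well A01 --out cells.csv
phenogate classify --cells cells.csv --out labeled.csv
```

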