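# octneck

Aneurysm **neck-coverage analysis for intravascular high-frequency OCT
(HF-OCT) pullbacks**, for researchers evaluating intrasaccular aneurysm
devices in preclinical models.

When a saccular aneurysm is treated with an intrasaccular device, the device
must reconstruct the aneurysm neck (the ostium between parent artery and
sac): uncovered openings let flow keep entering the dome and the aneurysm
fails to occlude. HF-OCT images the implanted construct at ~10 µm resolution,
so gaps invisible to angiography can be measured directly. `octneck`
implements that measurement as a tested pipeline:

1. **Segmentation** — each pullback frame is remapped to polar coordinates
   about the catheter centre and every pixel of every A-line is classified as
   *lumen*, *clot/tissue* or *device* by a deterministic rule cascade built
   from four cues: local gradient, signal threshold, the complete shadow
   trailed by metallic struts, and the cumulative A-line sum.
2. **Coverage** — device labels are projected onto the manually annotated
   neck surface, reconstructed as a (frame × angle) grid of cells with
   physical areas `Δz · r · Δθ` (mm²). Connected uncovered regions
   (8-connected, wrapping in θ) are the coverage gaps.
3. **Prediction** — the largest gap area feeds the occlusion rule: a gap
   **strictly larger than 1 mm²** predicts residual aneurysm filling at
   follow-up.
4. **Statistics** — group summaries, two-sided Fisher exact tests,
   Mann–Whitney U (exact permutation enumeration for small n), threshold
   predictivity and Bland–Altman agreement (bias ± 1.96 SD).

Because no pullback data are deposited for this kind of study, the package
ships a **calibrated phantom generator** (`octneck.phantom`): tubular vessel,
saccular ostium spanned by a strut mesh with a designed uncovered gap, OCT
speckle, depth attenuation and complete strut shadows — with exact
ground-truth labels and gap areas, so every stage is testable end to end.

## Worked example

The bundled case table (`octneck.load_reference_cases()`) describes an
11-aneurysm canine study: 7 aneurysms treated with a next-generation
intrasaccular device (NGID) and 4 with platinum coils, each with implant
count, herniation status, the largest neck-coverage gap measured at implant
(NGID only — coil artifacts preclude the analysis) and angiographic occlusion
grades at implant and 180 days.

```python
import octneck as on
from octneck.pipeline import run_study, summarize_report

print(summarize_report(run_study(on.load_reference_cases())))
```

prints

```
Study of 11 aneurysms (config 849f1ed336fa0247)
  NGID: n=7, mean implants 1.86, herniation 0%
  coils: n=4, mean implants 6.75, herniation 75%
  herniation Fisher p = 0.024
  implant counts: U = 0.0, p = 0.0061 (exact_permutation)
  gap > 1.0 mm^2 rule: Fisher p = 0.0476, 0/7 misclassified
```

Reading the numbers: coiling needed 6.75 implants per aneurysm on average
versus 1.86 for the intrasaccular device, and the implant counts separate the
groups completely (U = 0). Coils herniated into the parent artery in 75% of
cases, the intrasaccular device never (Fisher p = 0.024). The >1 mm² rule
classifies all seven device cases correctly against the dichotomised 180-day
outcome — both aneurysms with a gap above the threshold (1.57 and 1.30 mm²)
showed residual filling, all five below it occluded (Fisher p = 1/21 ≈
0.0476).

The same works from a shell, end to end on a phantom:

```sh
octneck --out-dir demo simulate --seed 4 --gap-area 1.3 --name ph
octneck --out-dir demo run-case demo/ph.tif demo/ph.json demo/ph_annotation.json
octneck params   # print all defaults
```

The `run-case` report contains the measured gap areas, the covered fraction
and the `RESIDUAL`/`OCCLUDED` prediction.

## Layout

| module | contents |
| --- | --- |
| `octneck.io` | calibrated volume / annotation / case-table data model, TIFF+JSON+CSV I/O |
| `octneck.geometry` | polar remapping, wall interpolation, neck-surface reconstruction |
| `octneck.segmentation` | the three-class A-line classifier |
| `octneck.coverage` | coverage map, gap finding, the 1 mm² rule |
| `octneck.stats` | Fisher exact, Mann–Whitney U, Bland–Altman, threshold predictivity |
| `octneck.phantom` | phantom generator with ground truth |
| `octneck.pipeline`, `octneck.cli` | per-case / whole-study orchestration and the `octneck` CLI |

See `docs/methods.md` for the model, parameter defaults and known
limitations.
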