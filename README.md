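# mcakscreen

Analysis pipeline for in-vitro small-molecule screens against MCAK
(KIF2C), the Kinesin-13 microtubule depolymerase. MCAK inhibition
induces aneuploidy in tumor cells and sensitizes them to taxanes, which
makes the enzyme an attractive drug target; screening for inhibitors
combines two orthogonal in-vitro readouts, and this package implements
the complete analysis for both, plus the downstream cell-assay
statistics:

* **Image-based depolymerization assay** — microtubules bound in
  96-well plates are imaged before and after enzyme addition; polymer
  is quantified by a sharpen → Sobel edge detection → binary threshold →
  particle analysis pipeline with size and circularity filters.
  The screen metric is the *MT polymer level* (particle count × mean
  particle area, i.e. total segmented area); the sedimentation variant
  converts each particle perimeter *P* into a length via
  *L = (P − 2w)/2* with *w* the post-processing microtubule width, and
  reports total polymer length normalized to an enzyme-free (FCP)
  control.
* **Conformational FRET assay** — a sensor with an mCitrine acceptor
  and mCerulean donor fused to the enzyme reports its closed/active
  versus open/inhibited state through the background-corrected ratio
  *I_F/I_D*. Uninhibited enzyme reads 1.64 ± 0.02; inhibitory antibody
  drops the ratio to 1.34 ± 0.03 and Aurora-B phosphorylation to
  1.10 ± 0.01.
* **Screen analytics** — assay quality by the Z′-factor,
  Z′ = 1 − 3(σ_PC + σ_NC)/|μ_PC − μ_NC|, and the coefficient of
  variation; hit calling (>50% polymer remaining → inhibitor, <10% →
  activator; FRET ratio change of ≥15% in either direction); duplicate-
  replicate intersection, rescreen confirmation and an FCP counter
  screen for fluorescence artifacts.
* **Dose–response** — MTT viability preprocessing and the
  three-parameter log-logistic fit
  *y = Bottom + (Top − Bottom)/(1 + 10^(x − logIC50))* (unit Hill
  slope), with IC50 fold-changes for taxane-sensitization analysis.
* **Cell-assay statistics** — micronucleus / lagging-chromosome
  proportions out of 100 scored cells per repeat with Student's
  t-tests, and clonogenic colony counts (strictly >50 cells) with
  one-sample t-tests against the DMSO control.

A first-class synthetic-data module generates ground-truth filament
images, plate-reader emissions, duplicate screens, viability tables and
binomial micronucleus counts, so every stage of the pipeline runs and
is validated without any external data.

## Worked example

Simulate a 96-well FRET pilot plate, compute ratios, score quality and
call hits:

```python
import numpy as np
from mcakscreen import builtin_layout, WellRole
from mcakscreen.synth import FretEffectModel, simulate_fret_plate
from mcakscreen.fret import compute_plate_ratios, plate_baselines
from mcakscreen.screen import assay_quality, call_fret_plate, hit_set

layout = builtin_layout("pilot96")           # FCP in A1-H1, FMCAK in A12-D12,
model = FretEffectModel()                    # antibody in E12-H12, 80 compounds
cid = layout.wells["B2"].compound_id         # plant one inhibitor at 0.7x ratio
readings, truth = simulate_fret_plate(layout, model, seed=3, effects={cid: 0.7})

ratios = compute_plate_ratios(readings, layout, background=model.background)
baselines = plate_baselines(ratios, layout)
print(f"FMCAK baseline: {baselines.mean(WellRole.FMCAK_CONTROL):.3f}")

pc = ratios[ratios.role == "FMCAK_CONTROL"].ratio
nc = ratios[ratios.role == "ANTIBODY_CONTROL"].ratio
q = assay_quality(pc, nc)
print(f"Z' = {q.z_prime:.2f}, CV = {q.cv_percent:.1f}%")

calls = call_fret_plate(ratios, baselines)
print(f"hits: {sorted(hit_set(calls))}")
```

Output:

```
FMCAK baseline: 1.650
Z' = 0.55, CV = 1.5%
hits: ['cpd-B2']
```

The enzyme baseline recovers the 1.64 control ratio within well noise;
Z′ of 0.55 with a 1.5% CV marks a usable (if small-n) plate, and the
planted compound — a 30% ratio drop, far past the −15% threshold — is
the only hit called among 80 compounds.

The same workflow is scriptable from the shell:

```bash
mcakscreen simulate --kind fret --layout pilot96 --seed 3 --out run/
mcakscreen fret --readings run/readings.csv --layout run/layout.csv --out run/ratios.tsv
mcakscreen qc --ratios run/ratios.tsv --layout run/layout.csv --out run/qc.tsv
mcakscreen call-hits --assay fret --ratios run/ratios.tsv --layout run/layout.csv --out run/hits.tsv
```

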