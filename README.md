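# oculovasc

Ocular vascular phenotyping for paired-eye studies: a tested, reusable
implementation of a multimodal retinal/choroidal image-analysis pipeline
with a generalized-estimating-equation statistical layer.

Retinal and choroidal vascular changes are candidate non-invasive proxies
for cerebrovascular pathology — of particular interest in Down syndrome,
the largest genetically predisposed group for Alzheimer's disease.
Quantifying them requires several bespoke measurements that are usually
locked inside interactive tools.  This package re-implements that whole
measurement chain as parameter-explicit, seedable library code, together
with a synthetic-data module that generates every input with known ground
truth so each stage can be validated end to end.

## What it computes

* **Peripapillary vessel count** (`oculovasc.ringscan`) — vessels crossing a
  3.4 mm OCT ring scan are counted from the shadows they cast on the bright
  outer-retina band: per-column band intensity is normalized by a circular
  median baseline and attenuated runs are detected, merging across the wrap
  point.  Shadows of 1–2 px (thin ciliary vessels, ~6.8–13.6 µm) are
  excluded; eyes are classified *low* (< 18) or *high* (≥ 18 vessels).
* **UWF vessel-tree metrics** (`oculovasc.uwf`) — from an ultra-widefield
  binary vessel map with labelled arteriole/venule centerlines:
  * **FD**: sandbox-count fractal dimension — the slope of log ⟨M(R)⟩ vs
    log R, where M(R) is the vessel mass in boxes of side R centred on
    structure pixels — within standard / posterior / mid-periphery regions
    aligned to the disc–fovea axis;
  * **WG, WI**: width gradient (µm/mm) and width intercept (µm) from a
    robust (Tukey bisquare) regression of caliber on arclength,
    `width = WI + WG·d`, sampled at regular intervals along the path;
  * **TORT**: tortuosity density
    `((n−1)/n)·(1/L)·Σᵢ(L_arc,i/L_chord,i − 1)` over the n curve segments
    separated by inflection points of the smoothed path;
  * quadrant aggregation into temporal / nasal / global summaries.
* **Lesion zoning and phenotyping** (`oculovasc.lesions`) — graded
  microaneurysms and hemorrhages are assigned to central / mid-peripheral /
  far-peripheral zones and temporal/nasal hemispheres of a fovea-centred
  grading grid; eyes are phenotyped hierarchically (any hemorrhage →
  hemorrhage group; only microaneurysms → microaneurysm group).
* **Choroidal vascularity index** (`oculovasc.cvi`) — the choroid between
  Bruch's membrane and the choroidal–scleral interface is binarized by
  multi-scale local Otsu thresholding with distance gating (dark pixels
  deeper than the Otsu radius from the choroid edge), opened and cleaned;
  CVI = luminal / total choroidal area, mapped en face and pooled per
  ETDRS sector (1 / 3 / 6 mm circles).
* **Statistics** (`oculovasc.stats`) — descriptive tables, chi-squared /
  Fisher / rank-sum group tests, leave-one-out outlier imputation to the
  group mean, GEE linear and logistic group contrasts (exchangeable
  working correlation over the two eyes of a participant, age/sex
  adjusted, robust sandwich SEs), Benjamini–Hochberg FDR within outcome
  families, and marginal R².
* **Synthetic data** (`oculovasc.synth`) — seedable generators for ring
  scans, vessel scenes with prescribed taper and tortuosity, analytic
  fractal fixtures, choroid volumes with a known luminal fraction, and
  paired-eye cohorts with planted group effects and exchangeable
  within-participant correlation ρ.

## Worked example

```python
import numpy as np
from oculovasc import synth
from oculovasc.ringscan import count_vessels
from oculovasc.cvi import volume_cvi
from oculovasc.stats import fit_gee

scan, truth = synth.gen_ring_scan(n_vessels=21, n_ciliary=2, snr=30.0, seed=7)
res = count_vessels(scan)
print(f"planted {truth.vessel_count} vessels -> counted {res.count} "
      f"({res.class_label}), thin shadows excluded: {res.excluded_thin}")

volume, ctruth = synth.gen_choroid_volume(n_bscans=4, luminal_fraction=0.42,
                                          n_cols=256, n_rows=220,
                                          thickness_px=90.0, seed=7)
_, _, cvi = volume_cvi(volume)
print(f"true luminal fraction {ctruth.luminal_fraction:.3f} -> recovered CVI {cvi:.3f}")

spec = synth.CohortSpec(
    n_per_group=100, rho=0.5, seed=7,
    outcomes=[synth.OutcomeSpec("vessel_count", beta_group=2.5,
                                intercept=16.0, residual_sd=3.0)])
cohort, _ = synth.gen_cohort(spec)
gee = fit_gee(cohort, "vessel_count")
row = gee.term("group[DS]")
print(f"GEE group effect: beta = {row['estimate']:.2f} "
      f"(95% CI {row['ci_low']:.2f} to {row['ci_high']:.2f}), "
      f"p = {row['p']:.2g}, working correlation = {gee.working_correlation:.2f}")
```

prints

```
planted 21 vessels -> counted 21 (high), thin shadows excluded: 2
true luminal fraction 0.418 -> recovered CVI 0.417
GEE group effect: beta = 2.60 (95% CI 1.88 to 3.32), p = 1.3e-12, working correlation = 0.56
```

The counter recovers the planted vessel number exactly and excludes the
two thin ciliary shadows; the binarization pipeline recovers the planted
choroidal luminal fraction to three decimals; and the GEE group contrast
recovers the planted mean difference of 2.5 vessels with an interval that
covers it, while estimating the planted eye-pair correlation of 0.5.

A command-line interface wraps the same functions
(`oculovasc synth|count-vessels|uwf-metrics|cvi|lesions|stats|run-all`);
`oculovasc run-all --out runs/demo --seed 0` runs a small synthetic cohort
end to end and writes per-eye metrics, GEE tables and a hash manifest.

## Documentation

`docs/methods.md` describes the models and algorithms, the synthetic-data
generators and what they do and do not emulate, all tunable parameters
with their defaults, and known limitations.
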