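# uspioquant

Quantitative analysis of USPIO-enhanced MRI for detecting macrophage-driven
chronic renal allograft damage — a tested, reusable implementation of the
full analysis chain, driven by a synthetic digital phantom so that every
stage is verifiable without animal data.

## The problem and who this is for

Chronic allograft damage (interstitial fibrosis and tubular atrophy) is the
leading cause of kidney-transplant failure, and the macrophages that drive
it can be imaged noninvasively: ultrasmall superparamagnetic iron-oxide
particles (USPIO, e.g. ferumoxytol) are taken up by tissue-resident
macrophages and shorten the local effective transverse relaxation time T2*.
In a murine transplant model, a multi-echo gradient-echo acquisition before
and 48 h after USPIO infusion quantifies that uptake voxel by voxel.

This package is for imaging scientists who want the complete numerical
chain of such a study as a library:

1. **Relaxometry** — each voxel's signal across echo times TE is fitted to
   the monoexponential decay `S(t) = S(0)·exp(−t/T2*)` by nonlinear least
   squares; voxels whose coefficient of determination satisfies r² ≤ 0.85
   are excluded; the relaxation rate is `R2* = 1000 / T2*[ms]` (s⁻¹).
2. **ROI quantification** — `ΔR2* = R2*(48 h) − R2*(baseline)` per labelled
   tissue, with the graft's ΔR2* indexed to the native kidney's (controls
   blood-pool concentration) and to skeletal muscle's (the clinically
   translatable reference).
3. **Exact statistics** — Mann-Whitney (allograft vs isograft, unpaired)
   and Wilcoxon matched-pairs signed-rank (graft vs native kidney, paired),
   with two-sided p-values from complete enumeration of the permutation
   null — essential at cohort sizes of 9 and 6.
4. **Histology percent-area** — percentage of tissue surface positive for
   F4/80 macrophage staining over ten nonoverlapping fields.
5. **Digital phantom** — renders pre/post multi-echo stacks (7 echoes at
   TE = 1.83–15 ms, 192×128 matrix, 35×35 mm field of view) with Rician
   noise, and simulates whole cohorts from two-piece uniform samplers
   calibrated to the reference study's group medians and interquartile
   ranges.

## Worked example

```python
import numpy as np
from uspioquant import (default_phantom_spec, render_multiecho,
                        render_label_mask, fit_map, roi_summary,
                        simulate_cohort, cohort_compare)

# fit a noiseless phantom slice and read the native kidney's rate
spec = default_phantom_spec()
maps = fit_map(render_multiecho(spec, "pre"))
mask = render_label_mask(spec)
print(roi_summary(maps, mask, "native_kidney").value)   # 42.79999999999986 (s^-1)
print(maps.n_valid, maps.n_invalid)                     # 5167 19409

# simulate the study cohort and run the headline comparison
records = simulate_cohort(allograft_n=9, isograft_n=6, seed=0)
comp = cohort_compare(records, measure="indexed_to_native",
                      comparison="allo_vs_iso_unpaired")
print(comp.summaries["allograft"])   # 1.27 (1.19 to 1.34), n=9
print(comp.summaries["isograft"])    # 0.96 (0.95 to 0.96), n=6
print(comp.result.p_value)           # 0.0003996003996003996
```

The fitted ROI value reproduces the phantom's configured baseline rate of
42.8 s⁻¹ exactly (noiseless data; only foreground voxels pass the r²
filter).  The simulated cohort's group medians fall inside the calibrated
interquartile ranges (allograft 1.12–1.36, isograft 0.92–1.04); because
those supports are disjoint, the exact Mann-Whitney p equals the
enumeration minimum 2/5005 ≈ 4.0×10⁻⁴, well below the 0.01 significance
bound it reproduces.

A command-line interface mirrors the stages (`uspioquant simulate`,
`fit`, `roi-report`, `cohort-stats`, `histo-quant`, `run`); `uspioquant
run --config config.json` executes the whole pipeline reproducibly and
writes a report comparing simulated summaries against the reference
values.

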