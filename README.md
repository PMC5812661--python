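# liverquant

Multiparametric MR quantification and longitudinal analysis of liver
regeneration after partial hepatectomy.

After a large liver resection the remnant regrows within days; whether it
regrows fast enough separates routine recovery from the small-for-size
syndrome and fatal post-hepatectomy liver failure. Quantitative MRI tracks
this process non-invasively: longitudinal (T1) and transverse (T2)
relaxation times rise with the water influx of hepatocyte hypertrophy, the
apparent diffusion coefficient (ADC) falls as cells swell, and the
magnetization transfer ratio (MTR) drops with the diluted macromolecular
pool. `liverquant` implements the full analysis chain for such a study —
and, because no per-animal data are publicly deposited, a synthetic layer
(digital liver phantom + cohort generator) that reproduces the study's
statistical structure so every stage can be exercised end to end.

The quantification core, per voxel:

- **T1**: Levenberg–Marquardt fit of the inversion-recovery trueFISP signal
  `S(TI) = S0(1 − INV·e^(−TI/T1*))` on magnitude data, with the flip-angle
  correction `T1 = T1*·cos(α/2)·(INV − 1)`.
- **T2**: bounded fit of `S(TE) = S0·e^(−TE/T2) + N` after Rician bias
  correction of the signals.
- **ADC**: `ln(S(b₀)/S(b))/b` from b ∈ {0, 800} s/mm², bias-corrected.
- **MTR**: `100·(M0 − Msat)/M0` from the MT off/on pair.
- Noise: background σ from a Rayleigh-mean air ROI; squared-subtraction
  correction `√(S² − N²)`.

On top: three auto-placed vessel-avoiding ROIs (mean of ROI means),
slice-summation volumetry normalized to the pre-operative volume, group
summaries with censoring, integer percent changes versus baseline, two-way
ANOVA (group × day) with Bonferroni post-tests, Pearson correlations against
relative liver volume, and logistic regression of fatal liver failure with
Nagelkerke R². See `docs/methods.md` for models, assumptions and numerical
choices.

## Worked example

```python
import numpy as np
from liverquant import (
    PhantomSpec, build_phantom, simulate_acquisitions, default_protocol_metas,
    fit_t1_map, auto_place_rois, roi_statistic,
)

phantom = build_phantom(PhantomSpec(seed=7))       # elliptical liver + vessels
meta = default_protocol_metas()["ir_truefisp"]     # 60 TIs from 90 ms, step 144 ms
series = simulate_acquisitions(phantom, meta, sigma=13.3, seed=1)  # image SNR ~50
maps, diags = fit_t1_map(series, mask=phantom.parenchyma_mask)
rois = auto_place_rois(phantom)
mean, sd = roi_statistic(maps["T1"], rois)
print(f"T1 = {mean:.1f} ± {sd:.1f} ms (truth {phantom.spec.parenchyma.t1_ms} ms)")
```

prints

```
T1 = 996.2 ± 0.9 ms (truth 997.0 ms)
```

i.e. the three-ROI mean recovers the simulated parenchyma T1 of a healthy
pre-operative liver (997 ms at 4.7 T) to within a fraction of a percent at
liver-typical SNR; `sd` is the spread among the three ROI means.

The full pipeline — simulate a 22-animal cohort, image and fit every
animal-day, ROI-average, volumetry, summaries and statistics — runs as

```sh
liverquant run --seed 1 --out out/
```

and writes `cohort_truth.csv`, `recovered.csv`, `summary.csv` (the group
mean±SD table including the censored cells), `abstract_check.csv` (the
integer percent-change check), `stats.json` and a `manifest.json` with
per-file SHA-256 hashes; a rerun with the same seed reproduces the hashes
exactly. `liverquant simulate|fit|roi-stats|volumetry|stats|check-abstract`
expose the individual stages.

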