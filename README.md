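# bcl6quant

Computer-assisted quantification of nuclear immunofluorescence in the
glandular epithelium of endometrial tissue sections.

Nuclear BCL6 expression in the eutopic endometrium is a candidate tissue
biomarker for endometriosis. It is traditionally read out with the HSCORE,
a semi-quantitative visual score over three staining-intensity categories:

    HSCORE = Σᵢ Pᵢ (i + 1) / 100,   i ∈ {1, 2, 3}  (weak, moderate, intense)

with Pᵢ the percentage of epithelial cells labelled at intensity *i*, giving a
scale of 0–4. Manual scoring is slow and observer-dependent. `bcl6quant`
implements a reproducible pixel-based alternative for scanned slides (RGB,
marker in green, DAPI counterstain in blue), together with the statistics
needed to compare patient groups and to check agreement with the HSCORE:

1. **Segmentation** — Otsu automatic thresholding of the grey-level green
   channel, then removal of small isolated stromal objects by erosion/opening
   followed by geodesic reconstruction (opening-by-reconstruction), keeping
   the large ring-like glandular epithelium; connected components are counted
   as glands.
2. **Quantification** — the binary epithelium mask multiplies the green
   channel to eliminate background; the remaining intensities are histogrammed
   on 256 grey levels. Sections with fewer than 20 glands are excluded.
3. **Statistics** — per-group mean ± SEM curves (point by point over sections),
   Stineman-interpolation smoothing, percentile summaries (p10–p90),
   Mann–Whitney tests both on scalar HSCOREs and point by point across grey
   levels, Gaussian fits A·exp(−(x−μ)²/2σ²) of intensity curves, and an OLS
   regression of HSCORE against the fitted distribution mean.
4. **Synthetic slides** — a generator for fluorescence-like sections with
   ground-truth epithelium/stroma masks and group-specific intensity
   distributions, so the whole pipeline is testable without clinical images.

## Worked example

Simulate a two-group cohort (5 sections per group, the second group's
epithelial marker intensity shifted by +40 grey levels) and analyse it:

```python
from bcl6quant import CohortSpec, GroupSpec, generate_cohort, write_cohort
from bcl6quant.pipeline import PipelineConfig, run_pipeline

spec = CohortSpec(
    groups=(GroupSpec("control", 5, 0.0), GroupSpec("endometriosis", 5, 40.0)),
    seed=1,
)
write_cohort(generate_cohort(spec), "demo_cohort")
run_pipeline("demo_cohort", "demo_cohort/meta.csv", PipelineConfig(), "demo_results")
```

or equivalently from the shell with `bcl6quant simulate` / `bcl6quant quantify`.
The output directory then contains per-section epithelium masks, histograms,
group tables and plots. The percentile table (`percentiles.csv`):

```
        group        p10        p25        p50        p75        p90
      control  94.281713 111.060944 131.093274 151.064974 169.738953
endometriosis 131.003811 149.320049 169.951485 190.577669 209.038374
```

The shifted group dominates at every percentile row, as expected for a +40
grey-level shift. The pointwise Mann–Whitney table flags 181 of 186 tested
grey levels at α = 0.05 (both groups are internally homogeneous here, so
nearly the whole shifted range differs). The Gaussian fits recover the group
curves' location and spread (`gaussian_fits.csv`):

```
        group  amplitude         mu     sigma  residual_ss  converged
      control   0.013499 130.472436 29.852255     0.000031       True
endometriosis   0.013036 169.987327 30.736471     0.000020       True
```

and the regression of the simulated observers' HSCOREs on the per-section
fitted means (`hscore_regression.csv`) gives r = 0.981 (p = 5.7·10⁻⁷, n = 10):
the categorical score and the pixel-based measurement agree.

## Layout

- `src/bcl6quant/io_slides.py` — image/metadata IO, channel extraction
- `src/bcl6quant/segmentation.py` — Otsu threshold, morphological filtering
- `src/bcl6quant/quantification.py` — masking, histograms, inclusion rule
- `src/bcl6quant/stats.py` — group curves, percentiles, tests, fits
- `src/bcl6quant/hscore.py` — HSCORE, categorisation, observer agreement
- `src/bcl6quant/synthetic.py` — slide and cohort generators
- `src/bcl6quant/pipeline.py`, `cli.py` — orchestration and `bcl6quant` CLI
- `docs/methods.md` — models, parameters, assumptions and limitations
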