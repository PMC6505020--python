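# susiq

Semi-quantification of dopamine-transporter (DAT) SPECT with the **specific
uptake size index (SUSI)** and the **specific binding ratio (SBR)**, plus
everything needed to study how the two estimators behave under realistic
imaging conditions: digital striatal phantoms with exact ground truth,
concentration-preserving affine stereotactical normalization, and a full
diagnostic-performance statistics stack (ROC/AUC with DeLong confidence
intervals and paired tests, Youden cutoffs, stratified bootstrap of AUC
differences, reference-variability analyses).

## Who this is for

Nuclear-medicine methodologists and imaging scientists who quantify striatal
FP-CIT uptake — in particular anyone comparing semi-quantitative measures
across cameras or sites, where spatial resolution varies between scanners
and partial-volume effects make the conventional SBR camera-dependent.

## The two estimators

With `C` the mean count concentration in an anatomical striatal ROI, `CR`
the non-displaceable reference concentration (estimated as the 75th
percentile of voxel intensities in the brain outside striata, thalamus and
brainstem), `T` the total counts in a large ROI around the structure, and
`V` that ROI's volume:

    SBR  = (C − CR) / CR                  (dimensionless)
    SUSI = (T − CR · V) / CR              (mL)

On an ideal count-conserving image, `SUSI = BPnd × Vs` (binding potential
times true structure volume), hence `SBR = SUSI / Vs`. The SBR is degraded
by partial-volume effects — at clinical resolution it recovers only about
half of the true specific signal, and the loss depends on the camera — while
the SUSI is resolution-independent as long as the large ROI captures all
displaced counts. The flip side: the SUSI's background correction term
`CR·V` is large, so errors in `CR` are amplified. This package exists to
quantify exactly these trade-offs.

## Worked example

Resolution dependence on a noiseless phantom (control-like, BPnd = 5,
putamen 5.5 mL/side), quantified with the default template ROIs:

```python
from susiq import make_roi_set, TEMPLATE_GRID
from susiq.studies import resolution_sweep

rois = make_roi_set(TEMPLATE_GRID)
print(resolution_sweep(rois).round(3).to_string(index=False))
```

```
 fwhm_mm  susi_striatum  sbr_striatum  susi_putamen  sbr_putamen     cr
     6.0         47.523         3.423        27.422        3.485 60.000
     8.0         47.548         2.947        27.302        3.019 60.000
    10.0         47.538         2.525        27.102        2.601 60.000
    12.0         47.297         2.156        26.714        2.231 59.998
    14.0         46.715         1.844        26.101        1.913 59.980
```

The striatal SUSI stays within 0.7% of its mean while the SBR drops by
almost half from 6 to 14 mm FWHM — the resolution independence that makes
the SUSI attractive for multi-camera settings. The true striatal
`BPnd × Vs` here is 47.52 mL, which the unblurred SUSI matches exactly; the
SBR at 10 mm recovers 2.53/5.0 ≈ 52% of the true binding potential, the
classic partial-volume loss.

Simulating a small multi-site cohort and scoring the hemisphere-minimum
putaminal measures:

```python
from susiq import CohortConfig, simulate_cohort, quantify_cohort, roc_analysis

cfg = CohortConfig(setting="MULTI", n_disease=40, n_control=20, n_sites=8, seed=7)
subjects = simulate_cohort(cfg, rois)
quant = quantify_cohort(subjects, rois)
y = quant["label"] == "disease"
for col in ("susi_putamen_min", "sbr_putamen_min"):
    r = roc_analysis(quant[col], y, "lower")
    print(f"{col}: AUC={r.auc:.3f} (95% CI {r.ci95[0]:.3f}-{r.ci95[1]:.3f}) "
          f"cutoff={r.cutoff:.3f} acc={r.accuracy:.3f}")
```

```
susi_putamen_min: AUC=0.990 (95% CI 0.974-1.000) cutoff=18.183 acc=0.967
sbr_putamen_min: AUC=0.991 (95% CI 0.977-1.000) cutoff=1.608 acc=0.950
```

Subjects below the Youden cutoff (18.2 mL of putaminal SUSI, or SBR 1.61)
are classified as neurodegenerative; both measures separate the groups
almost perfectly at this effect size.

## Command line

The `susiq` command orchestrates the pipeline stages on NIfTI volumes and
CSV/JSON artifacts:

```sh
susiq simulate --setting MULTI --n-disease 40 --n-control 20 --out cohort/
susiq build-template cohort/multi_00*.nii.gz --out template.nii.gz
susiq normalize patient.nii.gz template.nii.gz --mode affine --out-transform t.json
susiq quantify cohort/multi_0000.nii.gz --out quant.csv
susiq run-all --tiny --out experiment/      # end-to-end smoke run
```

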