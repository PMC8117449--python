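# fetdki

Combined ¹⁸F-FET PET and diffusion-kurtosis MRI analytics for separating
**tumor progression (TPR)** from **treatment-related changes (TRC)** in
pretreated glioblastoma.

After surgery and chemoradiation, a growing contrast-enhancing lesion can be
either true tumor regrowth or a benign treatment effect (pseudoprogression,
radiation necrosis) — a distinction conventional MRI often cannot make. This
package implements, as a tested and reusable library, an analysis that
combines two complementary signals:

- **Amino-acid PET**: uptake of the tracer O-(2-[¹⁸F]-fluoroethyl)-L-tyrosine
  quantified as tumor-to-brain ratios (TBR) on the summed 20–40 min image,
  plus dynamic time–activity-curve (TAC) metrics — time-to-peak (TTP) and the
  20–50 min late-phase slope in SUV/h.
- **Diffusion kurtosis imaging (DKI)**: multi-shell diffusion MRI fitted to
  the cumulant expansion

  &nbsp;&nbsp;&nbsp;&nbsp;ln S(b, **n**) = ln S₀ − b·**n**ᵀD**n** + (b²/6)·MD²·W(**n**),

  with D the diffusion tensor, W the rank-4 kurtosis tensor, and the apparent
  kurtosis K(**n**) = (MD/**n**ᵀD**n**)²·W(**n**). Scalar maps MD/RD/AD
  (mean/radial/axial diffusivity, μm²/ms) and MK/RK/AK (mean/radial/axial
  kurtosis) are derived per voxel. Cellular, proliferating tumor raises
  kurtosis; treatment-disrupted tissue lowers it.

The lesion is segmented in 3D on PET (connected region with TBR ≥ 1.6), the
kurtosis maps inside that metabolically active region are reduced to 18
histogram variables (mean plus C5/C10 for diffusivities, mean plus C90/C95
for kurtoses after truncation to 0.5–3.5 μm²/ms and 0.4–1.2 respectively),
and group statistics (Mann–Whitney with family-wise Bonferroni correction,
ROC analysis with Youden cutoffs, DeLong AUC comparison, logistic models)
identify the discriminative markers. The headline classifier is the
composite **FET–DKI index**

&nbsp;&nbsp;&nbsp;&nbsp;index = 4.7·TBRmax + 39.2·MK C90, &nbsp; call TPR iff index > 41.

No patient images ship with the package; a first-class synthetic-data module
generates image-level phantoms (DWI + dynamic PET with known ground truth)
and feature-level cohorts calibrated to the reference study's group medians
and interquartile ranges (TRC n=11, TPR n=21), so every stage is testable
end to end.

## Worked example

```python
from fetdki.cohort import CohortSimConfig, simulate_feature_cohort
from fetdki.stats import fet_dki_index, roc_analysis

for group, tbr, mk in (("TPR", 3.30, 0.78), ("TRC", 2.50, 0.61)):
    value, call = fet_dki_index(tbr, mk)
    print(f"{group} medians -> index {value:.3f} -> {call}")

cohort = simulate_feature_cohort(CohortSimConfig(n_trc=110, n_tpr=210, seed=5))
idx, calls = fet_dki_index(cohort["TBR_max"].to_numpy(), cohort["MK_C90"].to_numpy())
roc = roc_analysis(idx, cohort["group"].to_numpy())
print(f"accuracy {(calls == cohort['group']).mean():.1%}, AUC {roc.auc:.3f}")
```

prints

```
TPR medians -> index 46.086 -> TPR
TRC medians -> index 35.662 -> TRC
accuracy 81.9%, AUC 0.839
```

The two group-median operating points straddle the 41 cutoff — the index
separates the typical progression patient from the typical treatment-change
patient. On a full synthetic cohort individual patients scatter around their
group medians, so cohort-level accuracy (here 81.9%) is necessarily lower
than at the medians themselves.

The `examples/` directory walks through each capability: kurtosis fitting
with Rician bias correction on a noisy phantom, the PET read-out, histogram
feature extraction, the cohort statistics screen, the index classifier, and
the end-to-end pipeline. A thin CLI mirrors the stages:

```bash
fetdki simulate phantom --group TPR --seed 7 --out phantom/
fetdki fit-dki --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
    --bvec phantom/dwi.bvec --mask phantom/dwi_mask.nii.gz --out maps/
fetdki simulate cohort --n-trc 11 --n-tpr 21 --seed 7 --out cohort.csv
fetdki cohort-stats --features cohort.csv --out statsout/
fetdki run-all --n-trc 2 --n-tpr 2 --seed 7 --out run/
```

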