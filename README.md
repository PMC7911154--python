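# metpet

Preoperative ¹¹C-methionine (MET) PET analysis for brain tumors, as a tested,
reusable Python pipeline: threshold-based tumor delineation with
semi-quantitative uptake metrics, a 64-level / 36-feature gray-level texture
battery, clustering-based feature reduction, and survival modeling that links
texture features — low gray-level run emphasis (LGRE) and gray-level
co-occurrence (GLCM) correlation — to overall survival. A synthetic PET-phantom
and survival-cohort generator stands in for patient data, so every stage is
testable end to end without any download.

**Who it is for.** Researchers in PET radiomics and neuro-oncology imaging who
want a transparent, oracle-tested reference implementation of the classic
MET-PET texture/survival workflow, and a controllable simulator for method
studies (how do necrosis and spatial smoothness of uptake drive LGRE and
correlation, and how well does a Cox model recover a texture→hazard link?).

## The methods at the core

- **SUV and delineation.** SUV = [tissue radioactivity (Bq/mL)] × [body weight
  (g)] / [injected dose (Bq)]. The reference value is the mean SUV in a 10 mm
  sphere on normal contralateral tissue; the tumor boundary is the 26-connected
  component of voxels with SUV ≥ 1.3 × reference containing the hottest
  candidate voxel. Reported metrics: SUVmax, SUVmean, TNR = SUVmax/reference,
  MTV (mL), TLMU = MTV × SUVmean.
- **Texture battery.** Tumor SUVs are resampled to G = 64 gray levels,
  q(x) = 1 + ⌊G·(SUV−min)/(max−min)⌋ (clamped), and 36 features are computed:
  histogram (4), GLCM (7, one matrix aggregated over the 13 unique 3D
  directions, symmetrized), gray-level run-length GLRLM (11), neighborhood
  gray-level difference NGLDM (3), and gray-level zone-size GLZLM (11). E.g.
  LGRE = (1/N_r)·Σᵢₗ M(i,l)/i² weights runs by inverse squared gray level —
  high when many small low-uptake (necrotic) segments sit inside the boundary —
  and GLCM correlation = Σᵢⱼ(i−μ)(j−μ)p(i,j)/σ² is high when voxel-to-voxel
  changes are small.
- **Feature reduction.** Agglomerative ("ascendant") hierarchical clustering of
  features on d = 1 − |Pearson r| across subjects (average linkage), cut at
  k = 6; each cluster is represented by the member with the highest mean
  squared correlation to its co-members.
- **Survival.** Kaplan–Meier curves with log-rank tests on features
  dichotomized at a cutoff, and Cox proportional-hazards models (Efron ties,
  Wald 95% CIs): a univariate screen plus three adjusted models per texture
  feature (age / WHO grade / genetic status).
- **Simulator.** Phantoms with a unit-SUV noisy background, an ellipsoidal
  tumor at a tunable uptake ratio, a Gaussian random heterogeneity field with a
  controllable correlation length, and disjoint low-uptake necrotic foci;
  cohorts whose log hazard is linear in the normalized necrosis burden and
  field correlation length, with exponential survival times and administrative
  censoring.

## Worked example

```python
from metpet import PhantomSpec, ReferenceROI, generate_phantom, \
    reference_suvmean, segment_tumor, to_suv
from metpet.phantom import default_reference_center

spec = PhantomSpec(seed=42)                      # 64³ @ 2 mm, 2 necrotic foci
volume, truth = generate_phantom(spec)
suv = to_suv(volume, spec.dose_info)
ref = reference_suvmean(suv, ReferenceROI(default_reference_center(spec)))
seg = segment_tumor(suv, ref)
print(seg.tnr, seg.mtv_ml)
```

Running `python examples/01_phantom_and_segmentation.py` prints:

```
reference SUVmean (contralateral, 10 mm ROI): 0.999
SUVmax  3.92   SUVmean 3.25
TNR     3.93   (SUVmax / reference)
MTV     36.0 mL   TLMU 117.0
```

i.e. a 36 mL lesion at ~3.9× normal-tissue uptake — typical of a MET-avid
glioma. `examples/02_texture_features.py` then shows the texture mechanics:
adding 5 necrotic foci raises LGRE (0.0014 → 0.0084: more low-level runs
inside the boundary) and smoothing the heterogeneity field from white noise to
an 8 mm correlation length raises GLCM correlation (−0.002 → 0.955).
`examples/04_survival_analysis.py` fits the survival layer on a 200-subject
simulated cohort (univariate HR ≈ 3.0 for the true necrosis burden, null HRs
for the noise covariates), and `examples/05_full_pipeline.py` writes a complete
reproducible run directory. A thin CLI mirrors the stages:
`metpet simulate | segment | texture | select-features | survival | run-all`.

## Layout

```
src/metpet/         phantom.py (simulator) · segmentation.py · texture.py
                    selection.py · survival.py · pipeline.py · cli.py · io.py
examples/           one short narrative script per capability
tests/              pytest suite with independent brute-force oracles
docs/methods.md     models, conventions, numerical choices, limitations
```
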