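"""Extract the 36-feature texture battery from a phantom tumor.

Quantizes the delineated tumor to 64 gray levels and computes the
histogram, GLCM, GLRLM, NGLDM and GLZLM families.  Shows how the two
prognostic features behave: LGRE rises when small low-uptake (necrotic)
foci are added, and GLCM correlation rises when the intratumoral
heterogeneity field becomes spatially smoother.
"""

from metpet import PhantomSpec, ReferenceROI, extract_all, generate_phantom, reference_suvmean, segment_tumor, to_suv
from metpet.phantom import default_reference_center


def features(seed, n_foci, corr_length_mm):
    spec = PhantomSpec(seed=seed, n_necrotic_foci=n_foci, field_corr_length=corr_length_mm)
    vol, _ = generate_phantom(spec)
    suv = to_suv(vol, spec.dose_info)
    ref = reference_suvmean(suv, ReferenceROI(center=default_reference_center(spec)))
    return extract_all(segment_tumor(suv, ref), suv).values


base = features(seed=0, n_foci=0, corr_length_mm=0.0)
foci = features(seed=0, n_foci=5, corr_length_mm=0.0)
smooth = features(seed=0, n_foci=0, corr_length_mm=8.0)

print(f"{len(base)} features extracted; a few of them:")
for name in ("glcm_dissimilarity", "glcm_correlation", "glcm_entropy",
             "glrlm_lgre", "glrlm_hgre", "glrlm_glnur"):
    print(f"  {name:22s} {base[name]:10.4f}")

print("\nLGRE (low gray-level run emphasis): many small low-uptake segments raise it")
print(f"  0 necrotic foci: {base['glrlm_lgre']:.4f}   5 foci: {foci['glrlm_lgre']:.4f}")
print("GLCM correlation: smoother voxel-to-voxel variation raises it")
print(f"  white-noise field: {base['glcm_correlation']:.4f}   8 mm field: {smooth['glcm_correlation']:.4f}")
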