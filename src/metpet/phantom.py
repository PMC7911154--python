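"""Synthetic MET-PET phantoms and a linked survival cohort.

Each phantom is a 3D activity volume mimicking an amino-acid PET brain
study: near-zero activity outside an elliptical "head", a noisy unit-SUV
background inside it, and an ellipsoidal tumor whose uptake is a multiple
of background.  Intratumoral heterogeneity has two independently tunable
axes, matching the two texture mechanisms the pipeline is built to probe:

* a smooth Gaussian random field with a controllable spatial correlation
  length (white noise convolved with a Gaussian kernel of σ = the
  correlation length, renormalized to unit variance) — longer correlation
  means smaller voxel-to-voxel changes, which raises GLCM correlation;
* small spherical low-uptake "necrotic" foci wholly inside the tumor —
  many small low-accumulation segments inside the boundary raise LGRE.

The cohort generator samples per-subject phantom parameters and draws
survival times from a proportional-hazards model whose log-hazard is
linear in the normalized necrosis burden and correlation length, so that
parameter-recovery of the texture→survival link can be tested end to end.

All randomness derives from one root seed through fixed named substreams
(background, field, foci, clinical, survival, censoring), so every output
is a pure function of its spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import save_volume
from .segmentation import ActivityVolume, DoseInfo

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SubjectTruth",
    "FocusPlacementError",
    "smooth_noise_field",
    "generate_phantom",
    "default_reference_center",
    "generate_cohort",
    "cohort_to_dataframe",
    "write_phantom",
    "write_cohort",
]

_SUBSTREAMS = ("background", "field", "foci", "params", "clinical", "survival", "censoring")


class FocusPlacementError(RuntimeError):
    """A necrotic focus could not be placed disjointly inside the tumor."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(
            f"could not place necrotic focus {index} disjointly inside the tumor "
            "after 1000 retries; shrink focus_radius or n_necrotic_foci"
        )


def _substream(seed: int, name: str) -> np.random.Generator:
    k = _SUBSTREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic PET phantom.

    Uptake levels are expressed in SUV-equivalent units (multiples of
    ``background_mean``); the rendered volume is stored as activity in
    Bq/mL via the inverse SUV relation with ``body_weight_g`` and
    ``injected_dose_bq``.  Defaults depict a typical MET-avid glioma:
    tumor-to-background ratio ≈ 3.2 over a unit background, a ~37 mL
    lesion, and a 370 MBq injection in a 60 kg subject.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    background_mean: float = 1.0  # SUV-equivalent
    background_sd: float = 0.05
    tumor_center: tuple[int, int, int] = (32, 32, 18)  # voxel indices
    tumor_radii: tuple[float, float, float] = (22.0, 20.0, 20.0)  # mm
    tumor_uptake: float = 3.2  # × background
    field_corr_length: float = 4.0  # mm
    field_sd: float = 0.25  # × background
    n_necrotic_foci: int = 2
    focus_radius: float = 4.0  # mm
    focus_uptake: float = 0.5  # × background (< 1.3: sub-threshold)
    body_weight_g: float = 60000.0
    injected_dose_bq: float = 3.7e8
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_spacing) or any(r <= 0 for r in self.tumor_radii):
            raise ValueError("spacings and radii must be strictly positive")
        if not (self.tumor_uptake > self.focus_uptake >= 0):
            raise ValueError("tumor_uptake must exceed focus_uptake, which must be >= 0")
        if self.background_mean <= 0 or self.background_sd < 0 or self.field_sd < 0:
            raise ValueError("background_mean must be > 0; noise scales must be >= 0")
        if self.n_necrotic_foci < 0 or self.focus_radius <= 0:
            raise ValueError("n_necrotic_foci >= 0 and focus_radius > 0 required")
        if self.body_weight_g <= 0 or self.injected_dose_bq <= 0:
            raise ValueError("body weight and injected dose must be strictly positive")
        for c, r, n, sp in zip(
            self.tumor_center, self.tumor_radii, self.grid_shape, self.voxel_spacing
        ):
            if c - r / sp < 0 or c + r / sp > n - 1:
                raise ValueError("tumor ellipsoid must fit inside the grid")

    @property
    def dose_info(self) -> DoseInfo:
        return DoseInfo(body_weight_g=self.body_weight_g, injected_dose_bq=self.injected_dose_bq)


def smooth_noise_field(
    shape: tuple[int, int, int],
    corr_length: float,
    spacing: tuple[float, float, float],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Zero-mean, unit-variance field with spatial correlation length in mm.

    White Gaussian noise is convolved with a Gaussian kernel of
    σ = corr_length (per axis, in voxel units corr_length / spacing) and
    renormalized to sample mean 0 and variance 1.  corr_length = 0 returns
    (normalized) white noise.
    """
    if corr_length < 0:
        raise ValueError("corr_length must be >= 0")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be strictly positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    f = rng.standard_normal(shape)
    if corr_length > 0:
        sigma = [corr_length / s for s in spacing]
        f = ndimage.gaussian_filter(f, sigma=sigma, mode="nearest")
    f = f - f.mean()
    sd = f.std()
    if sd == 0:  # pathological single-voxel grid
        return f
    return f / sd


def _ellipsoid_mask(shape, spacing, center, radii_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    return (
        sum((((g - c) * sp) / r) ** 2 for g, c, sp, r in zip(grids, center, spacing, radii_mm))
        <= 1.0
    )


def default_reference_center(spec: PhantomSpec) -> tuple[int, int, int]:
    """Reference-ROI center mirrored contralaterally (across the last axis).

    The generator keeps the mirrored sphere inside the head and outside the
    tumor, so the reference region is guaranteed noise-only background.
    """
    c = spec.tumor_center
    return (c[0], c[1], spec.grid_shape[2] - 1 - c[2])


def generate_phantom(spec: PhantomSpec) -> tuple[ActivityVolume, np.ndarray]:
    """Render the phantom; returns (activity volume, ground-truth tumor mask).

    The truth mask marks the full tumor ellipsoid (including necrotic foci).
    Deterministic given ``spec.seed``.
    """
    shape, spacing = spec.grid_shape, spec.voxel_spacing
    center_vox = tuple((n - 1) / 2.0 for n in shape)
    head_radii = tuple(0.45 * n * sp for n, sp in zip(shape, spacing))
    head = _ellipsoid_mask(shape, spacing, center_vox, head_radii)
    tumor = _ellipsoid_mask(shape, spacing, spec.tumor_center, spec.tumor_radii)

    suv = np.zeros(shape, dtype=float)
    bg_rng = _substream(spec.seed, "background")
    noise = bg_rng.standard_normal(shape)
    suv[head] = spec.background_mean + spec.background_sd * noise[head]

    if spec.field_sd > 0:
        f = smooth_noise_field(shape, spec.field_corr_length, spacing, _substream(spec.seed, "field"))
    else:
        f = np.zeros(shape)
    suv[tumor] = spec.background_mean * (spec.tumor_uptake + spec.field_sd * f[tumor])

    # necrotic foci: rejection-sampled sphere centers, fully inside the
    # ellipsoid eroded by focus_radius and pairwise disjoint with a one-voxel
    # safety margin (keeps them 26-disconnected after rasterization)
    if spec.n_necrotic_foci > 0:
        foci_rng = _substream(spec.seed, "foci")
        shrunk = tuple(r - spec.focus_radius for r in spec.tumor_radii)
        if any(r <= 0 for r in shrunk):
            raise FocusPlacementError(0)
        min_sep = 2 * spec.focus_radius + 2 * max(spacing)
        centers: list[np.ndarray] = []
        for i in range(spec.n_necrotic_foci):
            for _ in range(1000):
                u = foci_rng.uniform(-1.0, 1.0, size=3)
                cand_mm = u * np.array(shrunk)
                if (np.sum((cand_mm / np.array(shrunk)) ** 2)) > 1.0:
                    continue
                cand = np.array(spec.tumor_center) + cand_mm / np.array(spacing)
                if all(
                    np.linalg.norm((cand - c) * np.array(spacing)) >= min_sep for c in centers
                ):
                    centers.append(cand)
                    break
            else:
                raise FocusPlacementError(i)
        for c in centers:
            sph = _ellipsoid_mask(shape, spacing, c, (spec.focus_radius,) * 3)
            suv[sph] = spec.background_mean * spec.focus_uptake

    np.clip(suv, 0.0, None, out=suv)
    activity = suv * (spec.injected_dose_bq / spec.body_weight_g)
    return ActivityVolume(values=activity, voxel_spacing=spacing), tumor


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges and survival model for a synthetic patient cohort.

    Per-subject phantom parameters are drawn uniformly from the stated
    ranges (integer-uniform for the focus count).  The log hazard is
    β_necrosis × (normalized necrosis burden) + β_corr × (normalized
    correlation length), with burden = n_foci / max(n_foci range) and the
    correlation length normalized by its range maximum.  Survival times are
    exponential with rate baseline_hazard × exp(log hazard); censoring is
    administrative at max_followup plus, with probability censor_rate, a
    uniform early administrative censoring time.

    Clinical covariates (age, sex, WHO grade, genetic status) are sampled
    with margins typical of a surgical glioma cohort but carry no hazard,
    so they act as pure-noise adjusters in model checks.
    """

    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_uptake_range: tuple[float, float] = (2.2, 4.2)
    tumor_radius_range: tuple[float, float] = (18.0, 24.0)  # mm, per axis
    field_corr_length_range: tuple[float, float] = (0.0, 8.0)  # mm
    field_sd: float = 0.25
    n_foci_range: tuple[int, int] = (0, 4)
    focus_radius_range: tuple[float, float] = (2.5, 4.0)
    focus_uptake_range: tuple[float, float] = (0.3, 0.8)
    beta_necrosis: float = 1.2  # log-hazard per unit normalized burden
    beta_corr: float = 0.8  # log-hazard per unit normalized corr length
    baseline_hazard: float = 0.02  # events per month
    censor_rate: float = 0.3
    max_followup: float = 60.0  # months
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")
        for name in (
            "tumor_uptake_range",
            "tumor_radius_range",
            "field_corr_length_range",
            "n_foci_range",
            "focus_radius_range",
            "focus_uptake_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty parameter range {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    phantom_spec: PhantomSpec
    necrosis_burden: float  # normalized to [0, 1]
    corr_length_norm: float  # normalized to [0, 1]
    true_linear_predictor: float
    survival_months: float
    event: bool
    age: float
    sex: str
    who_grade: int
    genetic_status: str


# WHO grade marginal and grade-conditional genetic status typical of a
# mixed surgical glioma series (grade II/III/IV ≈ 17/40/43%).
_GRADE_P = {2: 7 / 42, 3: 17 / 42, 4: 18 / 42}
_GENETIC_BY_GRADE = {
    2: (("mut", 1 / 7), ("codel", 6 / 7)),
    3: (("mut", 2 / 17), ("codel", 7 / 17), ("wild", 8 / 17)),
    4: (("wild", 1.0),),
}


def _sample_clinical(rng: np.random.Generator):
    age = float(np.clip(rng.normal(55.0, 13.0), 20.0, 85.0))
    sex = "male" if rng.random() < 0.43 else "female"
    grades, probs = zip(*_GRADE_P.items())
    grade = int(rng.choice(grades, p=probs))
    statuses, sp = zip(*_GENETIC_BY_GRADE[grade])
    status = str(rng.choice(statuses, p=np.array(sp) / np.sum(sp)))
    return age, sex, grade, status


def generate_cohort(spec: CohortSpec) -> list[SubjectTruth]:
    """Sample subjects: phantom parameters, clinical covariates, survival.

    Phantoms are not rendered here; render any subject on demand with
    ``generate_phantom(subject.phantom_spec)`` (the per-subject seed is part
    of the stored spec, so rendering is reproducible).
    """
    param_rng = _substream(spec.seed, "params")
    clin_rng = _substream(spec.seed, "clinical")
    surv_rng = _substream(spec.seed, "survival")
    cens_rng = _substream(spec.seed, "censoring")

    max_foci = spec.n_foci_range[1]
    max_corr = spec.field_corr_length_range[1]
    subjects: list[SubjectTruth] = []
    for i in range(spec.n_subjects):
        uptake = param_rng.uniform(*spec.tumor_uptake_range)
        radii = tuple(param_rng.uniform(*spec.tumor_radius_range) for _ in range(3))
        corr_len = param_rng.uniform(*spec.field_corr_length_range)
        n_foci = int(param_rng.integers(spec.n_foci_range[0], spec.n_foci_range[1] + 1))
        f_radius = param_rng.uniform(*spec.focus_radius_range)
        f_uptake = param_rng.uniform(*spec.focus_uptake_range)
        center = tuple(int(round((n - 1) / 2.0)) for n in spec.grid_shape[:2]) + (
            int(round(max(radii) / spec.voxel_spacing[2])) + 2,
        )
        pspec = PhantomSpec(
            grid_shape=spec.grid_shape,
            voxel_spacing=spec.voxel_spacing,
            tumor_center=center,
            tumor_radii=radii,
            tumor_uptake=uptake,
            field_corr_length=corr_len,
            field_sd=spec.field_sd,
            n_necrotic_foci=n_foci,
            focus_radius=f_radius,
            focus_uptake=f_uptake,
            seed=int(param_rng.integers(0, 2**31 - 1)),
        )
        burden = n_foci / max_foci if max_foci > 0 else 0.0
        corr_norm = corr_len / max_corr if max_corr > 0 else 0.0
        lp = spec.beta_necrosis * burden + spec.beta_corr * corr_norm
        rate = spec.baseline_hazard * np.exp(lp)
        t = float(surv_rng.exponential(1.0 / rate))
        c = spec.max_followup
        if cens_rng.random() < spec.censor_rate:
            c = min(c, float(cens_rng.uniform(0.0, spec.max_followup)))
        age, sex, grade, status = _sample_clinical(clin_rng)
        subjects.append(
            SubjectTruth(
                subject_id=f"S{i:04d}",
                phantom_spec=pspec,
                necrosis_burden=burden,
                corr_length_norm=corr_norm,
                true_linear_predictor=float(lp),
                survival_months=min(t, c),
                event=t <= c,
                age=age,
                sex=sex,
                who_grade=grade,
                genetic_status=status,
            )
        )
    return subjects


def cohort_to_dataframe(subjects: list[SubjectTruth]) -> pd.DataFrame:
    """Survival manifest: one row per subject with truth columns."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "time_months": [s.survival_months for s in subjects],
            "event": [int(s.event) for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "who_grade": [s.who_grade for s in subjects],
            "genetic_status": [s.genetic_status for s in subjects],
            "true_necrosis_burden": [s.necrosis_burden for s in subjects],
            "true_corr_length_norm": [s.corr_length_norm for s in subjects],
            "true_linear_predictor": [s.true_linear_predictor for s in subjects],
        }
    )


def write_phantom(spec: PhantomSpec, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Render and write one phantom: NIfTI volume + JSON sidecar (spec, dose)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol, truth = generate_phantom(spec)
    nii_path = out_dir / f"{stem}.nii"
    save_volume(vol.values, vol.voxel_spacing, nii_path)
    save_volume(truth.astype(np.uint8), vol.voxel_spacing, out_dir / f"{stem}_truth_mask.nii")
    sidecar = out_dir / f"{stem}.json"
    payload = asdict(spec)
    payload["reference_center"] = list(default_reference_center(spec))
    sidecar.write_text(json.dumps(payload, indent=2))
    return nii_path, sidecar


def write_cohort(subjects: list[SubjectTruth], out_dir: str | Path) -> Path:
    """Write a cohort: one volume + sidecar per subject and a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_phantom(s.phantom_spec, out_dir / "volumes", s.subject_id)
    manifest = out_dir / "cohort.csv"
    cohort_to_dataframe(subjects).to_csv(manifest, index=False)
    return manifest
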