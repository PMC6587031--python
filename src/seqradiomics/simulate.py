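"""Synthetic phantom cohorts and direct feature tables.

The generators emulate the statistical structure the analysis assumes:

* per-subtype DCE enhancement trajectories over 6 time points (piecewise
  linear wash-in to a subtype-specific peak phase, then washout),
* mono-exponential DWI decay over 3 b-values, ``S(b) = S0 exp(-b ADC)``,
  with voxelwise ADC drawn from a truncated normal whose spread encodes
  subtype heterogeneity (largest for triple-negative tumors),
* ellipsoidal whole-tumor masks and Gaussian-random-field texture with a
  subtype-specific correlation length inside the lesion,
* the study's subtype imbalance, 26:68:18:22 for Luminal A / Luminal B /
  HER2-positive / TN (n = 134).

Everything is deterministic under a fixed seed; per-subject seeds are
derived from the cohort seed so subjects are independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seqradiomics.io import EXCLUSION_FLAGS
from seqradiomics.types import (
    DCE_TAGS,
    DWI_BVALUES,
    DWI_TAGS,
    FeatureMeta,
    FeatureTable,
    ImageSeries,
    ImageVolume,
    Subject,
    SUBTYPES,
    TumorMask,
)

#: Default subtype prevalence of the modeled cohort.
DEFAULT_CLASS_COUNTS = {"LuminalA": 26, "LuminalB": 68, "HER2pos": 18, "TN": 22}

#: DCE enhancement curve per subtype: (wash_in_slope, washout_slope,
#: peak_phase), as fractions of baseline signal per phase. Luminal A enhances
#: slowly and persistently; TN enhances fast and washes out early.
DCE_PARAMS = {
    "LuminalA": (0.12, 0.00, 5),
    "LuminalB": (0.25, 0.05, 3),
    "HER2pos": (0.35, 0.08, 2),
    "TN": (0.45, 0.12, 1),
}

#: DWI parameters per subtype: (S0, ADC mean mm^2/s, ADC heterogeneity sd).
#: TN is the most heterogeneous (most necrosis), with the lowest mean ADC.
DWI_PARAMS = {
    "LuminalA": (400.0, 1.10e-3, 0.08e-3),
    "LuminalB": (400.0, 0.95e-3, 0.12e-3),
    "HER2pos": (400.0, 0.90e-3, 0.15e-3),
    "TN": (400.0, 0.80e-3, 0.25e-3),
}

#: Gaussian-random-field smoothing length (mm) of intra-lesion texture.
TEXTURE_CORRELATION_MM = {
    "LuminalA": 0.5,
    "LuminalB": 1.0,
    "HER2pos": 1.5,
    "TN": 2.5,
}


@dataclass
class PhantomSpec:
    """Geometry, noise and per-subtype signal model of one phantom subject."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_semi_axes_mm: tuple[float, float, float] = (9.0, 8.0, 7.0)
    background_level: float = 100.0
    noise_sd: float = 5.0
    texture_amplitude: float = 15.0
    texture_correlation_mm: dict = field(
        default_factory=lambda: dict(TEXTURE_CORRELATION_MM))
    dce_params: dict = field(default_factory=lambda: dict(DCE_PARAMS))
    dwi_params: dict = field(default_factory=lambda: dict(DWI_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.lesion_semi_axes_mm):
            raise ValueError("lesion semi-axes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        if any(2 * a >= e for a, e in zip(self.lesion_semi_axes_mm, extent)):
            raise ValueError("lesion larger than grid")
        for label, (_, adc, _) in self.dwi_params.items():
            if adc <= 0:
                raise ValueError(f"ADC must be positive ({label})")


@dataclass
class CohortSpec:
    """Per-class subject counts and the shared phantom spec."""

    n_per_class: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if sum(1 for n in self.n_per_class.values() if n > 0) < 2:
            raise ValueError("cohort needs at least two nonempty classes")


@dataclass
class TableSpec:
    """Direct feature-table generator parameters.

    ``effect_size`` is the standardized between-class mean shift of each
    planted informative feature; the first ``n_correlated_blocks`` groups of
    ``block_size`` noise columns share a latent factor giving pairwise
    correlation ``block_correlation``.
    """

    n_subjects: int = 134
    n_features: int = 500
    n_informative: int = 10
    effect_size: float = 0.6
    n_correlated_blocks: int = 0
    block_size: int = 4
    block_correlation: float = 0.8
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        if not (-1 < self.block_correlation < 1):
            raise ValueError("|block correlation| must be < 1")
        if self.n_informative + self.n_correlated_blocks * self.block_size \
                > self.n_features:
            raise ValueError("planted blocks exceed feature count")


def _ellipsoid_mask(grid_shape, spacing, semi_axes) -> np.ndarray:
    coords = [(np.arange(n) - (n - 1) / 2.0) * s
              for n, s in zip(grid_shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    a, b, c = semi_axes
    return (zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2 <= 1.0


def _gaussian_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Unit-variance smoothed white noise (zero sigma returns white noise)."""
    from scipy import ndimage

    field_ = rng.standard_normal(shape)
    if sigma_vox > 0:
        field_ = ndimage.gaussian_filter(field_, sigma_vox)
        sd = field_.std()
        if sd > 0:
            field_ = field_ / sd
    return field_


def generate_phantom_subject(spec: PhantomSpec, label: str,
                             seed: int | None = None,
                             subject_id: str = "") -> Subject:
    """One phantom subject with DCE and DWI series plus ellipsoidal masks.

    The lesion-mean DCE intensity follows the subtype's piecewise-linear
    enhancement curve; the DWI lesion signal follows S0 exp(-b ADC) with a
    per-voxel ADC ~ N(mean, sd^2) truncated > 0.
    """
    if label not in SUBTYPES:
        raise ValueError(f"unknown subtype {label!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask_arr = _ellipsoid_mask(spec.grid_shape, spec.spacing, spec.lesion_semi_axes_mm)
    sigma_vox = spec.texture_correlation_mm[label] / float(np.mean(spec.spacing))
    texture = spec.texture_amplitude * _gaussian_field(rng, spec.grid_shape, sigma_vox)

    wash_in, washout, peak = spec.dce_params[label]
    base = spec.background_level
    dce_vols = []
    for t in range(6):
        enh = wash_in * min(t, peak) - washout * max(0, t - peak)
        img = np.full(spec.grid_shape, base, dtype=float)
        img[mask_arr] = base * (1.0 + enh) + texture[mask_arr]
        img += spec.noise_sd * rng.standard_normal(spec.grid_shape)
        dce_vols.append(ImageVolume(img, spec.spacing, axis_label=DCE_TAGS[t]))

    s0, adc_mean, adc_sd = spec.dwi_params[label]
    adc = adc_mean + adc_sd * rng.standard_normal(spec.grid_shape)
    adc = np.abs(adc)  # truncate > 0 (reflection keeps determinism simple)
    adc[adc == 0] = adc_mean
    dwi_vols = []
    for b, tag in zip(DWI_BVALUES, DWI_TAGS):
        img = np.full(spec.grid_shape, 0.1 * base, dtype=float)
        img[mask_arr] = s0 * np.exp(-b * adc[mask_arr]) \
            + 0.05 * texture[mask_arr]
        img += spec.noise_sd * rng.standard_normal(spec.grid_shape)
        dwi_vols.append(ImageVolume(img, spec.spacing, axis_label=tag))

    mask = TumorMask(mask_arr, spacing=spec.spacing)
    return Subject(
        id=subject_id or f"phantom_{label}_{seed if seed is not None else spec.seed}",
        dce=ImageSeries(dce_vols, "DCE_time", tuple(range(6))),
        dwi=ImageSeries(dwi_vols, "DWI_bvalue", DWI_BVALUES),
        dce_mask=mask,
        dwi_mask=TumorMask(mask_arr.copy(), spacing=spec.spacing),
        label=label,
    )


def _subject_seed(cohort_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def generate_image_cohort(spec: CohortSpec) -> list[Subject]:
    """Phantom subjects for every class, with derived per-subject seeds."""
    cohort: list[Subject] = []
    index = 0
    for label in SUBTYPES:
        for _ in range(spec.n_per_class.get(label, 0)):
            cohort.append(generate_phantom_subject(
                spec.phantom, label,
                seed=_subject_seed(spec.seed, index),
                subject_id=f"S{index:03d}_{label}",
            ))
            index += 1
    if not cohort:
        raise ValueError("empty cohort")
    return cohort


def _labels_from_counts(class_counts: dict, n_subjects: int) -> list[str]:
    names = [k for k in class_counts if class_counts[k] > 0]
    total = sum(class_counts[k] for k in names)
    counts = {k: int(round(class_counts[k] / total * n_subjects)) for k in names}
    # fix rounding drift on the largest class
    drift = n_subjects - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    labels = [k for k in names for _ in range(counts[k])]
    return labels[:n_subjects]


def generate_feature_table(spec: TableSpec) -> FeatureTable:
    """Gaussian feature table with planted class signal and correlated blocks.

    Informative columns get class-conditional means of magnitude
    ``effect_size`` (drawn once per feature from a standard normal across
    classes and centered, so the between-class standardized separation is on
    the stated scale); all columns have unit noise variance.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _labels_from_counts(spec.class_counts, spec.n_subjects)
    class_names = sorted(set(labels))
    y = np.array([class_names.index(l) for l in labels])
    n, p = spec.n_subjects, spec.n_features
    X = rng.standard_normal((n, p))

    # planted informative columns: class-specific mean offsets
    for j in range(spec.n_informative):
        offsets = rng.standard_normal(len(class_names))
        offsets = (offsets - offsets.mean())
        sd = offsets.std()
        if sd > 0:
            offsets = offsets / sd * spec.effect_size
        X[:, j] += offsets[y]

    # correlated noise blocks sharing one latent factor
    rho = spec.block_correlation
    if spec.n_correlated_blocks and rho < 0:
        raise ValueError("block correlation must be >= 0 for shared-factor blocks")
    start = spec.n_informative
    for b in range(spec.n_correlated_blocks):
        latent = rng.standard_normal(n)
        for k in range(spec.block_size):
            j = start + b * spec.block_size + k
            X[:, j] = (np.sqrt(rho) * latent
                       + np.sqrt(1 - rho) * rng.standard_normal(n))

    meta = []
    for j in range(p):
        if j < spec.n_informative:
            kind = "informative"
        elif j < start + spec.n_correlated_blocks * spec.block_size:
            kind = f"block{(j - start) // spec.block_size}"
        else:
            kind = "noise"
        meta.append(FeatureMeta("synthetic", kind, f"f{j:04d}"))
    return FeatureTable(
        values=X,
        subject_ids=[f"S{i:03d}" for i in range(n)],
        labels=labels,
        feature_meta=meta,
    )


def make_enrollment_table(n_enrolled: int = 190,
                          exclusion_counts: dict | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic enrollment table carrying the study's exclusion flags.

    Defaults reproduce the screening arithmetic of the modeled study:
    190 enrolled; 5 prior malignancy, 31 neoadjuvant chemotherapy, 16 lesion
    < 1 cm, 3 poor DWI fat saturation, 1 slice-count discordance (all
    disjoint), leaving 134.
    """
    if exclusion_counts is None:
        exclusion_counts = {
            "prior_malignancy": 5,
            "neoadjuvant_chemo": 31,
            "lesion_below_1cm": 16,
            "poor_fat_saturation_dwi": 3,
            "slice_count_discordance": 1,
        }
    unknown = set(exclusion_counts) - set(EXCLUSION_FLAGS)
    if unknown:
        raise ValueError(f"unknown exclusion flags: {unknown}")
    if sum(exclusion_counts.values()) > n_enrolled:
        raise ValueError("more exclusions than enrolled patients")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"patient_id": [f"P{i:03d}" for i in range(n_enrolled)]})
    for flag in EXCLUSION_FLAGS:
        df[flag] = False
    order = rng.permutation(n_enrolled)
    pos = 0
    for flag in EXCLUSION_FLAGS:
        k = exclusion_counts.get(flag, 0)
        df.loc[order[pos:pos + k], flag] = True
        pos += k
    return df
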