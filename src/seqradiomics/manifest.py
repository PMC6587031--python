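"""Frozen feature catalog.

The texture catalog is pinned to 92 features across the six standard
families (first-order 18, GLCM 23, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5);
the shape catalog to 14 mesh/axis descriptors; the sequential-statistic sets
to 10 (DCE) and 8 (DWI) names. Column identity of every feature table
depends on this ordering, so it must never be reordered.
"""

from __future__ import annotations

FIRST_ORDER_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median",
    "minimum", "maximum", "range", "percentile10", "percentile90",
    "interquartile_range", "mean_absolute_deviation",
    "robust_mean_absolute_deviation", "root_mean_squared",
    "energy", "total_energy", "entropy", "uniformity",
)

GLCM_FEATURES = (
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "idm", "idmn", "id", "idn",
    "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
    "sum_squares",
)

GLRLM_FEATURES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)

GLSZM_FEATURES = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)

GLDM_FEATURES = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_nonuniformity", "dependence_nonuniformity",
    "dependence_nonuniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
    "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

#: The 92-feature texture catalog as ordered (family, name) pairs.
TEXTURE_CATALOG: tuple[tuple[str, str], ...] = (
    tuple(("firstorder", n) for n in FIRST_ORDER_FEATURES)
    + tuple(("glcm", n) for n in GLCM_FEATURES)
    + tuple(("glrlm", n) for n in GLRLM_FEATURES)
    + tuple(("glszm", n) for n in GLSZM_FEATURES)
    + tuple(("gldm", n) for n in GLDM_FEATURES)
    + tuple(("ngtdm", n) for n in NGTDM_FEATURES)
)

#: Flat "family_name" ids in frozen order (length 92).
TEXTURE_FEATURE_IDS: tuple[str, ...] = tuple(
    f"{fam}_{name}" for fam, name in TEXTURE_CATALOG
)

SHAPE_FEATURES = (
    "mesh_volume", "voxel_volume", "surface_area", "surface_volume_ratio",
    "sphericity", "maximum_3d_diameter", "maximum_2d_diameter_slice",
    "maximum_2d_diameter_column", "maximum_2d_diameter_row",
    "major_axis_length", "minor_axis_length", "least_axis_length",
    "elongation", "flatness",
)

#: Per-subject trajectory statistics (computed from one subject's trajectory).
PER_SUBJECT_STATS = ("mean", "variance", "kurtosis", "skewness", "energy", "entropy")

#: Cohort-interactive trajectory statistics (computed against the remainder
#: of the cohort).
COHORT_STATS = ("kendall_tau_b", "conservation", "stability", "dispersion")

#: Sequential-statistic sets per modality. Kurtosis and entropy are dropped
#: for DWI because three b-values are too few to support them.
DCE_SEQUENTIAL_STATS = PER_SUBJECT_STATS + COHORT_STATS
DWI_SEQUENTIAL_STATS = tuple(
    s for s in DCE_SEQUENTIAL_STATS if s not in ("kurtosis", "entropy")
)

assert len(TEXTURE_CATALOG) == 92
assert len(SHAPE_FEATURES) == 14
assert len(DCE_SEQUENTIAL_STATS) == 10
assert len(DWI_SEQUENTIAL_STATS) == 8
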