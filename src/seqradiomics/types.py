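"""Core data model: image volumes/series, tumor masks, subjects, feature tables.

Grids are never resampled: a mask must share the exact voxel grid of the
series it annotates (the acquisitions of one modality are co-registered by
acquisition, and features from different modalities are pooled only at the
table level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four immunohistochemistry (IHC) subtypes, in canonical order.
SUBTYPES = ("LuminalA", "LuminalB", "HER2pos", "TN")

#: DCE acquisition tags: one pre-contrast phase and five post-contrast phases.
DCE_TAGS = tuple(f"DCE_phase{i}" for i in range(6))

#: DWI acquisition tags and their diffusion-sensitization b-values (s/mm^2).
DWI_BVALUES = (50.0, 400.0, 800.0)
DWI_TAGS = tuple(f"DWI_b{int(b)}" for b in DWI_BVALUES)

#: Feature-table column groups.
FEATURE_GROUPS = (
    "DCE_shape",
    "DCE_texture",
    "DCE_sequential",
    "DWI_texture",
    "DWI_sequential",
)


class GridMismatchError(ValueError):
    """Raised when a mask or volume does not share the expected voxel grid."""


class SeriesLengthError(ValueError):
    """Raised when a series does not have the required number of acquisitions."""


@dataclass
class ImageVolume:
    """A single 3D acquisition.

    Parameters
    ----------
    voxels
        3D array of finite real intensities.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        World coordinates of voxel (0, 0, 0) in mm.
    axis_label
        Acquisition tag, e.g. ``"DCE_phase0"`` or ``"DWI_b800"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def same_grid(self, other: "ImageVolume | TumorMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class TumorMask:
    """Binary whole-tumor segmentation on the grid of one acquisition series."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.voxels.ndim}")
        if not self.voxels.any():
            raise ValueError("mask must contain at least one foreground voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other: "ImageVolume | TumorMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class ImageSeries:
    """Ordered stack of co-registered volumes along an acquisition axis.

    ``axis_kind`` is ``"DCE_time"`` (six phases, axis values 0..5) or
    ``"DWI_bvalue"`` (three b-values 50/400/800 s/mm^2).
    """

    volumes: list[ImageVolume]
    axis_kind: str
    axis_values: tuple[float, ...]

    EXPECTED_LENGTH = {"DCE_time": 6, "DWI_bvalue": 3}

    def __post_init__(self) -> None:
        if self.axis_kind not in self.EXPECTED_LENGTH:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        expected = self.EXPECTED_LENGTH[self.axis_kind]
        if len(self.volumes) != expected:
            raise SeriesLengthError(
                f"{self.axis_kind} series requires {expected} volumes, "
                f"got {len(self.volumes)}"
            )
        self.axis_values = tuple(float(v) for v in self.axis_values)
        if len(self.axis_values) != len(self.volumes):
            raise ValueError("axis_values length must match volume count")
        if not all(b > a for a, b in zip(self.axis_values, self.axis_values[1:])):
            raise ValueError("axis_values must be strictly increasing")
        ref = self.volumes[0]
        for vol in self.volumes[1:]:
            if not ref.same_grid(vol):
                raise GridMismatchError("all volumes of a series must share one grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class Subject:
    """One patient: DCE and DWI series with per-modality whole-tumor masks."""

    id: str
    dce: ImageSeries
    dwi: ImageSeries
    dce_mask: TumorMask
    dwi_mask: TumorMask
    label: str

    def __post_init__(self) -> None:
        if self.label not in SUBTYPES:
            raise ValueError(f"label must be one of {SUBTYPES}, got {self.label!r}")
        if self.dce.axis_kind != "DCE_time":
            raise ValueError("dce series must have axis_kind 'DCE_time'")
        if self.dwi.axis_kind != "DWI_bvalue":
            raise ValueError("dwi series must have axis_kind 'DWI_bvalue'")
        if not self.dce_mask.same_grid(self.dce.volumes[0]):
            raise GridMismatchError(f"subject {self.id}: DCE mask grid mismatch")
        if not self.dwi_mask.same_grid(self.dwi.volumes[0]):
            raise GridMismatchError(f"subject {self.id}: DWI mask grid mismatch")


@dataclass
class FeatureMeta:
    """Provenance of one feature-table column."""

    group: str
    source: str  # acquisition tag, or "trajectory" for sequential features
    base_feature: str
    statistic: str = ""  # sequential-statistic name, "" for static features

    @property
    def column_id(self) -> str:
        parts = [self.group, self.source, self.base_feature]
        if self.statistic:
            parts.append(self.statistic)
        return "|".join(parts)


@dataclass
class FeatureTable:
    """Subjects x features matrix with per-column provenance.

    ``values`` is an (N, P) float array aligned with ``subject_ids`` (rows)
    and ``feature_meta`` (columns).
    """

    values: np.ndarray
    subject_ids: list[str]
    labels: list[str]
    feature_meta: list[FeatureMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D subjects x features matrix")
        n, p = self.values.shape
        if n == 0:
            raise ValueError("feature table must have at least one subject")
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids and labels must match the row count")
        if len(self.feature_meta) != p:
            raise ValueError("feature_meta must describe every column")
        ids = [m.column_id for m in self.feature_meta]
        if len(set(ids)) != p:
            raise ValueError("feature metadata must uniquely identify each column")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_ids(self) -> list[str]:
        return [m.column_id for m in self.feature_meta]

    def columns_in_group(self, group: str) -> list[int]:
        return [j for j, m in enumerate(self.feature_meta) if m.group == group]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_ids)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        return df

    def subset(self, column_indices: list[int]) -> "FeatureTable":
        return FeatureTable(
            values=self.values[:, column_indices],
            subject_ids=list(self.subject_ids),
            labels=list(self.labels),
            feature_meta=[self.feature_meta[j] for j in column_indices],
        )
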