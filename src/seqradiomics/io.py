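"""Readers/writers (NIfTI volumes, CSV feature tables), mask propagation,
and the study-population screening rule."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from seqradiomics.types import (
    DCE_TAGS,
    DWI_BVALUES,
    DWI_TAGS,
    FeatureMeta,
    FeatureTable,
    GridMismatchError,
    ImageSeries,
    ImageVolume,
    SeriesLengthError,
    Subject,
    TumorMask,
)

log = logging.getLogger("seqradiomics")


# ---------------------------------------------------------------------------
# NIfTI volumes and masks
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(path: str | Path, voxels: np.ndarray,
                 spacing: Sequence[float] = (1.0, 1.0, 1.0),
                 origin: Sequence[float] = (0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float32),
                          _affine(spacing, origin))
    nib.save(img, str(path))


def read_volume(path: str | Path, axis_label: str = "") -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(aff))
    origin = tuple(float(o) for o in aff[:3, 3])
    return ImageVolume(np.asarray(img.get_fdata(), dtype=float),
                       spacing=spacing, origin=origin, axis_label=axis_label)


def read_mask(path: str | Path) -> TumorMask:
    vol = read_volume(path)
    return TumorMask(vol.voxels > 0.5, spacing=vol.spacing, origin=vol.origin)


def read_subject(subject_id: str,
                 dce_paths: Sequence[str | Path],
                 dce_mask_path: str | Path,
                 dwi_paths: Sequence[str | Path],
                 dwi_mask_path: str | Path,
                 label: str) -> Subject:
    """Load and validate one subject from NIfTI files.

    Requires exactly 6 DCE volumes (pre-contrast + 5 post-contrast phases,
    in order) and 3 DWI volumes (b = 50, 400, 800 s/mm^2, in order), with one
    whole-tumor mask per modality on the matching grid.
    """
    if len(dce_paths) != 6:
        raise SeriesLengthError(f"expected 6 DCE volumes, got {len(dce_paths)}")
    if len(dwi_paths) != 3:
        raise SeriesLengthError(f"expected 3 DWI volumes, got {len(dwi_paths)}")
    for p in [*dce_paths, dce_mask_path, *dwi_paths, dwi_mask_path]:
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    dce = ImageSeries(
        volumes=[read_volume(p, tag) for p, tag in zip(dce_paths, DCE_TAGS)],
        axis_kind="DCE_time",
        axis_values=tuple(range(6)),
    )
    dwi = ImageSeries(
        volumes=[read_volume(p, tag) for p, tag in zip(dwi_paths, DWI_TAGS)],
        axis_kind="DWI_bvalue",
        axis_values=DWI_BVALUES,
    )
    return Subject(
        id=subject_id,
        dce=dce,
        dwi=dwi,
        dce_mask=read_mask(dce_mask_path),
        dwi_mask=read_mask(dwi_mask_path),
        label=label,
    )


def propagate_mask(mask: TumorMask, series: ImageSeries) -> list[TumorMask]:
    """Propagate one whole-tumor mask to every volume of a series.

    The acquisitions of one modality are co-registered, so propagation is the
    identity on the shared grid: each volume receives an exact copy.
    """
    if not mask.same_grid(series.volumes[0]):
        raise GridMismatchError("mask grid does not match series grid")
    return [
        TumorMask(mask.voxels.copy(), spacing=mask.spacing, origin=mask.origin)
        for _ in series.volumes
    ]


# ---------------------------------------------------------------------------
# Feature tables: CSV with a JSON metadata sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly through text
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    meta = [
        {"group": m.group, "source": m.source,
         "base_feature": m.base_feature, "statistic": m.statistic}
        for m in table.feature_meta
    ]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "label" not in df.columns:
        raise ValueError("malformed feature table: missing subject_id/label columns")
    cols = list(df.columns[2:])
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate feature column ids")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = [FeatureMeta(**d) for d in json.loads(sidecar.read_text())]
        if [m.column_id for m in meta] != cols:
            raise ValueError("metadata sidecar does not match table columns")
    else:
        meta = []
        for c in cols:
            parts = c.split("|")
            if len(parts) < 3:
                parts = [c, "", c]
            meta.append(FeatureMeta(group=parts[0], source=parts[1],
                                    base_feature=parts[2],
                                    statistic=parts[3] if len(parts) > 3 else ""))
    return FeatureTable(
        values=df[cols].to_numpy(dtype=float),
        subject_ids=[str(s) for s in df["subject_id"]],
        labels=[str(s) for s in df["label"]],
        feature_meta=meta,
    )


# ---------------------------------------------------------------------------
# Study-population screening
# ---------------------------------------------------------------------------

#: Exclusion rules applied to the enrolled cohort, in order. Each is a column
#: of the enrollment table holding a boolean flag.
EXCLUSION_FLAGS = (
    "prior_malignancy",
    "neoadjuvant_chemo",
    "lesion_below_1cm",
    "poor_fat_saturation_dwi",
    "slice_count_discordance",
)


def screen_cohort(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Apply the study's exclusion criteria to an enrollment table.

    A patient is retained iff every exclusion flag is False. Multicentric /
    multifocal disease does not exclude a patient (the largest lesion is
    analyzed), so it is not a flag here.
    """
    missing = [f for f in EXCLUSION_FLAGS if f not in enrollment.columns]
    if missing:
        raise ValueError(f"enrollment table missing flags: {missing}")
    keep = ~enrollment[list(EXCLUSION_FLAGS)].astype(bool).any(axis=1)
    excluded = int((~keep).sum())
    log.info("screening: %d enrolled, %d excluded, %d retained",
             len(enrollment), excluded, int(keep.sum()))
    return enrollment[keep].reset_index(drop=True)
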