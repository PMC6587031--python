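"""Cohort-level feature extraction: static catalog and sequential augmentation.

The static catalog per subject is 14 shape features (first post-contrast DCE
mask) + 92 texture features on each of the 9 acquisitions (6 DCE phases +
3 DWI b-values) = 842 columns. Sequential augmentation adds, for every base
texture feature, 10 DCE-trajectory statistics and 8 DWI-trajectory
statistics: 920 + 736 columns, a full catalog of 2,498.
"""

from __future__ import annotations

import logging

import numpy as np

from seqradiomics.manifest import (
    DCE_SEQUENTIAL_STATS,
    DWI_SEQUENTIAL_STATS,
    SHAPE_FEATURES,
    TEXTURE_FEATURE_IDS,
)
from seqradiomics.sequential import sequential_stats_for_matrix
from seqradiomics.shape import compute_shape_features
from seqradiomics.texture import compute_texture_features
from seqradiomics.types import (
    DCE_TAGS,
    DWI_TAGS,
    FeatureMeta,
    FeatureTable,
    Subject,
)

log = logging.getLogger("seqradiomics")


def static_feature_meta() -> list[FeatureMeta]:
    """Column metadata of the 842-column static catalog, in frozen order."""
    meta = [FeatureMeta("DCE_shape", DCE_TAGS[1], name) for name in SHAPE_FEATURES]
    for tag in DCE_TAGS:
        meta += [FeatureMeta("DCE_texture", tag, fid) for fid in TEXTURE_FEATURE_IDS]
    for tag in DWI_TAGS:
        meta += [FeatureMeta("DWI_texture", tag, fid) for fid in TEXTURE_FEATURE_IDS]
    return meta


def sequential_feature_meta() -> list[FeatureMeta]:
    """Column metadata of the 920 + 736 sequential columns, in frozen order."""
    meta = [
        FeatureMeta("DCE_sequential", "trajectory", fid, stat)
        for fid in TEXTURE_FEATURE_IDS
        for stat in DCE_SEQUENTIAL_STATS
    ]
    meta += [
        FeatureMeta("DWI_sequential", "trajectory", fid, stat)
        for fid in TEXTURE_FEATURE_IDS
        for stat in DWI_SEQUENTIAL_STATS
    ]
    return meta


def _impute_nonfinite(values: np.ndarray, context: str) -> np.ndarray:
    bad = ~np.isfinite(values)
    if bad.any():
        log.warning("%s: imputing %d non-finite values to 0", context, int(bad.sum()))
        values = np.where(bad, 0.0, values)
    return values


def extract_subject_static(subject: Subject, bin_count: int = 32) -> np.ndarray:
    """The 842 static feature values of one subject, in catalog order."""
    row: list[float] = []
    shape = compute_shape_features(subject.dce_mask)
    row += [shape[name] for name in SHAPE_FEATURES]
    for vol in subject.dce.volumes:
        tex = compute_texture_features(vol, subject.dce_mask, bin_count)
        row += [tex[fid] for fid in TEXTURE_FEATURE_IDS]
    for vol in subject.dwi.volumes:
        tex = compute_texture_features(vol, subject.dwi_mask, bin_count)
        row += [tex[fid] for fid in TEXTURE_FEATURE_IDS]
    return np.asarray(row, dtype=float)


def extract_static_features(cohort: list[Subject], bin_count: int = 32) -> FeatureTable:
    """Static 842-column feature table for a cohort (rows in cohort order)."""
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    for subject in cohort:
        try:
            rows.append(extract_subject_static(subject, bin_count))
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for subject {subject.id}: {exc}"
            ) from exc
    values = _impute_nonfinite(np.stack(rows), "static extraction")
    return FeatureTable(
        values=values,
        subject_ids=[s.id for s in cohort],
        labels=[s.label for s in cohort],
        feature_meta=static_feature_meta(),
    )


def assemble_sequential(static: FeatureTable) -> FeatureTable:
    """Augment a static table with the 1,656 sequential columns.

    For each base texture feature the per-subject DCE trajectory is its value
    across the 6 phases (in phase order) and the DWI trajectory its value
    across the 3 b-values; the sequential statistics of those trajectories
    become new columns (source ``"trajectory"``).
    """
    col_of = {m.column_id: j for j, m in enumerate(static.feature_meta)}
    blocks = [static.values]
    for group, tags, stats in (
        ("DCE_texture", DCE_TAGS, DCE_SEQUENTIAL_STATS),
        ("DWI_texture", DWI_TAGS, DWI_SEQUENTIAL_STATS),
    ):
        for fid in TEXTURE_FEATURE_IDS:
            try:
                idx = [col_of[f"{group}|{tag}|{fid}"] for tag in tags]
            except KeyError as exc:
                raise ValueError(f"static table missing acquisition column: {exc}")
            M = static.values[:, idx]
            blocks.append(sequential_stats_for_matrix(M, stats))
    values = _impute_nonfinite(np.hstack(blocks), "sequential assembly")
    return FeatureTable(
        values=values,
        subject_ids=list(static.subject_ids),
        labels=list(static.labels),
        feature_meta=list(static.feature_meta) + sequential_feature_meta(),
    )


def extract_all_features(cohort: list[Subject], bin_count: int = 32) -> FeatureTable:
    """Full 2,498-column feature table: static catalog + sequential statistics."""
    return assemble_sequential(extract_static_features(cohort, bin_count))
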