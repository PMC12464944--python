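"""Delimited-text and NIfTI readers/writers.

Edge matrices are tab-delimited, subjects x edges, with a header naming
each edge by its 1-based ROI id pair ``e<i>_<j>`` in row-major
upper-triangle order; values round-trip at 15 significant digits.
Metadata tables use the documented column names below.  Atlas label
images and lesion masks are NIfTI volumes (affine preserved on
round-trip by the lesion_mapping helpers).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import edge_pairs
from .synthetic_cohort import Atlas, SubjectRecord, SyntheticCohort

__all__ = [
    "edge_columns",
    "write_edge_table",
    "read_edge_table",
    "write_metadata",
    "read_metadata",
    "write_atlas",
    "read_atlas",
    "write_cohort",
]

METADATA_COLUMNS = ("subject_id", "group", "age", "sex", "idh", "who_grade",
                    "lesion_volume")


def edge_columns(n_rois: int) -> list[str]:
    """Header names e<i>_<j> (1-based ROI ids, i < j, row-major)."""
    return [f"e{i + 1}_{j + 1}" for i, j in edge_pairs(n_rois)]


def write_edge_table(path, edges: np.ndarray, n_rois: int, subject_ids=None) -> None:
    edges = np.asarray(edges, dtype=float)
    cols = edge_columns(n_rois)
    if edges.shape[1] != len(cols):
        raise ValueError(f"expected {len(cols)} edges for {n_rois} ROIs, got {edges.shape[1]}")
    idx = subject_ids if subject_ids is not None else range(len(edges))
    df = pd.DataFrame(edges, columns=cols, index=pd.Index(idx, name="subject_id"))
    df.to_csv(path, sep="\t", float_format="%.15g")


def read_edge_table(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return df.to_numpy(dtype=float), df.index.astype(str).tolist()


def write_metadata(path, subjects: list[SubjectRecord]) -> None:
    rows = [{c: getattr(s, c) for c in METADATA_COLUMNS} for s in subjects]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            idh=str(row["idh"]) or "NA",
            who_grade=str(row["who_grade"]) or "NA",
            lesion_volume=int(row["lesion_volume"]),
        ))
    return out


def write_atlas(path, atlas: Atlas) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(atlas.label_image.astype(np.int32), atlas.affine),
             str(path))


def read_atlas(path, n_per_hemisphere: int) -> Atlas:
    import nibabel as nib

    img = nib.load(str(path))
    return Atlas(label_image=np.asarray(img.dataobj).astype(np.int32),
                 n_per_hemisphere=n_per_hemisphere, affine=img.affine)


def write_cohort(directory, cohort: SyntheticCohort) -> None:
    """Write a cohort as text + NIfTI: metadata, edges, atlas, lesion masks."""
    import nibabel as nib

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_metadata(d / "metadata.tsv", list(cohort.subjects))
    write_edge_table(d / "edges.tsv", cohort.edges, cohort.atlas.n_per_hemisphere,
                     subject_ids=[s.subject_id for s in cohort.subjects])
    write_atlas(d / "atlas.nii.gz", cohort.atlas)
    for s in cohort.subjects:
        if s.lesion_mask_ref is not None:
            mask = cohort.masks[s.lesion_mask_ref]
            nib.save(nib.Nifti1Image(mask.voxels.astype(np.int8), cohort.atlas.affine),
                     str(d / f"lesion_{s.subject_id}.nii.gz"))
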