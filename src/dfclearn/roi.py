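"""Node time-series extraction from 4D NIfTI volumes.

Each node is a sphere of configurable radius around an MNI-mm centroid;
the node signal at each volume is the mean over voxels whose world-space
centers lie within the sphere (Euclidean distance, coordinates from the
image affine — voxel centers, not corners).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import DesignSchedule, NodeSet
from .exceptions import DataError
from .synth import NodeTimeSeries, SubjectRecord

logger = logging.getLogger(__name__)


def read_centroid_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited centroid table with columns node, x, y, z (mm)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"node", "x", "y", "z"}
    if not required.issubset(frame.columns):
        raise DataError(f"centroid table needs columns {sorted(required)}")
    return frame


def sphere_masks(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    centroids: np.ndarray,
    radius_mm: float,
) -> list[np.ndarray]:
    """Boolean in-sphere masks (one per centroid) over the voxel grid."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = nib.affines.apply_affine(affine, vox)
    masks = []
    for c in np.atleast_2d(centroids):
        d2 = ((world - np.asarray(c, dtype=float)) ** 2).sum(axis=1)
        masks.append((d2 <= radius_mm**2).reshape(shape))
    return masks


def _sphere_clipped_by_fov(
    shape: tuple[int, int, int], affine: np.ndarray, centroid: np.ndarray, radius: float
) -> bool:
    # sphere bounding box in voxel coordinates vs grid extent
    inv = np.linalg.inv(affine)
    corners = centroid + radius * np.array(
        [[dx, dy, dz] for dx in (-1, 1) for dy in (-1, 1) for dz in (-1, 1)]
    )
    vox = nib.affines.apply_affine(inv, corners)
    return bool(np.any(vox < -0.5) or np.any(vox > np.array(shape) - 0.5))


def extract_roi_timeseries(
    nifti_path: str | Path,
    centroids: pd.DataFrame,
    radius_mm: float,
    subject: SubjectRecord,
    schedule: DesignSchedule,
) -> NodeTimeSeries:
    """Average each node sphere's voxels over the 4D image.

    Raises
    ------
    DataError
        If the image is missing/not 4D, a node's sphere contains no
        in-image voxel, or the volume count mismatches the schedule.
    """
    path = Path(nifti_path)
    if not path.exists():
        raise DataError(f"image not found: {path}")
    if not radius_mm > 0:
        raise DataError("radius_mm must be > 0")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DataError(f"expected a 4D image, got {data.ndim}D")
    shape3 = data.shape[:3]
    points = centroids[["x", "y", "z"]].to_numpy(dtype=float)
    labels = tuple(str(n) for n in centroids["node"])
    masks = sphere_masks(shape3, img.affine, points, radius_mm)
    series = np.empty((data.shape[3], len(labels)))
    for col, (label, mask, c) in enumerate(zip(labels, masks, points)):
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise DataError(f"node {label!r}: sphere contains no in-image voxel")
        if _sphere_clipped_by_fov(shape3, img.affine, c, radius_mm):
            logger.warning(
                "node %s: sphere extends beyond the field of view; "
                "averaging %d in-image voxels only", label, n_vox,
            )
        series[:, col] = data[mask, :].mean(axis=0)
    return NodeTimeSeries(
        subject=subject, schedule=schedule, node_labels=labels, data=series
    )


def write_synthetic_sphere_image(
    path: str | Path,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    centroid: np.ndarray,
    radius_mm: float,
    n_volumes: int,
    inside_value: float = 7.0,
    outside_value: float = 0.0,
) -> None:
    """Write a synthetic 4D test fixture: constant value inside one sphere.

    Only used to exercise the extractor; not a simulation of fMRI data.
    """
    mask = sphere_masks(shape, affine, np.asarray(centroid)[None, :], radius_mm)[0]
    vol = np.full(shape, outside_value, dtype=np.float32)
    vol[mask] = inside_value
    data = np.repeat(vol[..., None], n_volumes, axis=3)
    nib.Nifti1Image(data, affine).to_filename(str(path))
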