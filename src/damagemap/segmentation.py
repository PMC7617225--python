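"""Marker-positive cell identification by threshold-and-superimpose.

Given an externally produced nuclei instance segmentation (e.g. a Cellpose
label volume, consumed as input) and the marker channels, this module

1. thresholds a marker channel into a binary mask (Otsu by default — the
   marker foreground is far brighter than autofluorescence background — or a
   fixed value),
2. superimposes the mask on the instance segmentation and keeps nuclei whose
   overlap fraction is significant (default: majority overlap, >= 0.5),
   optionally dilating each instance first — required for CD8, whose
   immunomarker binds the cell membrane and therefore rings the nucleus
   rather than filling it, and
3. extracts per-cell records and 64x64 gamma-H2AX patches for the texture
   branches.

Dilation never merges instances: every dilated voxel belongs to the nearest
original instance (Euclidean distance), so overlap fractions stay per-cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.transform import resize

from .volume_io import CellTable, ChannelVolume, Condition, LabelVolume

logger = logging.getLogger(__name__)


class ThresholdMethod(str, Enum):
    OTSU = "OTSU"
    FIXED = "FIXED"


@dataclass
class MarkerMask:
    """Binary marker-positivity mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_value: float
    method: ThresholdMethod


@dataclass
class SegmentationConfig:
    """Positivity-call parameters.

    ``min_overlap_frac`` quantifies "significant overlap": the fraction of a
    nucleus' (possibly dilated) voxels that must fall inside the marker mask.
    gamma-H2AX is nuclear, so its call uses no dilation; CD8 is membranous,
    so its instances are dilated by ``cd8_dilation_vox`` voxels first.
    """

    min_overlap_frac: float = 0.5
    cd8_min_overlap_frac: float = 0.2
    cd8_dilation_vox: int = 2
    patch_size: int = 64
    mask_background: bool = True


def threshold_channel(
    channel: ChannelVolume,
    method: ThresholdMethod | str = ThresholdMethod.OTSU,
    fixed_value: float | None = None,
) -> MarkerMask:
    """Binarize a marker channel; mask = intensity > threshold."""
    method = ThresholdMethod(method)
    data = np.asarray(channel.data)
    if method is ThresholdMethod.FIXED:
        if fixed_value is None:
            raise ValueError("FIXED thresholding requires fixed_value")
        thr = float(fixed_value)
    else:
        if data.min() == data.max():
            raise ValueError(
                "constant-intensity channel: Otsu is undefined; use method=FIXED"
            )
        thr = float(threshold_otsu(data))
    return MarkerMask(mask=data > thr, threshold_value=thr, method=method)


def _dilated_labels(labels: np.ndarray, dilate_by: int) -> np.ndarray:
    """Grow every instance by ``dilate_by`` voxels without merging.

    Each background voxel within the dilation radius is assigned to its
    nearest original instance (Euclidean distance transform), so instances
    that would collide simply split the contested voxels.
    """
    if dilate_by <= 0:
        return labels
    dist, (iz, iy, ix) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    grown = labels[iz, iy, ix]
    grown = np.where(dist <= dilate_by, grown, 0)
    return grown


def superimpose_filter(
    labels: LabelVolume,
    mask: MarkerMask,
    min_overlap_frac: float = 0.5,
    dilate_labels_by: int = 0,
) -> list[tuple[int, float, bool]]:
    """Per-instance overlap of (dilated) nuclei with a marker mask.

    Returns ``(cell_id, overlap_frac, positive)`` per instance, where
    ``overlap_frac = |dilated instance ∩ mask| / |dilated instance|`` and a
    cell is positive iff the fraction reaches ``min_overlap_frac``.
    """
    if not 0.0 < min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must lie in (0, 1]")
    if dilate_labels_by < 0:
        raise ValueError("dilate_labels_by must be >= 0")
    lab = np.asarray(labels.labels)
    m = np.asarray(mask.mask, dtype=bool)
    if lab.shape != m.shape:
        raise ValueError(f"shape mismatch: labels {lab.shape} vs mask {m.shape}")
    grown = _dilated_labels(lab, dilate_labels_by)
    nmax = int(grown.max()) + 1
    sizes = np.bincount(grown.ravel(), minlength=nmax)
    inter = np.bincount(grown.ravel(), weights=m.ravel(), minlength=nmax)
    out = []
    for cid in labels.instance_ids():
        size = sizes[cid]
        frac = float(inter[cid] / size) if size > 0 else 0.0
        out.append((int(cid), frac, frac >= min_overlap_frac))
    return out


def build_cell_table(
    labels: LabelVolume,
    gh2ax: MarkerMask,
    cd8: MarkerMask,
    cfg: SegmentationConfig | None = None,
    condition: Condition = Condition.UNKNOWN,
    region_id: str = "",
) -> CellTable:
    """One record per nucleus with centroid, bbox and both positivity calls.

    Centroids are intensity-unweighted voxel means; bounding boxes are
    half-open and 0-based. The gamma-H2AX call uses undilated instances,
    the CD8 call the configured membrane dilation.
    """
    import pandas as pd

    cfg = cfg or SegmentationConfig()
    lab = np.asarray(labels.labels)
    cols = [
        "cell_id", "centroid_z", "centroid_y", "centroid_x", "voxel_count",
        "z0", "y0", "x0", "z1", "y1", "x1",
        "gh2ax_overlap_frac", "cd8_overlap_frac", "gh2ax_pos", "cd8_pos",
    ]
    if lab.max() == 0:
        return CellTable(pd.DataFrame(columns=cols), condition, region_id, labels.voxel_size_um)

    gh = {cid: (frac, pos) for cid, frac, pos in
          superimpose_filter(labels, gh2ax, cfg.min_overlap_frac, dilate_labels_by=0)}
    cd = {cid: (frac, pos) for cid, frac, pos in
          superimpose_filter(labels, cd8, cfg.cd8_min_overlap_frac, cfg.cd8_dilation_vox)}

    rows = []
    for prop in regionprops(lab):
        cid = int(prop.label)
        cz, cy, cx = prop.centroid
        z0, y0, x0, z1, y1, x1 = prop.bbox
        rows.append(
            dict(
                cell_id=cid,
                centroid_z=cz, centroid_y=cy, centroid_x=cx,
                voxel_count=int(prop.area),
                z0=z0, y0=y0, x0=x0, z1=z1, y1=y1, x1=x1,
                gh2ax_overlap_frac=gh[cid][0], cd8_overlap_frac=cd[cid][0],
                gh2ax_pos=gh[cid][1], cd8_pos=cd[cid][1],
            )
        )
    df = pd.DataFrame(rows, columns=cols)
    logger.info(
        "region %s: %d nuclei, %d gamma-H2AX+, %d CD8+",
        region_id or "<unnamed>", len(df), int(df.gh2ax_pos.sum()), int(df.cd8_pos.sum()),
    )
    return CellTable(df, condition, region_id, labels.voxel_size_um)


def extract_patch(
    channel: ChannelVolume,
    record,
    labels: LabelVolume,
    size: int = 64,
    mask_background: bool = True,
) -> np.ndarray | None:
    """Cut one nucleus into a ``size x size`` patch scaled to [0, 1].

    Takes the central-z slice of the record's bounding box from the marker
    channel, zeroes voxels outside the instance mask (so neighboring nuclei
    do not contaminate the texture), centers it on the canvas — padding if
    smaller, isotropically rescaling if larger — then min-max scales.
    A constant patch maps to all zeros. Returns None (with a warning) for
    bounding boxes degenerate in y or x.
    """
    z0, y0, x0 = int(record["z0"]), int(record["y0"]), int(record["x0"])
    z1, y1, x1 = int(record["z1"]), int(record["y1"]), int(record["x1"])
    if (y1 - y0) < 2 or (x1 - x0) < 2:
        warnings.warn(
            f"cell {record['cell_id']}: bbox degenerate in y or x, skipping patch"
        )
        return None
    zc = (z0 + z1 - 1) // 2  # central plane of the half-open z extent
    sl = np.asarray(channel.data[zc, y0:y1, x0:x1], dtype=np.float64)
    if sl.max() - sl.min() <= 0:
        # constant slice carries no texture; the min-max decision maps it to zeros
        return np.zeros((size, size), dtype=np.float64)
    if mask_background:
        inst = np.asarray(labels.labels[zc, y0:y1, x0:x1]) == int(record["cell_id"])
        sl = np.where(inst, sl, 0.0)
    h, w = sl.shape
    if h > size or w > size:
        scale = size / max(h, w)
        nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
        sl = resize(sl, (nh, nw), order=1, anti_aliasing=True, preserve_range=True)
        h, w = sl.shape
    canvas = np.zeros((size, size), dtype=np.float64)
    oy, ox = (size - h) // 2, (size - w) // 2
    canvas[oy : oy + h, ox : ox + w] = sl
    lo, hi = canvas.min(), canvas.max()
    if hi - lo <= 0:
        return np.zeros((size, size), dtype=np.float64)
    return (canvas - lo) / (hi - lo)


def extract_patches(
    channel: ChannelVolume,
    table: CellTable,
    labels: LabelVolume,
    size: int = 64,
    mask_background: bool = True,
    positives_only: bool = True,
) -> dict[int, np.ndarray]:
    """Patches for every (by default gamma-H2AX-positive) cell in a table."""
    out: dict[int, np.ndarray] = {}
    df = table.df
    if positives_only:
        df = df[df["gh2ax_pos"]]
    for _, rec in df.iterrows():
        patch = extract_patch(channel, rec, labels, size=size, mask_background=mask_background)
        if patch is not None:
            out[int(rec["cell_id"])] = patch
    return out
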