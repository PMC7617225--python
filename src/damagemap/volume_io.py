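"""Reading and writing of image volumes, label volumes and tabular outputs.

Conventions used throughout the package:

* All volumes are indexed ``(z, y, x)`` — plane-major, the usual storage
  order of confocal z-stacks.
* Physical voxel size is carried as a ``(z, y, x)`` triple in micrometers.
  The default lateral pixel size is 10.28/32 = 0.32125 um/px; the axial
  step defaults to the lateral size (isotropic treatment), and is
  configurable because acquisition z-steps vary between experiments.
* Tables are CSV files with a JSON sidecar (``<path>.json``) carrying the
  metadata that does not fit a rectangular table: condition, region id and
  voxel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Lateral pixel pitch in micrometers implied by 32 px == 10.28 um.
DEFAULT_LATERAL_UM = 10.28 / 32.0

#: Default isotropic voxel size (z, y, x) in micrometers.
DEFAULT_VOXEL_SIZE_UM = (DEFAULT_LATERAL_UM, DEFAULT_LATERAL_UM, DEFAULT_LATERAL_UM)


class ChannelName(str, Enum):
    DAPI = "DAPI"
    GH2AX = "GH2AX"
    CD8 = "CD8"
    PAN = "PAN"


class Condition(str, Enum):
    CONTROL = "CONTROL"
    TREATED = "TREATED"
    UNKNOWN = "UNKNOWN"


def px_to_um(px: float, voxel_size_um: Sequence[float] = DEFAULT_VOXEL_SIZE_UM) -> float:
    """Convert a length in lateral pixels to micrometers."""
    return float(px) * float(voxel_size_um[2])


@dataclass
class ChannelVolume:
    """One named fluorescence channel as a 3D ``(z, y, x)`` intensity array."""

    data: np.ndarray
    channel_name: ChannelName
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"ChannelVolume needs a 3D (z, y, x) array, got ndim={self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")
        self.channel_name = ChannelName(self.channel_name)
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive floats, got {vs}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """3D instance map of nuclei; 0 is background, positive ints are instances.

    Instance ids need not be contiguous; each id labels exactly one nucleus.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelVolume needs a 3D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(
                "label volume must be integer-typed; cast explicitly if the "
                "source is float (values would be reinterpreted silently)"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellTable:
    """Per-cell records for one region (see :mod:`damagemap.segmentation`)."""

    df: pd.DataFrame
    condition: Condition = Condition.UNKNOWN
    region_id: str = ""
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if len(self.df) and self.df["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique within a region")


# ---------------------------------------------------------------------------
# Volume I/O


def read_volume(
    path: str | Path,
    channel_name: ChannelName | str,
    voxel_size_um: Sequence[float] = DEFAULT_VOXEL_SIZE_UM,
    channel_order: Sequence[str] | None = None,
    channel_axis: int = 0,
) -> ChannelVolume:
    """Read a 3D (or 4D multi-channel) TIFF/OME-TIFF as a ChannelVolume.

    4D stacks are sliced to the requested channel using ``channel_order``, a
    declared list of channel names in file order (metadata heuristics are
    deliberately not used). ``channel_axis`` says which axis of the 4D array
    holds channels (default 0, i.e. CZYX).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channel_name = ChannelName(channel_name)
    arr = tifffile.imread(path)
    if arr.ndim == 4:
        if channel_order is None:
            raise ValueError(
                "4D stack requires channel_order (declared channel names in file order)"
            )
        names = [ChannelName(c) for c in channel_order]
        if channel_name not in names:
            raise KeyError(f"channel {channel_name.value} not in declared order {channel_order}")
        idx = names.index(channel_name)
        if idx >= arr.shape[channel_axis]:
            raise IndexError(
                f"channel index {idx} out of range for axis {channel_axis} "
                f"of size {arr.shape[channel_axis]}"
            )
        arr = np.take(arr, idx, axis=channel_axis)
    elif arr.ndim != 3:
        raise ValueError(
            f"expected a 3D volume or 4D multi-channel stack, got ndim={arr.ndim} "
            f"with shape {arr.shape}"
        )
    return ChannelVolume(arr, channel_name, tuple(voxel_size_um))  # type: ignore[arg-type]


def write_volume(volume: ChannelVolume, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(volume.data))


def read_labels(
    path: str | Path, voxel_size_um: Sequence[float] = DEFAULT_VOXEL_SIZE_UM
) -> LabelVolume:
    """Read an integer-typed 3D TIFF as a LabelVolume; values preserved exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ValueError(f"label volume must be 3D, got shape {arr.shape}")
    return LabelVolume(arr, tuple(voxel_size_um))  # type: ignore[arg-type]


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels.labels))


# ---------------------------------------------------------------------------
# Table I/O (CSV + JSON sidecar)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_table(
    table: CellTable | pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a table as CSV with a JSON metadata sidecar.

    Floats are rendered with full repr precision (>= 6 significant digits);
    integers and boolean flags round-trip losslessly.
    """
    path = Path(path)
    meta: dict[str, object] = dict(metadata or {})
    if isinstance(table, CellTable):
        df = table.df
        meta.setdefault("condition", table.condition.value)
        meta.setdefault("region_id", table.region_id)
        meta.setdefault("voxel_size_um", list(table.voxel_size_um))
    else:
        df = table
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV table and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    df = pd.read_csv(path)
    # restore boolean flag columns written as True/False strings
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna().unique()) <= {"True", "False"}:
            df[col] = df[col] == "True"
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
    return df, meta


def read_cell_table(path: str | Path) -> CellTable:
    df, meta = read_table(path)
    return CellTable(
        df,
        condition=Condition(meta.get("condition", "UNKNOWN")),
        region_id=str(meta.get("region_id", "")),
        voxel_size_um=tuple(meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM)),  # type: ignore[arg-type]
    )
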