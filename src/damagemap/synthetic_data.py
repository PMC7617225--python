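"""Synthetic 3D multi-channel fixtures with known ground truth.

The generator emulates curated sub-volumes of cleared, confocally imaged
tumor tissue: a DAPI channel in which every nucleus is stained, a gamma-H2AX
channel in which only a subset of nuclei is positive — rendered with
per-class damage textures (bright punctate foci and/or diffuse pan-nuclear
fill) — and a CD8 channel in which sparse cytotoxic T cells carry a
membrane-localized ring of signal just outside the nuclear surface.

Nuclei are non-overlapping axis-aligned ellipsoids with jittered radii.
Default parameters follow the curated regions the pipeline targets:
302x302 px laterally, 130 planes, 500-900 cells per region; tests use
scaled-down specs. A small additive Gaussian background models
autofluorescence; no optics (PSF, shot noise) are simulated, since the
fixtures exist to exercise identification, texture and neighborhood logic,
not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import ChannelName, ChannelVolume, LabelVolume, DEFAULT_VOXEL_SIZE_UM

# Rendering intensity levels (arbitrary camera units, ~8-bit scale).
BACKGROUND_LEVEL = 10.0
DAPI_LEVEL = 120.0
GH2AX_FOCUS_LEVEL = 200.0
GH2AX_DIFFUSE_LEVEL = 160.0
CD8_SHELL_LEVEL = 150.0


@dataclass(frozen=True)
class TextureClassSpec:
    """A planted damage-texture class: how many foci, how big, how diffuse."""

    class_id: int
    foci_count_range: tuple[int, int] = (8, 14)
    foci_radius_range: tuple[float, float] = (1.0, 2.0)
    diffuse_level: float = 0.0

    def __post_init__(self) -> None:
        if self.foci_count_range[0] > self.foci_count_range[1]:
            raise ValueError("foci_count_range min > max")
        if self.foci_radius_range[0] > self.foci_radius_range[1]:
            raise ValueError("foci_radius_range min > max")
        if not 0.0 <= self.diffuse_level <= 1.0:
            raise ValueError("diffuse_level must lie in [0, 1]")


#: Two well-separated default classes: punctate foci on a moderate pan-nuclear
#: fill vs a bright diffuse fill. Both fills sit well above background so that
#: positive nuclei threshold as positive over their whole volume.
DEFAULT_TEXTURE_CLASSES = (
    TextureClassSpec(0, foci_count_range=(10, 16), foci_radius_range=(1.5, 2.5), diffuse_level=0.5),
    TextureClassSpec(1, foci_count_range=(0, 0), foci_radius_range=(1.5, 2.5), diffuse_level=0.9),
)


@dataclass
class SynthSpec:
    """Parameters of one synthetic region.

    Defaults mirror the curated regions the pipeline is designed for
    (302x302x130 voxels, ~700 nuclei); shrink ``shape``/``n_nuclei`` for
    desk-scale tests.
    """

    shape: tuple[int, int, int] = (130, 302, 302)
    n_nuclei: int = 700
    frac_gh2ax_pos: float = 0.05
    n_cd8: int = 15
    texture_classes: tuple[TextureClassSpec, ...] = DEFAULT_TEXTURE_CLASSES
    rng_seed: int = 0
    noise_sd: float = 2.0
    radius_range: tuple[float, float] = (4.0, 10.0)
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if not 0.0 <= self.frac_gh2ax_pos <= 1.0:
            raise ValueError("frac_gh2ax_pos must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cd8 > self.n_nuclei:
            raise ValueError("n_cd8 cannot exceed n_nuclei")


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle-style assertions."""

    cells: pd.DataFrame  # cell_id, centroid z/y/x, radii, gh2ax_pos, cd8_pos, texture_class_id
    foci_mask: np.ndarray  # boolean volume marking planted focus voxels

    @property
    def n_gh2ax_pos(self) -> int:
        return int(self.cells["gh2ax_pos"].sum())

    @property
    def n_cd8_pos(self) -> int:
        return int(self.cells["cd8_pos"].sum())


def _place_nuclei(spec: SynthSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rejection-sample non-overlapping ellipsoid (center, radii) pairs."""
    zdim, ydim, xdim = spec.shape
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    max_attempts = 200 * spec.n_nuclei
    attempts = 0
    rmin, rmax = spec.radius_range
    while len(placed) < spec.n_nuclei:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in shape "
                f"{spec.shape} after {max_attempts} attempts; placed {len(placed)} — "
                f"reduce n_nuclei or enlarge the region"
            )
        attempts += 1
        radii = rng.uniform(rmin, rmax, size=3)
        # z radius capped so nuclei fit thin test stacks
        radii[0] = min(radii[0], max(rmin, (zdim - 2) / 2.0))
        center = np.array(
            [
                rng.uniform(radii[0], zdim - radii[0]),
                rng.uniform(radii[1], ydim - radii[1]),
                rng.uniform(radii[2], xdim - radii[2]),
            ]
        )
        ok = True
        for c, r in placed:
            # conservative bounding-sphere test keeps instances disjoint
            if np.linalg.norm(center - c) <= radii.max() + r.max() + 1.0:
                ok = False
                break
        if ok:
            placed.append((center, radii))
    return placed


def _ellipsoid_mask(center: np.ndarray, radii: np.ndarray, shape: tuple[int, int, int]):
    """Boolean mask of an ellipsoid within its bounding box; returns (slices, mask)."""
    lo = np.maximum(np.floor(center - radii).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii).astype(int) + 1, shape)
    grids = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return sl, d <= 1.0


def _render_foci(
    volume: np.ndarray,
    foci_mask: np.ndarray,
    center: np.ndarray,
    radii: np.ndarray,
    tex: TextureClassSpec,
    rng: np.random.Generator,
) -> None:
    n_foci = int(rng.integers(tex.foci_count_range[0], tex.foci_count_range[1] + 1))
    for _ in range(n_foci):
        # uniform direction, biased inward so foci stay inside the nucleus
        u = rng.normal(size=3)
        u /= np.linalg.norm(u) + 1e-12
        frac = rng.uniform(0.0, 0.7)
        pos = center + u * frac * radii
        fr = rng.uniform(*tex.foci_radius_range)
        sl, ball = _ellipsoid_mask(pos, np.full(3, fr), volume.shape)
        volume[sl][ball] = GH2AX_FOCUS_LEVEL
        foci_mask[sl][ball] = True


def generate_region(spec: SynthSpec) -> tuple[dict[ChannelName, ChannelVolume], LabelVolume, GroundTruth]:
    """Generate one synthetic region: channels, instance labels and truth.

    Deterministic given ``spec.rng_seed`` (voxel-exact). Truth-positive
    nuclei are constructed so their channel mean exceeds background by well
    over 3 noise SDs, making positivity calls unambiguous for testing.
    """
    rng = np.random.default_rng(spec.rng_seed)
    zdim, ydim, xdim = spec.shape

    placed = _place_nuclei(spec, rng)
    n = len(placed)

    labels = np.zeros(spec.shape, dtype=np.int32)
    dapi = np.full(spec.shape, BACKGROUND_LEVEL, dtype=np.float32)
    gh2ax = np.full(spec.shape, BACKGROUND_LEVEL, dtype=np.float32)
    cd8 = np.full(spec.shape, BACKGROUND_LEVEL, dtype=np.float32)
    foci_mask = np.zeros(spec.shape, dtype=bool)

    n_pos = int(round(spec.frac_gh2ax_pos * n))
    pos_ids = rng.choice(n, size=n_pos, replace=False) if n_pos else np.array([], dtype=int)
    pos_set = set(pos_ids.tolist())
    # CD8 cells drawn preferentially from gamma-H2AX-negative nuclei
    neg = [i for i in range(n) if i not in pos_set]
    pool = neg if len(neg) >= spec.n_cd8 else list(range(n))
    cd8_ids = rng.choice(len(pool), size=spec.n_cd8, replace=False) if spec.n_cd8 else np.array([], dtype=int)
    cd8_set = {pool[i] for i in cd8_ids.tolist()}

    rows = []
    for i, (center, radii) in enumerate(placed):
        cell_id = i + 1
        sl, mask = _ellipsoid_mask(center, radii, spec.shape)
        labels[sl][mask] = cell_id
        dapi[sl][mask] = DAPI_LEVEL * rng.uniform(0.85, 1.15)

        tex_id = -1
        if i in pos_set:
            tex = spec.texture_classes[int(rng.integers(len(spec.texture_classes)))]
            tex_id = tex.class_id
            if tex.diffuse_level > 0:
                gh2ax[sl][mask] = BACKGROUND_LEVEL + tex.diffuse_level * (
                    GH2AX_DIFFUSE_LEVEL - BACKGROUND_LEVEL
                )
            _render_foci(gh2ax, foci_mask, center, radii, tex, rng)

        if i in cd8_set:
            # membrane ring: ellipsoid grown by ~2 voxels, minus the nucleus
            sl2, outer = _ellipsoid_mask(center, radii + 2.0, spec.shape)
            grids = np.ogrid[sl2]
            inner = (
                sum(((g - cc) / r) ** 2 for g, cc, r in zip(grids, center, radii + 0.5))
                <= 1.0
            )
            shell = outer & ~inner
            cd8[sl2][shell] = CD8_SHELL_LEVEL

        rows.append(
            dict(
                cell_id=cell_id,
                centroid_z=center[0],
                centroid_y=center[1],
                centroid_x=center[2],
                radius_z=radii[0],
                radius_y=radii[1],
                radius_x=radii[2],
                gh2ax_pos=i in pos_set,
                cd8_pos=i in cd8_set,
                texture_class_id=tex_id,
            )
        )

    if spec.noise_sd > 0:
        for vol in (dapi, gh2ax, cd8):
            vol += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
            np.clip(vol, 0.0, None, out=vol)

    channels = {
        ChannelName.DAPI: ChannelVolume(dapi, ChannelName.DAPI, spec.voxel_size_um),
        ChannelName.GH2AX: ChannelVolume(gh2ax, ChannelName.GH2AX, spec.voxel_size_um),
        ChannelName.CD8: ChannelVolume(cd8, ChannelName.CD8, spec.voxel_size_um),
    }
    truth = GroundTruth(cells=pd.DataFrame(rows), foci_mask=foci_mask)
    return channels, LabelVolume(labels, spec.voxel_size_um), truth


def generate_patch_bank(
    class_specs: list[TextureClassSpec] | tuple[TextureClassSpec, ...] = DEFAULT_TEXTURE_CLASSES,
    n_per_class: int = 50,
    seed: int = 0,
    size: int = 64,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a balanced bank of 2D nucleus patches, one texture per class.

    Each patch is a centered elliptical nucleus rendered per its class spec
    (foci and/or diffuse fill on a dark background), values scaled to [0, 1].
    Returns ``(patches, labels)`` with ``patches.shape == (n, size, size)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    patches = []
    labels = []
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    for tex in class_specs:
        for _ in range(n_per_class):
            ry = rng.uniform(0.33, 0.37) * size
            rx = rng.uniform(0.33, 0.37) * size
            nucleus = ((yy - c) / ry) ** 2 + ((xx - c) / rx) ** 2 <= 1.0
            img = np.zeros((size, size), dtype=np.float64)
            img[nucleus] = 0.1 + tex.diffuse_level * 0.7
            n_foci = int(rng.integers(tex.foci_count_range[0], tex.foci_count_range[1] + 1))
            for _ in range(n_foci):
                ang = rng.uniform(0, 2 * np.pi)
                frac = rng.uniform(0.0, 0.7)
                fy = c + np.sin(ang) * frac * ry
                fx = c + np.cos(ang) * frac * rx
                fr = rng.uniform(*tex.foci_radius_range) * (size / 32.0)
                ball = (yy - fy) ** 2 + (xx - fx) ** 2 <= fr**2
                img[ball & nucleus] = 1.0
            if noise_sd > 0:
                img[nucleus] += rng.normal(0, noise_sd, size=int(nucleus.sum()))
            img = np.clip(img, 0.0, 1.0)
            patches.append(img)
            labels.append(tex.class_id)
    return np.asarray(patches), np.asarray(labels)
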