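"""Pseudo texture classes and local-neighborhood profiles.

Per-cell representations (GLCM feature vectors or VAE-GAN latent means) are
standardized and clustered with KMeans into k pseudo texture classes
(default k=5) — surrogate phenotype labels in the absence of expert
annotation — and projected to 2D with PCA for inspection.

Spatial profiling then builds, around every labeled gamma-H2AX+ cell, the
spherical neighborhood of a given radius and counts neighbors per class
(self excluded) plus nearby CD8+ cells. Aggregating over centers of each
class yields a k x k co-occurrence heatmap per condition; counting
gamma-H2AX+ cells around CD8+ cells at 32/64/128 px (10.28/20.56/41.13 um
at the default pixel pitch) quantifies immune/DNA-damage colocalization.
Radii are expressed in lateral pixels; axial displacements are rescaled by
the voxel anisotropy so physical distance is respected.

Condition contrasts (treated - control) use a region-label permutation test:
regions are the exchangeable units, condition labels are shuffled across
regions (>= 999 permutations, seeded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .volume_io import DEFAULT_VOXEL_SIZE_UM, CellTable, Condition

RADII_PX_DEFAULT = (32.0, 64.0, 128.0)


@dataclass
class PseudoClassTable:
    """Cluster labels plus 2D PCA coordinates for every represented cell."""

    df: pd.DataFrame  # cell_id, class_label, pca_x, pca_y
    k: int
    representation: str  # "GLCM" or "VAEGAN"
    cluster_centers: np.ndarray
    inertia: float


def cluster_representations(
    features: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    representation: str = "GLCM",
    standardize: bool = True,
) -> PseudoClassTable:
    """KMeans pseudo texture classes + 2D PCA projection.

    ``features`` must have a ``cell_id`` column; all remaining numeric
    columns are the representation. Columns are standardized to zero mean
    and unit variance first (without this, heavy-tailed features such as
    cluster prominence dominate the Euclidean metric).
    """
    if "cell_id" not in features.columns:
        raise ValueError("features must have a cell_id column")
    feat_cols = [c for c in features.columns if c != "cell_id" and not c.startswith("logvar_")]
    X = features[feat_cols].to_numpy(dtype=np.float64)
    if len(X) < k:
        raise ValueError(f"need at least k={k} cells, got {len(X)}")
    if standardize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns scale to 0, which is fine
            X = StandardScaler().fit_transform(X)
        X = np.nan_to_num(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    n_comp = min(2, X.shape[1])
    xy = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    if n_comp < 2:
        xy = np.column_stack([xy, np.zeros(len(xy))])
    df = pd.DataFrame(
        {
            "cell_id": features["cell_id"].to_numpy(),
            "class_label": labels.astype(int),
            "pca_x": xy[:, 0],
            "pca_y": xy[:, 1],
        }
    )
    return PseudoClassTable(df, k=k, representation=representation,
                            cluster_centers=km.cluster_centers_, inertia=float(km.inertia_))


def _scaled_coords(df: pd.DataFrame, voxel_size_um) -> np.ndarray:
    """Centroids in lateral-pixel units: each axis scaled by its anisotropy."""
    vz, vy, vx = voxel_size_um
    coords = df[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(dtype=np.float64)
    return coords * np.array([vz / vx, vy / vx, 1.0])


def neighborhood_counts(
    cells: CellTable,
    classes: PseudoClassTable,
    radius_px: float,
    voxel_size_um=None,
) -> pd.DataFrame:
    """Spherical-neighborhood profile of every labeled gamma-H2AX+ cell.

    A neighbor is counted iff 0 < distance <= radius (the center itself is
    never counted). Returns one row per center with per-class neighbor
    counts and the CD8+ count in the same ball; exact (KD-tree with full
    radius, equivalent to the quadratic scan).
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    voxel_size_um = voxel_size_um or cells.voxel_size_um or DEFAULT_VOXEL_SIZE_UM
    df = cells.df
    merged = df.merge(classes.df[["cell_id", "class_label"]], on="cell_id", how="left")
    centers = merged[merged["gh2ax_pos"]]
    if centers["class_label"].isna().any():
        raise ValueError(
            "gamma-H2AX+ cells without a pseudo-class label; run the cluster step first"
        )
    k = classes.k
    ccoords = _scaled_coords(centers, voxel_size_um)
    cclass = centers["class_label"].to_numpy(dtype=int)
    cd8 = merged[merged["cd8_pos"]]
    cd8_coords = _scaled_coords(cd8, voxel_size_um)

    rows = []
    tree = cKDTree(ccoords) if len(ccoords) else None
    cd8_tree = cKDTree(cd8_coords) if len(cd8_coords) else None
    for i in range(len(ccoords)):
        counts = np.zeros(k, dtype=int)
        for j in tree.query_ball_point(ccoords[i], radius_px):
            d = np.linalg.norm(ccoords[i] - ccoords[j])
            if 0.0 < d <= radius_px:
                counts[cclass[j]] += 1
        n_cd8 = 0
        if cd8_tree is not None:
            for j in cd8_tree.query_ball_point(ccoords[i], radius_px):
                d = np.linalg.norm(ccoords[i] - cd8_coords[j])
                if 0.0 < d <= radius_px:
                    n_cd8 += 1
        rows.append(
            dict(
                center_cell_id=int(centers.iloc[i]["cell_id"]),
                center_class=int(cclass[i]),
                radius_px=float(radius_px),
                **{f"n_class_{c}": int(counts[c]) for c in range(k)},
                cd8_count=int(n_cd8),
            )
        )
    cols = ["center_cell_id", "center_class", "radius_px",
            *[f"n_class_{c}" for c in range(k)], "cd8_count"]
    return pd.DataFrame(rows, columns=cols)


def cooccurrence_heatmap(profiles: pd.DataFrame, k: int, condition=Condition.UNKNOWN
                         ) -> tuple[np.ndarray, list[int]]:
    """k x k matrix H[i, j] = mean class-j neighbor count over class-i centers.

    Returns ``(H, absent)`` where rows in ``absent`` had no center of that
    class in the data and are NaN (flagged, never imputed).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one neighborhood profile")
    H = np.full((k, k), np.nan)
    absent = []
    for i in range(k):
        sub = profiles[profiles["center_class"] == i]
        if len(sub) == 0:
            absent.append(i)
            continue
        H[i] = [sub[f"n_class_{j}"].mean() for j in range(k)]
    return H, absent


def cd8_proximity_report(
    cells: CellTable,
    radii_px=RADII_PX_DEFAULT,
    voxel_size_um=None,
) -> pd.DataFrame:
    """Counts of gamma-H2AX+ cells within each radius of every CD8+ cell.

    One row per (CD8+ cell, radius) with the count, plus the radius in um
    (lateral pixel pitch). Counts are monotone non-decreasing in radius.
    """
    voxel_size_um = voxel_size_um or cells.voxel_size_um or DEFAULT_VOXEL_SIZE_UM
    df = cells.df
    cd8 = df[df["cd8_pos"]] if len(df) else df
    gh = df[df["gh2ax_pos"]] if len(df) else df
    rows = []
    gh_coords = _scaled_coords(gh, voxel_size_um) if len(gh) else np.zeros((0, 3))
    tree = cKDTree(gh_coords) if len(gh_coords) else None
    cd8_coords = _scaled_coords(cd8, voxel_size_um) if len(cd8) else np.zeros((0, 3))
    for r in radii_px:
        for i in range(len(cd8)):
            n = 0
            if tree is not None:
                for j in tree.query_ball_point(cd8_coords[i], r):
                    d = np.linalg.norm(cd8_coords[i] - gh_coords[j])
                    if 0.0 < d <= r:
                        n += 1
            rows.append(
                dict(
                    cd8_cell_id=int(cd8.iloc[i]["cell_id"]),
                    radius_px=float(r),
                    radius_um=float(r) * float(voxel_size_um[2]),
                    gh2ax_count=int(n),
                )
            )
    return pd.DataFrame(rows, columns=["cd8_cell_id", "radius_px", "radius_um", "gh2ax_count"])


def summarize_proximity(report: pd.DataFrame) -> pd.DataFrame:
    """Per-radius mean and total gamma-H2AX+ counts around CD8+ cells."""
    if len(report) == 0:
        return pd.DataFrame(columns=["radius_px", "radius_um", "n_cd8", "total", "mean"])
    g = report.groupby(["radius_px", "radius_um"])["gh2ax_count"]
    out = g.agg(n_cd8="count", total="sum", mean="mean").reset_index()
    return out


# ---------------------------------------------------------------------------
# condition comparison


@dataclass
class RegionStats:
    """One region's aggregated statistics entering the condition contrast."""

    region_id: str
    condition: Condition
    heatmaps: dict[float, np.ndarray]  # radius_px -> k x k (NaN rows allowed)
    cd8_mean_counts: dict[float, float]  # radius_px -> mean gamma-H2AX+ near CD8+


def region_stats(
    cells: CellTable,
    classes: PseudoClassTable,
    radii_px=RADII_PX_DEFAULT,
    voxel_size_um=None,
) -> RegionStats:
    """Compute everything compare_conditions needs from one region."""
    heatmaps = {}
    cd8_means = {}
    for r in radii_px:
        prof = neighborhood_counts(cells, classes, r, voxel_size_um)
        if len(prof):
            H, _ = cooccurrence_heatmap(prof, classes.k, cells.condition)
        else:
            H = np.full((classes.k, classes.k), np.nan)
        heatmaps[float(r)] = H
        rep = cd8_proximity_report(cells, [r], voxel_size_um)
        cd8_means[float(r)] = float(rep["gh2ax_count"].mean()) if len(rep) else np.nan
    return RegionStats(cells.region_id, cells.condition, heatmaps, cd8_means)


def _mean_diff(values: np.ndarray, is_treated: np.ndarray) -> float:
    """nanmean(treated) - nanmean(control) for one statistic across regions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = np.nanmean(values[is_treated])
        c = np.nanmean(values[~is_treated])
    return float(t - c)


def compare_conditions(
    regions: list[RegionStats],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Treated-minus-control differences with region-permutation p-values.

    For every heatmap cell (i, j) at every radius, and for the mean
    gamma-H2AX-near-CD8 count at every radius, the statistic is the
    difference of condition means over regions; the null distribution comes
    from shuffling condition labels across regions (two-sided p with the
    add-one correction). With a single region per condition differences are
    still reported but p-values are suppressed with a warning.
    """
    is_treated = np.array([Condition(r.condition) is Condition.TREATED for r in regions])
    if not is_treated.any() or is_treated.all():
        raise ValueError("need regions from both conditions")
    suppress_p = is_treated.sum() < 2 or (~is_treated).sum() < 2
    if suppress_p:
        warnings.warn("only one region in some condition; p-values suppressed")

    radii = sorted(regions[0].heatmaps.keys())
    k = next(iter(regions[0].heatmaps.values())).shape[0]
    rng = np.random.default_rng(seed)

    # assemble (statistic name, per-region value vector)
    stats: list[tuple[str, float, int, int, np.ndarray]] = []
    for r in radii:
        for i in range(k):
            for j in range(k):
                vals = np.array([reg.heatmaps[r][i, j] for reg in regions])
                stats.append((f"heatmap_{i}_{j}", r, i, j, vals))
        vals = np.array([reg.cd8_mean_counts[r] for reg in regions])
        stats.append(("gh2ax_near_cd8", r, -1, -1, vals))

    perms = [rng.permutation(is_treated) for _ in range(n_permutations)]
    rows = []
    for name, r, i, j, vals in stats:
        if np.all(np.isnan(vals)):
            continue
        obs = _mean_diff(vals, is_treated)
        p = np.nan
        if not suppress_p and np.isfinite(obs):
            null = np.array([_mean_diff(vals, pm) for pm in perms])
            p = (1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (n_permutations + 1)
        rows.append(dict(statistic=name, radius_px=r, class_i=i, class_j=j,
                         difference=obs, p_value=p))
    return pd.DataFrame(rows)
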