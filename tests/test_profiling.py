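import numpy as np
import pandas as pd
import pytest

from damagemap.profiling import (
    RegionStats,
    cluster_representations,
    compare_conditions,
    cooccurrence_heatmap,
    cd8_proximity_report,
    neighborhood_counts,
    summarize_proximity,
)
from damagemap.volume_io import CellTable, Condition

from conftest import random_cell_table


def brute_force_profile(cells, classes, radius, voxel_size_um, k):
    """O(n^2) oracle for neighborhood counts (same 0 < d <= r rule)."""
    vz, vy, vx = voxel_size_um
    df = cells.df.merge(classes.df[["cell_id", "class_label"]], on="cell_id", how="left")
    coords = df[["centroid_z", "centroid_y", "centroid_x"]].to_numpy() * np.array(
        [vz / vx, vy / vx, 1.0]
    )
    out = {}
    idx = df.index[df.gh2ax_pos].tolist()
    for i in idx:
        counts = np.zeros(k, dtype=int)
        ncd8 = 0
        for j in range(len(df)):
            d = np.linalg.norm(coords[i] - coords[j])
            if 0.0 < d <= radius:
                if df.gh2ax_pos[j] and not np.isnan(df.class_label[j]):
                    counts[int(df.class_label[j])] += 1
                if df.cd8_pos[j]:
                    ncd8 += 1
        out[int(df.cell_id[i])] = (counts, ncd8)
    return out


def make_classes(cells, k=3, seed=0):
    rng = np.random.default_rng(seed)
    from damagemap.profiling import PseudoClassTable

    df = cells.df[cells.df.gh2ax_pos][["cell_id"]].copy()
    df["class_label"] = rng.integers(0, k, len(df))
    df["pca_x"] = 0.0
    df["pca_y"] = 0.0
    return PseudoClassTable(df, k=k, representation="GLCM",
                            cluster_centers=np.zeros((k, 1)), inertia=0.0)


class TestClusterRepresentations:
    def test_every_cell_gets_one_label_in_range(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({"cell_id": np.arange(30),
                              "a": rng.normal(size=30), "b": rng.normal(size=30)})
        pct = cluster_representations(feats, k=5, seed=0)
        assert len(pct.df) == 30
        assert set(pct.df.class_label) <= set(range(5))
        assert {"pca_x", "pca_y"} <= set(pct.df.columns)

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(50, 3))
        b = rng.normal(10, 1, size=(50, 3))  # 10-sigma separation
        feats = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"])
        feats.insert(0, "cell_id", np.arange(100))
        pct = cluster_representations(feats, k=2, seed=0)
        labels = pct.df.class_label.to_numpy()
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_duplicate_points_get_identical_labels(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 2))
        feats = pd.DataFrame(np.vstack([base, base]), columns=["a", "b"])
        feats.insert(0, "cell_id", np.arange(40))
        pct = cluster_representations(feats, k=4, seed=0)
        labels = pct.df.class_label.to_numpy()
        np.testing.assert_array_equal(labels[:20], labels[20:])

    def test_fewer_cells_than_k_rejected(self):
        feats = pd.DataFrame({"cell_id": [1, 2], "a": [0.0, 1.0]})
        with pytest.raises(ValueError, match="at least"):
            cluster_representations(feats, k=5)


class TestNeighborhoodCounts:
    def _pair(self, dist, cls=(0, 0)):
        df = pd.DataFrame(
            {
                "cell_id": [1, 2],
                "centroid_z": [5.0, 5.0],
                "centroid_y": [5.0, 5.0],
                "centroid_x": [5.0, 5.0 + dist],
                "gh2ax_pos": [True, True],
                "cd8_pos": [False, False],
            }
        )
        cells = CellTable(df, Condition.UNKNOWN, "pair")
        from damagemap.profiling import PseudoClassTable

        cdf = pd.DataFrame({"cell_id": [1, 2], "class_label": list(cls),
                            "pca_x": 0.0, "pca_y": 0.0})
        classes = PseudoClassTable(cdf, k=2, representation="GLCM",
                                   cluster_centers=np.zeros((2, 1)), inertia=0.0)
        return cells, classes

    def test_pair_within_radius_counts_each_other(self):
        cells, classes = self._pair(10.0, cls=(0, 0))
        prof = neighborhood_counts(cells, classes, 15.0)
        assert list(prof.n_class_0) == [1, 1]
        assert list(prof.n_class_1) == [0, 0]

    def test_pair_outside_radius_counts_nothing(self):
        cells, classes = self._pair(10.0)
        prof = neighborhood_counts(cells, classes, 5.0)
        assert prof[["n_class_0", "n_class_1", "cd8_count"]].to_numpy().sum() == 0

    def test_symmetry_for_equal_class_pairs(self):
        cells, classes = self._pair(10.0, cls=(1, 1))
        prof = neighborhood_counts(cells, classes, 15.0)
        assert prof.n_class_1.tolist() == [1, 1]

    @pytest.mark.parametrize("voxel_size", [(0.32125,) * 3, (1.0, 0.32125, 0.32125)])
    def test_matches_quadratic_oracle_exactly(self, voxel_size):
        """KD-tree counts equal the O(n^2) double loop, isotropic or not."""
        cells = random_cell_table(n=100, seed=3)
        classes = make_classes(cells, k=3)
        for radius in (10.0, 25.0, 40.0):
            prof = neighborhood_counts(cells, classes, radius, voxel_size)
            oracle = brute_force_profile(cells, classes, radius, voxel_size, 3)
            for _, row in prof.iterrows():
                counts, ncd8 = oracle[row.center_cell_id]
                assert [row[f"n_class_{c}"] for c in range(3)] == counts.tolist()
                assert row.cd8_count == ncd8

    def test_counts_monotone_in_radius(self):
        cells = random_cell_table(n=80, seed=4)
        classes = make_classes(cells, k=2)
        prev = None
        for radius in (10.0, 20.0, 40.0, 80.0):
            prof = neighborhood_counts(cells, classes, radius).set_index("center_cell_id")
            tot = prof[["n_class_0", "n_class_1", "cd8_count"]].sum(axis=1)
            if prev is not None:
                assert (tot >= prev).all()
            prev = tot

    def test_unlabeled_centers_rejected(self):
        cells = random_cell_table(n=20, seed=5)
        classes = make_classes(cells, k=2)
        classes.df = classes.df.iloc[:-1]  # drop one labeled positive
        with pytest.raises(ValueError, match="cluster"):
            neighborhood_counts(cells, classes, 10.0)


class TestCooccurrenceHeatmap:
    def _profiles(self, rows, k=4):
        recs = []
        for center_class, counts in rows:
            rec = {"center_cell_id": len(recs), "center_class": center_class,
                   "radius_px": 10.0, "cd8_count": 0}
            rec.update({f"n_class_{j}": c for j, c in enumerate(counts)})
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_single_center_single_neighbor(self):
        prof = self._profiles([(0, [0, 0, 0, 1])])
        H, absent = cooccurrence_heatmap(prof, 4)
        assert H[0, 3] == 1.0 and np.nansum(H) == 1.0
        assert absent == [1, 2, 3]

    def test_planted_lattice_mean_of_two(self):
        prof = self._profiles([(0, [0, 2, 0, 0]), (0, [0, 2, 0, 0])])
        H, _ = cooccurrence_heatmap(prof, 4)
        assert H[0, 1] == 2.0

    def test_duplicating_profiles_leaves_means_unchanged(self):
        prof = self._profiles([(0, [1, 0, 3, 0]), (1, [0, 2, 0, 1]), (0, [2, 0, 1, 0])])
        H1, _ = cooccurrence_heatmap(prof, 4)
        H2, _ = cooccurrence_heatmap(pd.concat([prof, prof], ignore_index=True), 4)
        np.testing.assert_allclose(H1, H2, equal_nan=True)


class TestCd8Proximity:
    def test_printed_radius_conversions(self):
        cells = random_cell_table(n=30, seed=6)
        rep = cd8_proximity_report(cells)
        by_r = rep.drop_duplicates("radius_px").set_index("radius_px").radius_um
        assert by_r[32.0] == pytest.approx(10.28)
        assert by_r[64.0] == pytest.approx(20.56)
        assert by_r[128.0] == pytest.approx(41.12, abs=0.02)

    def test_no_cd8_cells_gives_empty_rows_zero_totals(self):
        cells = random_cell_table(n=20, seed=7, frac_cd8=0.0)
        rep = cd8_proximity_report(cells)
        assert len(rep) == 0
        assert summarize_proximity(rep).empty

    def test_counts_nested_in_radius_per_cell(self):
        cells = random_cell_table(n=100, seed=8)
        rep = cd8_proximity_report(cells, radii_px=(32, 64, 128))
        wide = rep.pivot(index="cd8_cell_id", columns="radius_px", values="gh2ax_count")
        assert (wide[64.0] >= wide[32.0]).all()
        assert (wide[128.0] >= wide[64.0]).all()


class TestCompareConditions:
    def _regions(self, control_level, treated_level, n_per=3, k=2):
        regs = []
        for i in range(2 * n_per):
            cond = Condition.CONTROL if i < n_per else Condition.TREATED
            level = control_level if i < n_per else treated_level
            H = {32.0: np.full((k, k), float(level))}
            regs.append(RegionStats(f"r{i}", cond, H, {32.0: float(level)}))
        return regs

    def test_identical_conditions_give_zero_differences(self):
        comp = compare_conditions(self._regions(2.0, 2.0), n_permutations=99, seed=0)
        assert (comp.difference == 0).all()

    def test_planted_shift_detected_with_correct_sign(self):
        comp = compare_conditions(self._regions(1.0, 3.0, n_per=5), n_permutations=199, seed=0)
        assert (comp.difference == 2.0).all()
        assert (comp.p_value <= 0.05).all()

    def test_single_region_per_condition_suppresses_p(self):
        regs = self._regions(1.0, 2.0, n_per=1)
        with pytest.warns(UserWarning, match="suppressed"):
            comp = compare_conditions(regs, n_permutations=99, seed=0)
        assert comp.p_value.isna().all()
        assert (comp.difference == 1.0).all()

    def test_one_condition_only_rejected(self):
        regs = self._regions(1.0, 2.0)[:3]
        with pytest.raises(ValueError, match="both conditions"):
            compare_conditions(regs)
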